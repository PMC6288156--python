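"""Survival and rank statistics for biochemical-recurrence analyses.

Self-contained implementations of the Cox proportional-hazards model (Newton–
Raphson on the partial likelihood, Efron or Breslow tie handling), the
Kaplan–Meier product-limit estimator, the log-rank test, Harrell's
concordance index and the Wilcoxon rank-sum test.  The clinical endpoint
throughout is time to biochemical recurrence (BCR) after radical
prostatectomy; patients without BCR are censored at their last PSA test.

Clinical tables are DataFrames with at least ``time`` (> 0) and ``event``
(boolean) columns; covariates are additional numeric columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_CONV_TOL = 1e-8
_MAX_ITER = 50


class SurvivalError(ValueError):
    pass


def _check_clinical(clinical: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=bool)
    if np.any(time <= 0):
        raise SurvivalError("all survival times must be positive")
    if not event.any():
        raise SurvivalError("no events in the cohort")
    return time, event


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model.

    ``beta`` are log-hazard-ratio coefficients; ``hr`` = exp(beta); Wald
    standard errors come from the observed information at the optimum.
    """

    beta: pd.Series
    se: pd.Series
    loglik: float
    ties: str
    converged: bool
    n: int
    n_events: int

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.beta)

    @property
    def wald_z(self) -> pd.Series:
        return self.beta / self.se

    @property
    def wald_p(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.wald_z)), index=self.beta.index)

    @property
    def ci95(self) -> pd.DataFrame:
        half = 1.959963984540054 * self.se
        return pd.DataFrame(
            {"hr_low": np.exp(self.beta - half), "hr_high": np.exp(self.beta + half)}
        )

    def linear_predictor(self, covariates: pd.DataFrame) -> pd.Series:
        x = covariates[list(self.beta.index)].to_numpy(dtype=float)
        return pd.Series(x @ self.beta.to_numpy(), index=covariates.index)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "beta": self.beta,
                "hr": self.hr,
                "se": self.se,
                "p": self.wald_p,
            }
        )
        return out.join(self.ci95)


def cox_partial_loglik(
    beta: np.ndarray,
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
) -> float:
    """Partial log-likelihood at ``beta`` (reference formula, loop form)."""
    eta = x @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event]):
        dead = event & (time == t)
        risk = time >= t
        d = int(dead.sum())
        s_risk = w[risk].sum()
        s_dead = w[dead].sum()
        ll += eta[dead].sum()
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= np.log(s_risk - frac * s_dead)
    return float(ll)


def fit_cox(
    clinical: pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
    max_iter: int = _MAX_ITER,
    tol: float = _CONV_TOL,
    ridge: float = 0.0,
) -> CoxFit:
    """Newton–Raphson maximisation of the Cox partial likelihood.

    Efron's correction (default) matches the R ``survival`` package; Breslow
    is available via ``ties='breslow'``.  Convergence requires the maximum
    absolute score component to fall below ``tol`` within ``max_iter``
    iterations; a monotone likelihood (complete separation) is reported as
    ``converged=False`` rather than raising.  ``ridge`` adds an L2 penalty
    0.5 * ridge * ||beta||^2, useful when panel genes are collinear.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    time, event = _check_clinical(clinical)
    x = clinical[covariates].to_numpy(dtype=float)
    if np.any(x.std(axis=0) == 0):
        constant = [c for c in covariates if clinical[c].nunique() == 1]
        raise SurvivalError(f"constant covariates: {constant}")
    n, p = x.shape
    center = x.mean(axis=0)
    xc = x - center  # centering stabilises exp(eta); beta is unchanged

    beta = np.zeros(p)
    event_times = np.unique(time[event])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = xc @ beta
        w = np.exp(eta)
        score = np.zeros(p)
        info = np.zeros((p, p))
        ll = 0.0
        for t in event_times:
            dead = event & (time == t)
            risk = time >= t
            d = int(dead.sum())
            wr = w[risk]
            xr = xc[risk]
            s0_r = wr.sum()
            s1_r = wr @ xr
            s2_r = (wr[:, None] * xr).T @ xr
            wd = w[dead]
            xd = xc[dead]
            s0_d = wd.sum()
            s1_d = wd @ xd
            s2_d = (wd[:, None] * xd).T @ xd
            ll += eta[dead].sum()
            score += xd.sum(axis=0)
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                s0 = s0_r - frac * s0_d
                s1 = s1_r - frac * s1_d
                s2 = s2_r - frac * s2_d
                ll -= np.log(s0)
                score -= s1 / s0
                info += s2 / s0 - np.outer(s1, s1) / s0**2
        if ridge > 0:
            ll -= 0.5 * ridge * float(beta @ beta)
            score -= ridge * beta
            info += ridge * np.eye(p)
        if np.max(np.abs(score)) < tol:
            converged = True
            ll_old = ll
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break

        def penalised_ll(b: np.ndarray) -> float:
            out = cox_partial_loglik(b, xc, time, event, ties)
            return out - 0.5 * ridge * float(b @ b)

        # step-halving if the likelihood would decrease
        factor = 1.0
        for _half in range(30):
            cand = beta + factor * step
            if penalised_ll(cand) >= ll - 1e-12:
                break
            factor /= 2
        beta = beta + factor * step
        ll_old = ll
        if np.max(np.abs(beta)) > 50:
            break  # monotone likelihood / separation

    # observed information at the optimum for Wald standard errors
    eta = xc @ beta
    w = np.exp(eta)
    info = np.zeros((p, p))
    for t in event_times:
        dead = event & (time == t)
        risk = time >= t
        d = int(dead.sum())
        wr, xr = w[risk], xc[risk]
        s0_r, s1_r = wr.sum(), wr @ xr
        s2_r = (wr[:, None] * xr).T @ xr
        wd, xd = w[dead], xc[dead]
        s0_d, s1_d = wd.sum(), wd @ xd
        s2_d = (wd[:, None] * xd).T @ xd
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            s0 = s0_r - frac * s0_d
            s1 = s1_r - frac * s1_d
            s2 = s2_r - frac * s2_d
            info += s2 / s0 - np.outer(s1, s1) / s0**2
    if np.max(np.abs(beta)) > 15:
        converged = False  # divergent coefficients: monotone likelihood / separation
    if ridge > 0:
        info += ridge * np.eye(p)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False

    return CoxFit(
        beta=pd.Series(beta, index=covariates),
        se=pd.Series(se, index=covariates),
        loglik=float(cox_partial_loglik(beta, xc, time, event, ties)),
        ties=ties,
        converged=converged,
        n=n,
        n_events=int(event.sum()),
    )


@dataclass
class KMEstimate:
    """Product-limit survival estimate for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


def km_estimate(time: np.ndarray, event: np.ndarray, group: str = "") -> KMEstimate:
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time[event])
    surv, s = [], 1.0
    at_risk, n_ev = [], []
    for t in uniq:
        n_r = int((time >= t).sum())
        d = int(((time == t) & event).sum())
        s *= 1.0 - d / n_r
        surv.append(s)
        at_risk.append(n_r)
        n_ev.append(d)
    return KMEstimate(
        group=group,
        times=uniq,
        survival=np.array(surv),
        at_risk=np.array(at_risk),
        n_events=np.array(n_ev),
    )


def km_logrank(
    clinical: pd.DataFrame, groups: pd.Series | np.ndarray | list
) -> tuple[dict[str, KMEstimate], LogRankResult]:
    """Kaplan–Meier curves per group plus the k-sample log-rank test."""
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=bool)
    glab = np.asarray(pd.Series(groups).to_numpy())
    labels = [str(v) for v in pd.unique(glab)]
    if len(labels) < 2:
        raise SurvivalError("log-rank needs at least two groups")
    for lab in labels:
        if (glab.astype(str) == lab).sum() == 0:
            raise SurvivalError(f"group {lab!r} is empty")

    curves = {
        lab: km_estimate(time[glab.astype(str) == lab], event[glab.astype(str) == lab], lab)
        for lab in labels
    }

    k = len(labels)
    o_minus_e = np.zeros(k - 1)
    v = np.zeros((k - 1, k - 1))
    for t in np.unique(time[event]):
        risk = time >= t
        dead = (time == t) & event
        n = int(risk.sum())
        d = int(dead.sum())
        if n < 2:
            continue
        n_g = np.array([(risk & (glab.astype(str) == lab)).sum() for lab in labels], dtype=float)
        d_g = np.array([(dead & (glab.astype(str) == lab)).sum() for lab in labels], dtype=float)
        e_g = d * n_g / n
        o_minus_e += (d_g - e_g)[:-1]
        hyper = d * (n - d) / max(n - 1, 1)
        for a in range(k - 1):
            for b in range(k - 1):
                if a == b:
                    v[a, b] += hyper * n_g[a] * (n - n_g[a]) / n**2
                else:
                    v[a, b] -= hyper * n_g[a] * n_g[b] / n**2
    if np.allclose(v, 0):
        statistic = 0.0
    else:
        statistic = float(o_minus_e @ np.linalg.pinv(v) @ o_minus_e)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return curves, LogRankResult(statistic=statistic, df=df, p=p)


def harrell_c(scores: pd.Series | np.ndarray, clinical: pd.DataFrame) -> float:
    """Harrell's concordance index: higher score should mean earlier event.

    Usable pairs are those where the patient with the shorter time had an
    event; score ties contribute 0.5.  Pairs censored before the other's event
    are not comparable.
    """
    if isinstance(scores, pd.Series):
        if "patient_id" in clinical.columns and clinical["patient_id"].isin(scores.index).all():
            scores = scores.loc[clinical["patient_id"]]
        elif scores.index.equals(clinical.index):
            scores = scores.loc[clinical.index]
        elif len(scores) != len(clinical):
            raise SurvivalError("scores cannot be aligned with the clinical table")
    s = np.asarray(scores, dtype=float)
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=bool)
    dt = time[:, None] - time[None, :]          # dt[i,j] = t_i - t_j
    usable = (dt > 0) & event[None, :]           # j failed before i
    if not usable.any():
        raise SurvivalError("no usable pairs for the concordance index")
    ds = s[:, None] - s[None, :]                 # score_i - score_j
    concordant = (ds < 0) & usable               # earlier failure has higher score
    tied = (ds == 0) & usable
    return float((concordant.sum() + 0.5 * tied.sum()) / usable.sum())


@dataclass
class RankSumResult:
    u: float
    p: float
    method: str


def wilcoxon_ranksum(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U).

    Exact distribution for combined n <= 20 without ties; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(u=float(res.statistic), p=float(res.pvalue), method=method)
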