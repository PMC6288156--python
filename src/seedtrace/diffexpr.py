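"""Two-group differential expression on negative-binomial counts.

The pipeline mirrors the classic count-based exact-test workflow: trimmed mean
of M-values (TMM) normalisation, library-size equalisation into pseudo-counts,
conditional-likelihood dispersion estimation (common value with per-gene
moderation), and a conditional exact test for equality of the two group means
given the gene's total, followed by Benjamini–Hochberg adjustment.

Counts are modelled NB(mu, alpha) with variance mu + alpha * mu**2 (alpha is
the dispersion).  The sum of n i.i.d. NB(mu, alpha) draws is NB(n*mu, alpha/n),
which is what makes the two-group conditional test exact once library sizes
have been equalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_prep import ExpressionMatrix

logger = logging.getLogger(__name__)

DE_COLUMNS = ["log2fc", "pvalue", "fdr", "mean_expr"]

_MIN_DISPERSION = 1e-6
_MAX_DISPERSION = 10.0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tmm_factors(
    counts: np.ndarray,
    ref_col: int | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """TMM composition factors (doubling sequencing depth alone gives factor 1).

    The reference sample is the one whose upper quartile of scaled counts is
    closest to the mean upper quartile.  For each sample, M (log ratio) and A
    (log abundance) values against the reference are computed over genes
    positive in both; the most extreme 30% of M and 5% of A are trimmed and the
    remaining M values averaged with inverse-variance (delta-method) weights.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with zero total counts")
    if ref_col is None:
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
        ref_col = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_col] / lib[ref_col]
    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        obs = counts[:, j] / lib[j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 10:
            continue
        m = np.log2(obs[ok] / ref[ok])
        a = 0.5 * np.log2(obs[ok] * ref[ok])
        # delta-method variance of M drives the weights
        y_ref = ref[ok] * lib[ref_col]
        w = (lib[j] - counts[ok, j]) / (lib[j] * counts[ok, j]) + (
            lib[ref_col] - y_ref
        ) / (lib[ref_col] * y_ref)
        keep = np.ones(ok.sum(), dtype=bool)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep &= (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            continue
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    log_factors -= log_factors.mean()  # geometric mean 1
    return 2.0 ** log_factors


def norm_factors(counts: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample scale factors: library size x TMM factor, geometric mean 1.

    Dividing each column by its factor puts all samples on a common effective
    scale; a column that is a pure x2 copy of another gets a factor ~2x its
    twin's.
    """
    data = counts.data if isinstance(counts, ExpressionMatrix) else counts
    arr = data.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need at least two samples")
    lib = arr.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with zero total counts")
    eff = lib * tmm_factors(arr)
    eff = eff / np.exp(np.mean(np.log(eff)))
    return pd.Series(eff, index=data.columns, name="scale_factor")


def _pseudo_counts(data: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts rescaled to a common effective library size (continuous values)."""
    if factors is None:
        factors = norm_factors(data)
    return data.div(factors, axis=1)


def normalized_log2(counts: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(normalised counts + pseudocount): the clustering-ready matrix.

    Columns are first divided by their TMM x library-size scale factor so that
    sequencing-depth differences do not show up as global per-sample offsets.
    """
    data = counts.data if isinstance(counts, ExpressionMatrix) else counts
    pseudo = _pseudo_counts(data)
    return ExpressionMatrix(data=np.log2(pseudo + pseudocount), unit="log2counts")


def _group_cond_loglik(pseudo: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Conditional log-likelihood of each gene's counts given their group total.

    ``pseudo``: genes x samples (one group, equalised libraries).
    ``alphas``: dispersion grid.  Returns genes x alphas.  The conditional
    likelihood is free of the gene mean, which is what removes the bias of
    plugging in estimated means.
    """
    g, n = pseudo.shape
    t = pseudo.sum(axis=1)
    out = np.empty((g, len(alphas)))
    for k, a in enumerate(alphas):
        r = 1.0 / a
        ll = gammaln(pseudo + r).sum(axis=1) - n * gammaln(r)
        ll -= gammaln(t + n * r) - gammaln(n * r)
        out[:, k] = ll
    return out


def estimate_dispersion(
    counts: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series | dict,
    prior_df: float = 10.0,
    tagwise: bool = True,
) -> pd.DataFrame:
    """Common + moderated per-gene NB dispersions by conditional likelihood.

    Per-gene estimates maximise the gene's own conditional log-likelihood plus
    a prior weight (``prior_df`` / residual df) times the genewise-average
    log-likelihood, shrinking noisy single-gene estimates toward the common
    value.  Returns a DataFrame with ``common`` and ``tagwise`` columns.
    """
    data = counts.data if isinstance(counts, ExpressionMatrix) else counts
    groups = pd.Series(groups)
    pseudo = _pseudo_counts(data)
    labels = groups.loc[data.columns]
    group_arrays = []
    single = False
    for lab in labels.unique():
        cols = labels.index[labels == lab]
        if len(cols) < 2:
            single = True
            continue
        group_arrays.append(pseudo[cols].to_numpy(dtype=float))
    if not group_arrays:
        raise ValueError("no group with >= 2 samples; cannot estimate dispersion")
    if single:
        logger.warning("estimate_dispersion: singleton group ignored (no replication)")

    alphas = np.exp(np.linspace(np.log(_MIN_DISPERSION), np.log(_MAX_DISPERSION), 80))
    ll = sum(_group_cond_loglik(arr, alphas) for arr in group_arrays)
    total = ll.sum(axis=0)
    common = float(alphas[int(np.argmax(total))])
    # refine the common estimate off the grid
    def neg_total(log_a: float) -> float:
        a = np.array([np.exp(log_a)])
        return -sum(_group_cond_loglik(arr, a) for arr in group_arrays).sum()

    res = minimize_scalar(
        neg_total,
        bounds=(np.log(_MIN_DISPERSION), np.log(_MAX_DISPERSION)),
        method="bounded",
    )
    if res.success:
        common = float(np.exp(res.x))

    if not tagwise:
        tw = np.full(data.shape[0], common)
    else:
        n_samples = sum(arr.shape[1] for arr in group_arrays)
        df_res = max(n_samples - len(group_arrays), 1)
        weight = prior_df / df_res
        objective = ll + weight * ll.mean(axis=0, keepdims=True)
        tw = alphas[np.argmax(objective, axis=1)]
    return pd.DataFrame({"common": common, "tagwise": tw}, index=data.index)


def _cond_exact_pvalue(t1: float, t: float, n1: int, n2: int, alpha: float) -> float:
    """Exact two-sided p for the split of an integer total ``t`` into group sums.

    Group sums are NB(n_i * mu, alpha / n_i); conditioning on t removes mu.
    Two-sided p = total conditional probability of outcomes no more likely
    than the observed split.
    """
    t = int(round(t))
    t1 = int(round(t1))
    if t == 0:
        return 1.0
    alpha = max(alpha, _MIN_DISPERSION)
    r1, r2 = n1 / alpha, n2 / alpha
    y = np.arange(t + 1)
    mu = t / (n1 + n2)
    m1, m2 = n1 * mu, n2 * mu
    logw = (
        gammaln(y + r1) - gammaln(y + 1) + y * np.log(m1 / (r1 + m1))
        + gammaln(t - y + r2) - gammaln(t - y + 1) + (t - y) * np.log(m2 / (r2 + m2))
    )
    logw -= logsumexp(logw)
    obs = logw[t1]
    mask = logw <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logw[mask]))))


def nb_exact_test(
    counts: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series | dict,
    contrast: tuple[str, str],
    dispersion: pd.Series | np.ndarray | float | None = None,
    lfc_pseudocount: float = 0.125,
) -> pd.DataFrame:
    """Conditional NB exact test per gene for ``contrast = (group1, group2)``.

    Returns a DETable-style DataFrame (index gene id) with ``log2fc`` (group2
    over group1 on equalised counts, pseudocount ``lfc_pseudocount``),
    ``pvalue``, BH-adjusted ``fdr`` and ``mean_expr``.  A gene with zero counts
    everywhere gets p = 1 and log2fc = 0.
    """
    data = counts.data if isinstance(counts, ExpressionMatrix) else counts
    groups = pd.Series(groups)
    g1, g2 = contrast
    cols1 = [s for s in data.columns if groups.get(s) == g1]
    cols2 = [s for s in data.columns if groups.get(s) == g2]
    if not cols1 or not cols2:
        raise ValueError(f"contrast {contrast} selects an empty group")
    sub = data[cols1 + cols2]
    factors = norm_factors(sub)
    pseudo = _pseudo_counts(sub, factors)
    if dispersion is None:
        lab = pd.Series({s: g1 for s in cols1} | {s: g2 for s in cols2})
        dispersion = estimate_dispersion(sub, lab)["tagwise"]
    disp = (
        np.full(len(data.index), float(dispersion))
        if np.isscalar(dispersion)
        else np.asarray(pd.Series(dispersion).loc[data.index] if isinstance(dispersion, pd.Series) else dispersion, dtype=float)
    )

    n1, n2 = len(cols1), len(cols2)
    t1 = pseudo[cols1].sum(axis=1).round().to_numpy()
    t2 = pseudo[cols2].sum(axis=1).round().to_numpy()
    pvals = np.ones(len(data.index))
    for i in range(len(data.index)):
        pvals[i] = _cond_exact_pvalue(t1[i], t1[i] + t2[i], n1, n2, disp[i])
    m1 = t1 / n1
    m2 = t2 / n2
    log2fc = np.where(
        (t1 + t2) == 0, 0.0, np.log2((m2 + lfc_pseudocount) / (m1 + lfc_pseudocount))
    )
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
            "mean_expr": (t1 + t2) / (n1 + n2),
        },
        index=data.index,
    )
    table.index.name = "gene_id"
    return table


def welch_log_de(
    expr: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series | dict,
    contrast: tuple[str, str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Welch t-test on log2 values — documented fallback for FPKM-only cohorts."""
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    groups = pd.Series(groups)
    g1, g2 = contrast
    cols1 = [s for s in data.columns if groups.get(s) == g1]
    cols2 = [s for s in data.columns if groups.get(s) == g2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs >= 2 samples for the Welch fallback")
    x1 = np.log2(data[cols1].to_numpy(dtype=float) + pseudocount)
    x2 = np.log2(data[cols2].to_numpy(dtype=float) + pseudocount)
    t, p = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame(
        {
            "log2fc": x2.mean(axis=1) - x1.mean(axis=1),
            "pvalue": p,
            "fdr": bh_adjust(p),
            "mean_expr": data[cols1 + cols2].mean(axis=1).to_numpy(),
        },
        index=data.index,
    )
    table.index.name = "gene_id"
    return table


@dataclass
class DEResult:
    """Bundle of a DE table with the contrast and method that produced it."""

    table: pd.DataFrame
    contrast: tuple[str, str]
    method: str = "nb_exact"


def run_de(
    counts: ExpressionMatrix,
    groups: pd.Series | dict,
    contrast: tuple[str, str],
    method: str = "nb_exact",
) -> DEResult:
    """Full two-group pipeline: normalisation, dispersion, test, BH."""
    if method == "nb_exact":
        table = nb_exact_test(counts, groups, contrast)
    elif method == "welch_log":
        table = welch_log_de(counts, groups, contrast)
    else:
        raise ValueError(f"unknown DE method {method!r}")
    return DEResult(table=table, contrast=contrast, method=method)


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", columns=DE_COLUMNS, index_label="gene_id")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
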