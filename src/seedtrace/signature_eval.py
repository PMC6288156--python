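"""Cox-weighted prognostic signatures: fitting, scoring, cutoff transfer, evaluation.

A signature model is a gene panel whose per-gene weights come from a joint
(multivariate) Cox regression of biochemical recurrence on the panel's
expression.  The raw patient score is the Cox linear predictor
``sum_g beta_g * x_g``; the reported score divides this by the standard
deviation of raw scores in the fitting cohort, so hazard ratios are per score
standard deviation.  Risk groups transfer across cohorts as a quantile: the
top ``cutoff_fraction`` of patients by score are high-risk in every cohort.

The evaluation battery mirrors common prognostic-marker practice: univariate
Cox per clinicopathological covariate and for the score; a multivariate model
seeded with the univariate-significant covariates and pruned by stepwise
backward elimination (the score is always retained and reported); Harrell's
C-index for the final model with and without the score on the identical
patient set; Kaplan–Meier with log-rank on the transferred risk groups; and
Wilcoxon rank-sum of the score against each binary covariate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import ExpressionMatrix, match_panel_genes, to_log2
from .progression import GenePanel
from .survival_stats import (
    CoxFit,
    KMEstimate,
    LogRankResult,
    RankSumResult,
    SurvivalError,
    fit_cox,
    harrell_c,
    km_logrank,
    wilcoxon_ranksum,
)

logger = logging.getLogger(__name__)

SIGNIFICANCE = 0.05
DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.25, 0.751, 0.05), 2))


@dataclass
class SignatureModel:
    """A fitted, standardised prognostic signature."""

    panel: GenePanel
    weights: dict[str, float]
    score_sd: float
    cutoff_fraction: float | None = None
    reference_cohort: str = ""

    def __post_init__(self) -> None:
        if self.score_sd <= 0:
            raise ValueError("score_sd must be positive")
        extra = set(self.weights) - set(self.panel.gene_ids)
        if extra:
            raise ValueError(f"weights outside the panel: {sorted(extra)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "panel": self.panel.gene_ids,
            "directions": self.panel.directions,
            "provenance": self.panel.provenance,
            "weights": self.weights,
            "score_sd": self.score_sd,
            "cutoff_fraction": self.cutoff_fraction,
            "reference_cohort": self.reference_cohort,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            panel=GenePanel(
                gene_ids=payload["panel"],
                directions=payload.get("directions", {}),
                provenance=payload.get("provenance", ""),
            ),
            weights=payload["weights"],
            score_sd=payload["score_sd"],
            cutoff_fraction=payload.get("cutoff_fraction"),
            reference_cohort=payload.get("reference_cohort", ""),
        )


def _expression_covariates(
    expr: ExpressionMatrix, genes: list[str], clinical: pd.DataFrame
) -> pd.DataFrame:
    """Panel-gene expression as per-patient covariate columns (log2 scale)."""
    if expr.unit in ("counts", "fpkm"):
        expr = to_log2(expr)
    x = expr.data.loc[genes].T
    x = x.loc[clinical["patient_id"]]
    x.index = clinical.index
    return x


def fit_weighted_model(
    expr: ExpressionMatrix,
    panel: GenePanel,
    clinical: pd.DataFrame,
    reference_cohort: str = "",
    ridge: float = 0.0,
) -> SignatureModel:
    """Fit the per-gene Cox weights and the cohort score SD.

    Panel genes are entered *jointly* into a multivariate Cox regression on
    log2 expression; missing genes are dropped with a logged coverage
    fraction.  Weights are refit in each cohort that is scored — the design
    this reproduces — so cross-cohort evaluation is optimistic; freeze the
    returned model to validate externally.
    """
    matched, coverage = match_panel_genes(panel.gene_ids, expr)
    if not matched:
        raise ValueError("no panel genes available in the cohort")
    if coverage < 1:
        logger.warning("fit_weighted_model: panel coverage %.1f%%", 100 * coverage)
    x = _expression_covariates(expr, matched, clinical)
    table = pd.concat([clinical[["time", "event"]], x], axis=1)
    fit = fit_cox(table, matched, ridge=ridge)
    if not fit.converged:
        raise SurvivalError(
            "multivariate Cox on the panel did not converge; retry with ridge > 0"
        )
    raw = x.to_numpy() @ fit.beta.to_numpy()
    sd = float(np.std(raw, ddof=1))
    if sd <= 0:
        raise SurvivalError("degenerate panel: zero score variance")
    return SignatureModel(
        panel=panel,
        weights={g: float(b) for g, b in fit.beta.items()},
        score_sd=sd,
        reference_cohort=reference_cohort,
    )


def score_patients(model: SignatureModel, expr: ExpressionMatrix, clinical: pd.DataFrame) -> pd.Series:
    """Standardised signature score per patient (raw linear predictor / score SD)."""
    genes = [g for g in model.weights if g in set(expr.gene_ids)]
    if not genes:
        raise ValueError("no model genes present in the expression matrix")
    if len(genes) < len(model.weights):
        logger.warning(
            "score_patients: %d/%d weighted genes available", len(genes), len(model.weights)
        )
    x = _expression_covariates(expr, genes, clinical)
    beta = np.array([model.weights[g] for g in genes])
    raw = x.to_numpy() @ beta
    scores = pd.Series(raw / model.score_sd, index=clinical["patient_id"].to_numpy())
    scores.name = "signature_score"
    return scores


def transfer_cutoff(cutoff_fraction: float, scores: pd.Series) -> pd.Series:
    """Label the top ``cutoff_fraction`` of patients by score as ``high``.

    The same fraction defines the split in any cohort, which is how a cutoff
    chosen in a reference cohort transfers.  Score ties at the boundary break
    by patient-id order (warned), so labels depend only on score ranks.
    """
    if not 0 < cutoff_fraction < 1:
        raise ValueError("cutoff_fraction must lie in (0, 1)")
    n_high = int(round(cutoff_fraction * len(scores)))
    order = sorted(scores.index, key=lambda pid: (-scores[pid], str(pid)))
    boundary = scores[order[n_high - 1]] if n_high >= 1 else np.inf
    if n_high < len(scores) and scores[order[n_high]] == boundary:
        logger.warning("transfer_cutoff: score tie at the boundary broken by patient id")
    labels = pd.Series("low", index=scores.index, name="risk_group")
    labels.loc[order[:n_high]] = "high"
    return labels


def choose_cutoff_fraction(
    scores: pd.Series,
    clinical: pd.DataFrame,
    grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID,
) -> tuple[float, float]:
    """Reference-cohort cutoff fraction: grid point minimising the log-rank p.

    Returns (fraction, best_p).  Choosing the split this way is exploratory —
    the winning p-value is optimistic and must not be quoted as confirmatory.
    """
    if len(grid) == 0:
        raise ValueError("empty cutoff grid")
    aligned = clinical.set_index("patient_id").loc[scores.index].reset_index()
    best: tuple[float, float] | None = None
    for frac in grid:
        labels = transfer_cutoff(float(frac), scores)
        if labels.nunique() < 2:
            continue
        _, lr = km_logrank(aligned, labels.to_numpy())
        if best is None or lr.p < best[1]:
            best = (float(frac), lr.p)
    if best is None:
        raise ValueError("no grid fraction produced two nonempty groups")
    if best[1] >= SIGNIFICANCE:
        logger.warning(
            "choose_cutoff_fraction: best split not significant (p=%.3g)", best[1]
        )
    return best


@dataclass
class EvaluationReport:
    """Full prognostic evaluation of a signature in one cohort."""

    cohort: str
    univariate: dict[str, CoxFit]
    univariate_c: dict[str, float]
    multivariate: CoxFit
    selected_covariates: list[str]
    c_index_with: float
    c_index_without: float
    km_curves: dict[str, KMEstimate] | None
    logrank: LogRankResult | None
    risk_labels: pd.Series | None
    wilcoxon: dict[str, RankSumResult]
    scores: pd.Series

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.univariate.items():
            rows.append(
                {
                    "variable": name,
                    "analysis": "univariate",
                    "hr": fit.hr.iloc[0],
                    "p": fit.wald_p.iloc[0],
                    "c_index": self.univariate_c[name],
                }
            )
        for name in self.multivariate.beta.index:
            rows.append(
                {
                    "variable": name,
                    "analysis": "multivariate",
                    "hr": self.multivariate.hr[name],
                    "p": self.multivariate.wald_p[name],
                    "c_index": np.nan,
                }
            )
        out = pd.DataFrame(rows)
        out.attrs["c_index_with"] = self.c_index_with
        out.attrs["c_index_without"] = self.c_index_without
        if self.logrank is not None:
            out.attrs["logrank_p"] = self.logrank.p
        return out


def evaluate_model(
    model: SignatureModel,
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    clinical_covariates: list[str],
    cohort: str = "",
) -> EvaluationReport:
    """Run the full evaluation battery for one cohort.

    Backward selection starts from the univariate-significant covariates plus
    the score, repeatedly dropping the least significant covariate at
    p >= 0.05; the score is exempt from elimination so its multivariate
    hazard ratio is always reported.  The with/without C-index pair is
    computed on the identical patient set.
    """
    scores = score_patients(model, expr, clinical)
    work = clinical.copy()
    work["score"] = scores.to_numpy()

    univariate: dict[str, CoxFit] = {}
    univariate_c: dict[str, float] = {}
    for name in [*clinical_covariates, "score"]:
        fit = fit_cox(work, [name])
        univariate[name] = fit
        univariate_c[name] = harrell_c(fit.linear_predictor(work), work)

    candidates = [
        c for c in clinical_covariates if univariate[c].wald_p.iloc[0] < SIGNIFICANCE
    ]
    if not candidates:
        logger.warning("evaluate_model: no univariate-significant covariates; score-only model")
    current = [*candidates, "score"]
    while True:
        fit = fit_cox(work, current)
        removable = [c for c in current if c != "score"]
        if not removable:
            break
        worst = max(removable, key=lambda c: fit.wald_p[c])
        if fit.wald_p[worst] >= SIGNIFICANCE:
            current.remove(worst)
        else:
            break
    final = fit_cox(work, current)

    c_with = harrell_c(final.linear_predictor(work), work)
    without = [c for c in current if c != "score"]
    if without:
        fit_wo = fit_cox(work, without)
        c_without = harrell_c(fit_wo.linear_predictor(work), work)
    else:
        c_without = 0.5
    # paired comparison by construction: both C-indices use `work` in full
    assert len(work) == len(clinical)

    km_curves = logrank = risk_labels = None
    if model.cutoff_fraction is not None:
        risk_labels = transfer_cutoff(model.cutoff_fraction, scores)
        km_curves, logrank = km_logrank(work, risk_labels.to_numpy())

    wilcoxon: dict[str, RankSumResult] = {}
    for name in clinical_covariates:
        col = work[name]
        if set(col.dropna().unique()) <= {0, 1, True, False}:
            pos = work.loc[col.astype(bool), "score"]
            neg = work.loc[~col.astype(bool), "score"]
            if len(pos) and len(neg):
                wilcoxon[name] = wilcoxon_ranksum(pos, neg)

    return EvaluationReport(
        cohort=cohort,
        univariate=univariate,
        univariate_c=univariate_c,
        multivariate=final,
        selected_covariates=[c for c in current if c != "score"],
        c_index_with=c_with,
        c_index_without=c_without,
        km_curves=km_curves,
        logrank=logrank,
        risk_labels=risk_labels,
        wilcoxon=wilcoxon,
        scores=scores,
    )
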