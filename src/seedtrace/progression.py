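"""Monotone progression-gene selection and the per-patient progression score.

A gene is progression-associated when it changes strongly, significantly and
in the *same* direction across both disease transitions: adjacent normal (AN)
to primary tumour (CAN), and CAN to lymph-node metastasis (MET).  The
progression score of a sample is the log2 of the summed expression of the
selected panel — low scores mean the panel (typically downregulated genes) has
collapsed, i.e. more advanced disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_prep import ExpressionMatrix, match_panel_genes

logger = logging.getLogger(__name__)


@dataclass
class GenePanel:
    """Ordered gene list with per-gene direction ('up' or 'down')."""

    gene_ids: list[str]
    directions: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = set(self.directions.values()) - {"up", "down"}
        if bad:
            raise ValueError(f"invalid directions: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "direction": [self.directions.get(g, "") for g in self.gene_ids],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, provenance: str = "") -> "GenePanel":
        table = pd.read_csv(path, sep="\t")
        return cls(
            gene_ids=list(table["gene_id"]),
            directions={
                r.gene_id: r.direction for r in table.itertuples() if isinstance(r.direction, str) and r.direction
            },
            provenance=provenance or str(path),
        )


def select_monotone(
    de_an_can: pd.DataFrame,
    de_can_met: pd.DataFrame,
    lfc_thresh: float = 2.0,
    fdr_thresh: float = 0.05,
) -> GenePanel:
    """Select genes monotonely deregulated across AN→CAN and CAN→MET.

    Keeps a gene iff |log2fc| >= ``lfc_thresh`` (inclusive) and fdr <
    ``fdr_thresh`` in *both* contrasts with the same fold-change sign.  Both
    DE tables must share a gene universe.
    """
    shared = de_an_can.index.intersection(de_can_met.index)
    if len(shared) == 0:
        if len(de_an_can) == 0 or len(de_can_met) == 0:
            return GenePanel(gene_ids=[], provenance="select_monotone (empty input)")
        raise ValueError("DE tables share no genes")
    a = de_an_can.loc[shared]
    b = de_can_met.loc[shared]
    keep = (
        (a["log2fc"].abs() >= lfc_thresh)
        & (b["log2fc"].abs() >= lfc_thresh)
        & (a["fdr"] < fdr_thresh)
        & (b["fdr"] < fdr_thresh)
        & (np.sign(a["log2fc"]) == np.sign(b["log2fc"]))
        & (a["log2fc"] != 0)
    )
    genes = list(shared[keep])
    directions = {g: ("up" if a.loc[g, "log2fc"] > 0 else "down") for g in genes}
    n_up = sum(1 for d in directions.values() if d == "up")
    logger.info(
        "select_monotone: %d genes (%d up, %d down) at |lfc|>=%g, fdr<%g",
        len(genes), n_up, len(genes) - n_up, lfc_thresh, fdr_thresh,
    )
    return GenePanel(gene_ids=genes, directions=directions, provenance="select_monotone")


def progression_score(
    expr: ExpressionMatrix,
    panel: GenePanel,
    pseudocount: float = 1.0,
    aggregate: str = "sum",
) -> pd.Series:
    """Per-sample progression score: log2(aggregate of panel-gene expression + pseudocount).

    The aggregate is a plain sum by default (``mean`` available).  Panel genes
    missing from the cohort are dropped with a logged coverage fraction; a
    cohort with no panel genes at all is an error.
    """
    matched, coverage = match_panel_genes(panel.gene_ids, expr)
    if not matched:
        raise ValueError("no panel genes present in the expression matrix")
    if coverage < 1:
        logger.warning("progression_score: panel coverage %.1f%%", 100 * coverage)
    sub = expr.data.loc[matched]
    agg = sub.sum(axis=0) if aggregate == "sum" else sub.mean(axis=0)
    scores = np.log2(agg + pseudocount)
    scores.name = "progression_score"
    return scores


def patient_scores(scores: pd.Series, annotation: pd.DataFrame) -> pd.Series:
    """Collapse sample-level scores to patients (mean over a patient's samples)."""
    patient = annotation.set_index("sample_id")["patient_id"]
    return scores.groupby(patient.loc[scores.index]).mean()


def compare_score_groups(
    scores: pd.Series, groups: pd.Series | dict
) -> pd.DataFrame:
    """Welch two-sided t-test for every pair of score groups."""
    groups = pd.Series(groups)
    labels = list(pd.unique(groups.loc[scores.index]))
    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            x = scores[groups.loc[scores.index] == g1]
            y = scores[groups.loc[scores.index] == g2]
            if len(x) < 2 or len(y) < 2:
                raise ValueError(f"group {g1!r} or {g2!r} has fewer than two samples")
            t, p = stats.ttest_ind(x, y, equal_var=False)
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "mean1": x.mean(),
                    "mean2": y.mean(),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)
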