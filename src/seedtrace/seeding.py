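"""Seeding-focus identification for multifocal patients.

A patient with two or more primary tumour foci (CAN) and at least one matched
lymph-node metastasis (MET) is eligible.  For each K in ``k_list`` the
patient's CAN and MET samples are clustered hierarchically on the top-K most
variable transcripts; the metastasis's partner is the CAN sample in the
smallest dendrogram cluster containing the MET that holds at least one CAN.
The call is *resolved* only when every K (and every MET sample) points at the
same single focus — the stringent-agreement criterion; otherwise it is
*unresolved*, which is the expected outcome under polyclonal seeding or when
foci are exchangeable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from . import diffexpr
from .io_prep import ExpressionMatrix
from .progression import GenePanel

logger = logging.getLogger(__name__)

DEFAULT_K_LIST = (500, 100, 50)


def top_variable(expr: ExpressionMatrix, k: int) -> list[str]:
    """The k genes with the largest variance across samples.

    Ties are broken by gene-id lexical order so the selection is reproducible.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > expr.shape[0]:
        raise ValueError(f"k={k} exceeds the {expr.shape[0]} genes available")
    var = expr.data.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:k]


@dataclass
class Dendrogram:
    """Agglomerative clustering result over samples (scipy linkage encoding)."""

    labels: list[str]
    merge: np.ndarray  # scipy linkage matrix
    distance: str
    method: str

    def to_newick(self) -> str:
        tree = to_tree(self.merge)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            bl_l = node.dist - left.dist
            bl_r = node.dist - right.dist
            return f"({render(left)}:{bl_l:.6g},{render(right)}:{bl_r:.6g})"

        return render(tree) + ";"


def _distance_matrix(values: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return pdist(values)
    if distance == "pearson":
        corr = np.corrcoef(values)
        return squareform(1.0 - corr, checks=False)
    raise ValueError(f"unknown distance {distance!r}")


def hcluster(
    expr: ExpressionMatrix,
    distance: str = "euclidean",
    method: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of samples on log2 expression.

    Defaults (Euclidean distance, complete linkage) follow the common heatmap
    convention.  Deterministic: scipy's linkage resolves equal-distance merges
    by the lower cluster index.
    """
    if expr.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    values = expr.data.to_numpy(dtype=float).T  # samples x genes
    if method == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    merge = linkage(_distance_matrix(values, distance), method=method)
    return Dendrogram(labels=expr.sample_ids, merge=merge, distance=distance, method=method)


def _met_partner(dend: Dendrogram, met_label: str, can_labels: set[str]) -> str | None:
    """The unique CAN in the smallest cluster containing ``met_label`` and >= 1 CAN.

    Returns None when that cluster holds several CANs (no unique partner).
    """
    n = len(dend.labels)
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    parent: dict[int, int] = {}
    for k, (a, b, _h, _c) in enumerate(dend.merge):
        node = n + k
        members[node] = members[int(a)] | members[int(b)]
        parent[int(a)] = node
        parent[int(b)] = node
    can_idx = {i for i, lab in enumerate(dend.labels) if lab in can_labels}
    node = dend.labels.index(met_label)
    while node in parent:
        node = parent[node]
        hit = members[node] & can_idx
        if hit:
            if len(hit) == 1:
                return dend.labels[next(iter(hit))]
            return None
    return None


@dataclass
class SeedingCall:
    """Per-patient seeding-focus call with the per-K support trail."""

    patient_id: str
    status: str  # resolved | unresolved | ineligible
    seeding_focus: str | None = None
    support: dict[int, str | None] = field(default_factory=dict)


def call_seeding_focus(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    patient_id: str,
    k_list: tuple[int, ...] = DEFAULT_K_LIST,
    distance: str = "euclidean",
    method: str = "complete",
    cohort_variance: bool = False,
) -> SeedingCall:
    """Call the metastasis-seeding focus for one patient.

    Requires log2-scale expression.  Variance ranking uses the patient's own
    CAN+MET samples by default (``cohort_variance=True`` ranks on all samples
    in the matrix instead).  Resolved iff every K and every MET sample agree on
    one focus.
    """
    if expr.unit not in ("log2fpkm", "log2counts"):
        raise ValueError("call_seeding_focus expects log2-scale expression")
    ann = annotation.set_index("sample_id")
    mine = ann[ann["patient_id"] == patient_id]
    can_samples = list(mine.index[mine["tissue_type"] == "CAN"])
    met_samples = list(mine.index[mine["tissue_type"] == "MET"])
    if len(can_samples) < 2 or len(met_samples) < 1:
        return SeedingCall(patient_id=patient_id, status="ineligible")

    sub = expr.subset_samples(can_samples + met_samples)
    rank_source = expr if cohort_variance else sub
    support: dict[int, str | None] = {}
    for k in k_list:
        k_eff = min(k, rank_source.shape[0])
        genes = top_variable(rank_source, k_eff)
        dend = hcluster(sub.subset_genes(genes), distance=distance, method=method)
        partners = {
            _met_partner(dend, met, set(can_samples)) for met in met_samples
        }
        support[k] = partners.pop() if len(partners) == 1 else None

    partners = set(support.values())
    if len(partners) == 1 and None not in partners:
        sample = next(iter(partners))
        focus = str(ann.loc[sample, "focus_label"]) or sample
        return SeedingCall(
            patient_id=patient_id, status="resolved", seeding_focus=focus, support=support
        )
    return SeedingCall(patient_id=patient_id, status="unresolved", support=support)


def call_all_patients(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    **kwargs,
) -> list[SeedingCall]:
    return [
        call_seeding_focus(expr, annotation, pid, **kwargs)
        for pid in annotation["patient_id"].unique()
    ]


def seeding_calls_table(calls: list[SeedingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in calls],
            "status": [c.status for c in calls],
            "seeding_focus": [c.seeding_focus or "" for c in calls],
            "support": [
                ";".join(f"{k}:{v or 'ambiguous'}" for k, v in c.support.items())
                for c in calls
            ],
        }
    )


def seeding_de(
    counts: ExpressionMatrix,
    seeding_samples: list[str],
    non_seeding_samples: list[str],
    fdr_panel: float = 0.01,
    fdr_broad: float = 0.05,
) -> tuple[pd.DataFrame, GenePanel, GenePanel]:
    """Differential expression of seeding vs non-seeding foci.

    Returns the DE table plus the broad (fdr < ``fdr_broad``) and strict
    (fdr < ``fdr_panel``) gene panels; the strict panel nests inside the broad
    one by construction.  Fold changes are seeding over non-seeding.
    """
    if not seeding_samples or not non_seeding_samples:
        raise ValueError("both focus groups must be nonempty")
    if fdr_panel > fdr_broad:
        raise ValueError("fdr_panel must not exceed fdr_broad")
    sub = counts.subset_samples(non_seeding_samples + seeding_samples)
    groups = pd.Series(
        {s: "non_seeding" for s in non_seeding_samples} | {s: "seeding" for s in seeding_samples}
    )
    table = diffexpr.nb_exact_test(sub, groups, contrast=("non_seeding", "seeding"))

    def panel(threshold: float, name: str) -> GenePanel:
        hits = table[table["fdr"] < threshold]
        return GenePanel(
            gene_ids=list(hits.index),
            directions={g: ("up" if hits.loc[g, "log2fc"] > 0 else "down") for g in hits.index},
            provenance=f"seeding_de fdr<{threshold} ({name})",
        )

    broad = panel(fdr_broad, "broad")
    strict = panel(fdr_panel, "strict")
    logger.info("seeding_de: broad panel %d genes, strict panel %d genes", len(broad), len(strict))
    return table, broad, strict
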