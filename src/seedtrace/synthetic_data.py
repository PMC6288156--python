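"""Synthetic multifocal prostate-cancer datasets with known ground truth.

Two generators:

``gen_multifocal_counts``
    A discovery-style cohort: per patient, distant/proximal adjacent-normal
    samples (DAN/PAN), one or more primary tumour foci (CAN), lymph-node
    metastases (MET) and optionally non-malignant lymph-node tissue (LYMPH).
    Counts are negative binomial with variance mu + alpha * mu**2.  Three
    planted signals carry the ground truth:

    * *monotone progression genes* — mean multiplied by ``2**monotone_lfc`` in
      CAN relative to adjacent normal, and by the same factor again in MET
      relative to CAN;
    * *seeding genes* — shifted by ``2**seeding_lfc`` in one designated CAN
      focus per patient (the seeding focus) and in that patient's MET samples,
      so the metastasis shares the shift with exactly one focus;
    * *clone markers* — each CAN focus carries its own private set of strongly
      deregulated genes, and the MET inherits the seeding focus's set.  This
      reproduces the empirical pattern that tissue types cluster together
      cohort-wide (tissue shifts are shared across patients) while within a
      patient the metastasis sits transcriptionally closest to the focus that
      seeded it.

``gen_survival_cohort``
    A validation-style radical-prostatectomy cohort: lognormal expression, BCR
    times from an exponential-baseline proportional-hazards model on a gene
    panel, independent exponential censoring tuned to a target rate, and
    clinicopathological covariates (PSA, Gleason group, stage, margin, nodal
    status) optionally tied to the hazard.

The default multifocal design is the ten-patient discovery layout (per-patient
DAN/PAN/CAN/MET/LYMPH sample counts summing to 10/13/23/9/2 = 57 samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io_prep import ExpressionMatrix

#: Per-patient sample design of the ten-patient discovery cohort.
DISCOVERY_DESIGN = {
    "DAN": [1, 1, 1, 1, 1, 1, 1, 0, 1, 2],
    "PAN": [1, 1, 1, 2, 1, 1, 1, 0, 1, 4],
    "CAN": [2, 1, 2, 1, 3, 1, 3, 2, 4, 4],
    "MET": [1, 1, 1, 3, 1, 1, 1, 0, 0, 0],
    "LYMPH": [0, 1, 0, 1, 0, 0, 0, 0, 0, 0],
}


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Stated world for the multifocal count generator.

    ``nb_dispersion`` is the NB alpha (variance = mu + alpha mu^2); 0.1 is a
    typical bulk RNA-seq value.  ``monotone_lfc`` / ``seeding_lfc`` are log2
    shifts per transition; both default negative because progression-associated
    transcripts were predominantly downregulated.
    """

    n_patients: int = 10
    dan_per_patient: list[int] = field(default_factory=lambda: list(DISCOVERY_DESIGN["DAN"]))
    pan_per_patient: list[int] = field(default_factory=lambda: list(DISCOVERY_DESIGN["PAN"]))
    can_per_patient: list[int] = field(default_factory=lambda: list(DISCOVERY_DESIGN["CAN"]))
    met_per_patient: list[int] = field(default_factory=lambda: list(DISCOVERY_DESIGN["MET"]))
    lymph_per_patient: list[int] = field(default_factory=lambda: list(DISCOVERY_DESIGN["LYMPH"]))
    n_genes: int = 20000
    n_monotone_genes: int = 50
    monotone_lfc: float = -3.0
    n_seeding_genes: int = 20
    seeding_lfc: float = -2.0
    n_clone_genes: int = 300
    clone_lfc_range: tuple[float, float] = (1.0, 3.0)
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    baseline_log2_sd: float = 1.5
    library_size_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0:
            raise InvalidConfigError("need at least one patient and one gene")
        for name in ("dan", "pan", "can", "met", "lymph"):
            lst = getattr(self, f"{name}_per_patient")
            if len(lst) != self.n_patients:
                raise InvalidConfigError(
                    f"{name}_per_patient has {len(lst)} entries for {self.n_patients} patients"
                )
            if any(v < 0 for v in lst):
                raise InvalidConfigError("sample counts must be non-negative")
        if self.n_monotone_genes + self.n_seeding_genes > self.n_genes:
            raise InvalidConfigError("more planted genes than genes")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("library_size_range must be positive and ordered")


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    monotone_gene_ids: list[str] = field(default_factory=list)
    seeding_gene_ids: list[str] = field(default_factory=list)
    seeding_focus_per_patient: dict[str, str] = field(default_factory=dict)
    clone_marker_genes: dict[str, list[str]] = field(default_factory=dict)
    library_factors: pd.Series | None = None
    true_beta: dict[str, float] = field(default_factory=dict)
    linear_predictor: pd.Series | None = None


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def gen_multifocal_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a multifocal discovery cohort; deterministic under the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]

    base_log2 = rng.normal(np.log2(config.baseline_mean), config.baseline_log2_sd, g)

    perm = rng.permutation(g)
    monotone_idx = perm[: config.n_monotone_genes]
    seeding_idx = perm[config.n_monotone_genes : config.n_monotone_genes + config.n_seeding_genes]
    background_idx = perm[config.n_monotone_genes + config.n_seeding_genes :]

    lymph_effect = np.zeros(g)
    lymph_effect[rng.choice(background_idx, size=min(200, len(background_idx)), replace=False)] = (
        rng.normal(0.0, 2.0, min(200, len(background_idx)))
    )

    truth = GroundTruth(
        monotone_gene_ids=[gene_ids[i] for i in monotone_idx],
        seeding_gene_ids=[gene_ids[i] for i in seeding_idx],
    )

    lo, hi = config.library_size_range
    columns: dict[str, np.ndarray] = {}
    rows = []
    for p in range(config.n_patients):
        pid = f"PT{p + 1}"
        n_can = config.can_per_patient[p]
        n_met = config.met_per_patient[p]

        # focus-private clone markers; the MET inherits the seeding focus's set
        clone_effects = {}
        for f in range(n_can):
            focus = f"CAN{f + 1}"
            if config.n_clone_genes and len(background_idx):
                idx = rng.choice(background_idx, size=min(config.n_clone_genes, len(background_idx)), replace=False)
                eff = np.zeros(g)
                eff[idx] = rng.uniform(*config.clone_lfc_range, size=len(idx)) * rng.choice(
                    [-1.0, 1.0], size=len(idx)
                )
                clone_effects[focus] = eff
                truth.clone_marker_genes[f"{pid}:{focus}"] = [gene_ids[i] for i in idx]
            else:
                clone_effects[focus] = np.zeros(g)

        seeding_focus = None
        if n_can >= 1 and n_met >= 1:
            seeding_focus = f"CAN{rng.integers(n_can) + 1}"
            truth.seeding_focus_per_patient[pid] = seeding_focus

        def add_sample(sample_id: str, tissue: str, focus: str | None, log2_mean: np.ndarray):
            factor = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            mu = (2.0**log2_mean) * factor
            columns[sample_id] = _nb_draw(rng, mu, config.nb_dispersion)
            rows.append(
                {
                    "sample_id": sample_id,
                    "patient_id": pid,
                    "tissue_type": tissue,
                    "focus_label": focus if focus else "",
                    "qc_pass": True,
                }
            )
            if truth.library_factors is None:
                truth.library_factors = pd.Series(dtype=float)
            truth.library_factors[sample_id] = factor

        for i in range(config.dan_per_patient[p]):
            add_sample(f"{pid}_DAN{i + 1}", "DAN", None, base_log2)
        for i in range(config.pan_per_patient[p]):
            add_sample(f"{pid}_PAN{i + 1}", "PAN", None, base_log2)
        for f in range(n_can):
            focus = f"CAN{f + 1}"
            lm = base_log2.copy()
            lm[monotone_idx] += config.monotone_lfc
            lm += clone_effects[focus]
            if focus == seeding_focus:
                lm[seeding_idx] += config.seeding_lfc
            add_sample(f"{pid}_{focus}", "CAN", focus, lm)
        for i in range(n_met):
            lm = base_log2.copy()
            lm[monotone_idx] += 2 * config.monotone_lfc
            if seeding_focus is not None:
                lm += clone_effects[seeding_focus]
                lm[seeding_idx] += config.seeding_lfc
            add_sample(f"{pid}_MET{i + 1}", "MET", None, lm)
        for i in range(config.lymph_per_patient[p]):
            add_sample(f"{pid}_LYMPH{i + 1}", "LYMPH", None, base_log2 + lymph_effect)

    data = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"), dtype=float)
    annotation = pd.DataFrame(rows)
    return ExpressionMatrix(data=data, unit="counts"), annotation, truth


def gen_survival_cohort(
    n_patients: int,
    panel: list[str],
    beta: dict[str, float],
    censoring_rate: float = 0.3,
    seed: int = 0,
    n_background_genes: int = 200,
    baseline_hazard: float = np.log(2) / 1000.0,
    expr_log2_sd: float = 1.0,
    covariate_association: float = 0.5,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a radical-prostatectomy validation cohort with BCR follow-up.

    Expression is lognormal (gene-level log2 values gaussian); the BCR hazard
    is ``baseline_hazard * exp(sum_g beta_g * (x_g - mean_g))`` on centred log2
    expression.  Censoring is independent exponential, its rate solved
    numerically so the expected censored fraction equals ``censoring_rate``.
    ``covariate_association`` scales how strongly PSA/Gleason/stage track the
    linear predictor (0 makes them pure noise).
    """
    if n_patients < 20:
        raise InvalidConfigError("survival cohorts need n_patients >= 20")
    if not 0 <= censoring_rate < 1:
        raise InvalidConfigError("censoring_rate must lie in [0, 1)")
    bad = set(beta) - set(panel)
    if bad:
        raise InvalidConfigError(f"beta refers to genes outside the panel: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    genes = list(panel) + [f"BG{i:04d}" for i in range(n_background_genes)]
    gene_means = rng.normal(5.0, 2.0, len(genes))
    log2_x = gene_means[:, None] + rng.normal(0.0, expr_log2_sd, (len(genes), n_patients))
    patient_ids = [f"P{i + 1:04d}" for i in range(n_patients)]
    data = pd.DataFrame(
        2.0**log2_x, index=pd.Index(genes, name="gene_id"), columns=patient_ids
    )

    beta_vec = np.array([beta.get(gid, 0.0) for gid in genes])
    eta = (log2_x - gene_means[:, None]).T @ beta_vec
    lam = baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / lam)

    if censoring_rate == 0:
        time = event_time
        event = np.ones(n_patients, dtype=bool)
    else:
        def mean_censored(log_c: float) -> float:
            c = np.exp(log_c)
            return float(np.mean(c / (c + lam))) - censoring_rate

        log_c = brentq(mean_censored, np.log(baseline_hazard) - 20, np.log(baseline_hazard) + 20)
        censor_time = rng.exponential(np.exp(-log_c), n_patients)
        event = event_time <= censor_time
        time = np.minimum(event_time, censor_time)
    if not event.any():
        raise InvalidConfigError("configuration produced an all-censored cohort")

    a = covariate_association
    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "time": np.maximum(time, 0.5),
            "event": event,
            "psa": np.exp(rng.normal(2.3 + a * eta, 0.6)),
            "gleason_gt7": rng.random(n_patients) < expit(-0.5 + a * eta),
            "stage_pt3": rng.random(n_patients) < expit(0.0 + a * eta),
            "margin_pos": rng.random(n_patients) < 0.3,
            "nodal_pos": rng.random(n_patients) < 0.1,
        }
    )
    truth = GroundTruth(
        true_beta=dict(beta),
        linear_predictor=pd.Series(eta, index=patient_ids),
    )
    return ExpressionMatrix(data=data, unit="fpkm"), clinical, truth
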