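"""End-to-end orchestration: simulate/prep -> DE -> progression -> seeding -> model -> validate.

``run_pipeline`` executes the stages in dependency order against either a
simulated discovery cohort (the default) or user-supplied TSV inputs, writes
every stage output under the run directory, and records a manifest with a
SHA-256 hash of each output file plus a full parameter echo — re-running with
the same config and seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diffexpr, io_prep, progression, seeding, signature_eval, synthetic_data

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "prep", "de", "progression", "seeding", "build-model", "validate")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Parameters for one pipeline run; see docs for the YAML layout."""

    out_dir: str = "seedtrace_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # simulate
    sim: dict = field(default_factory=dict)
    survival_n_patients: int = 300
    survival_censoring_rate: float = 0.5
    survival_effect: float = 0.25  # per-gene |beta| used to plant prognostic signal
    # optional external inputs (skip `simulate` to use them)
    expression_path: str | None = None
    annotation_path: str | None = None
    # thresholds
    lfc_thresh: float = 2.0
    fdr_thresh: float = 0.05
    fdr_panel: float = 0.01
    fdr_broad: float = 0.05
    k_list: list[int] = field(default_factory=lambda: list(seeding.DEFAULT_K_LIST))
    cutoff_grid: list[float] = field(default_factory=lambda: list(signature_eval.DEFAULT_CUTOFF_GRID))

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        for path in (self.expression_path, self.annotation_path):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"input path does not exist: {path}")
        if "simulate" not in self.stages and (
            self.expression_path is None or self.annotation_path is None
        ):
            raise PipelineError("without the simulate stage, expression/annotation paths are required")
        if not (0 < self.fdr_panel <= self.fdr_broad < 1):
            raise PipelineError("need 0 < fdr_panel <= fdr_broad < 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "files": {},
    }

    def record(stage: str, name: str, path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(name)

    expr = annotation = truth = None
    try:
        if "simulate" in config.stages:
            sim_cfg = synthetic_data.SimulationConfig(**{**config.sim, "seed": config.seed})
            expr, annotation, truth = synthetic_data.gen_multifocal_counts(sim_cfg)
            io_prep.write_expression(expr, out / "counts.tsv")
            io_prep.write_annotation(annotation, out / "annotation.tsv")
            truth_table = pd.DataFrame(
                {
                    "kind": ["monotone"] * len(truth.monotone_gene_ids)
                    + ["seeding"] * len(truth.seeding_gene_ids),
                    "gene_id": truth.monotone_gene_ids + truth.seeding_gene_ids,
                }
            )
            truth_table.to_csv(out / "ground_truth_genes.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "patient_id": list(truth.seeding_focus_per_patient),
                    "seeding_focus": list(truth.seeding_focus_per_patient.values()),
                }
            ).to_csv(out / "ground_truth_seeding_foci.tsv", sep="\t", index=False)
            record("simulate", "counts", out / "counts.tsv")
            record("simulate", "annotation", out / "annotation.tsv")
            record("simulate", "ground_truth", out / "ground_truth_genes.tsv")
            record("simulate", "ground_truth_foci", out / "ground_truth_seeding_foci.tsv")
        else:
            expr = io_prep.read_expression(config.expression_path, unit="counts")
            annotation = io_prep.read_annotation(config.annotation_path)

        if "prep" in config.stages:
            annotation = io_prep.qc_filter(annotation)
            annotation = io_prep.collapse_an(annotation)
            expr = expr.subset_samples(list(annotation["sample_id"]))
            io_prep.write_annotation(annotation, out / "annotation_prepped.tsv")
            record("prep", "annotation_prepped", out / "annotation_prepped.tsv")

        groups = annotation.set_index("sample_id")["tissue_type"]
        de_tables = {}
        if "de" in config.stages:
            for contrast in (("AN", "CAN"), ("CAN", "MET")):
                res = diffexpr.run_de(expr, groups, contrast)
                name = f"de_{contrast[0]}_{contrast[1]}".lower()
                diffexpr.write_de_table(res.table, out / f"{name}.tsv")
                de_tables[contrast] = res.table
                record("de", name, out / f"{name}.tsv")

        panel = None
        if "progression" in config.stages:
            if not de_tables:
                raise PipelineError("progression stage requires the de stage")
            panel = progression.select_monotone(
                de_tables[("AN", "CAN")],
                de_tables[("CAN", "MET")],
                lfc_thresh=config.lfc_thresh,
                fdr_thresh=config.fdr_thresh,
            )
            panel.write(out / "progression_panel.tsv")
            record("progression", "panel", out / "progression_panel.tsv")
            if len(panel):
                scores = progression.progression_score(expr, panel)
                scores.to_frame().to_csv(out / "progression_scores.tsv", sep="\t")
                record("progression", "scores", out / "progression_scores.tsv")
                comparisons = progression.compare_score_groups(scores, groups)
                comparisons.to_csv(out / "progression_group_tests.tsv", sep="\t", index=False)
                record("progression", "group_tests", out / "progression_group_tests.tsv")

        seeding_panel = None
        if "seeding" in config.stages:
            log2 = diffexpr.normalized_log2(expr)
            calls = seeding.call_all_patients(
                log2, annotation, k_list=tuple(config.k_list)
            )
            table = seeding.seeding_calls_table(calls)
            table.to_csv(out / "seeding_calls.tsv", sep="\t", index=False)
            record("seeding", "calls", out / "seeding_calls.tsv")
            resolved = [c for c in calls if c.status == "resolved"]
            if resolved:
                ann = annotation.set_index("sample_id")
                seed_samples, nonseed_samples = [], []
                for call in resolved:
                    mine = ann[(ann["patient_id"] == call.patient_id) & (ann["tissue_type"] == "CAN")]
                    for sid, row in mine.iterrows():
                        (seed_samples if row["focus_label"] == call.seeding_focus else nonseed_samples).append(sid)
                de_table, broad, strict = seeding.seeding_de(
                    expr, seed_samples, nonseed_samples,
                    fdr_panel=config.fdr_panel, fdr_broad=config.fdr_broad,
                )
                diffexpr.write_de_table(de_table, out / "seeding_de.tsv")
                broad.write(out / "seeding_panel_broad.tsv")
                strict.write(out / "seeding_panel_strict.tsv")
                record("seeding", "de", out / "seeding_de.tsv")
                record("seeding", "panel_broad", out / "seeding_panel_broad.tsv")
                record("seeding", "panel_strict", out / "seeding_panel_strict.tsv")
                seeding_panel = strict

        if "build-model" in config.stages or "validate" in config.stages:
            active = panel if panel is not None and len(panel) else seeding_panel
            if active is None or not len(active):
                logger.warning("no nonempty panel available; skipping model stages")
            else:
                beta = {
                    g: (config.survival_effect if active.directions.get(g) == "up" else -config.survival_effect)
                    for g in active.gene_ids
                }
                vexpr, vclin, _vtruth = synthetic_data.gen_survival_cohort(
                    n_patients=config.survival_n_patients,
                    panel=active.gene_ids,
                    beta=beta,
                    censoring_rate=config.survival_censoring_rate,
                    seed=config.seed + 1,
                )
                io_prep.write_expression(vexpr, out / "validation_expression.tsv")
                io_prep.write_clinical(vclin, out / "validation_clinical.tsv")
                record("build-model", "validation_expression", out / "validation_expression.tsv")
                record("build-model", "validation_clinical", out / "validation_clinical.tsv")
                model = signature_eval.fit_weighted_model(
                    vexpr, active, vclin, reference_cohort="synthetic-reference"
                )
                scores = signature_eval.score_patients(model, vexpr, vclin)
                frac, _p = signature_eval.choose_cutoff_fraction(
                    scores, vclin, grid=tuple(config.cutoff_grid)
                )
                model.cutoff_fraction = frac
                model.to_json(out / "signature_model.json")
                record("build-model", "model", out / "signature_model.json")

                if "validate" in config.stages:
                    report = signature_eval.evaluate_model(
                        model, vexpr, vclin,
                        clinical_covariates=["psa", "gleason_gt7", "stage_pt3", "margin_pos"],
                        cohort="synthetic-reference",
                    )
                    summary = report.summary()
                    summary.to_csv(out / "evaluation_summary.tsv", sep="\t", index=False)
                    record("validate", "evaluation", out / "evaluation_summary.tsv")
                    extras = {
                        "c_index_with": report.c_index_with,
                        "c_index_without": report.c_index_without,
                        "logrank_p": report.logrank.p if report.logrank else None,
                        "cutoff_fraction": frac,
                    }
                    (out / "evaluation_extras.json").write_text(json.dumps(extras, indent=2))
                    record("validate", "evaluation_extras", out / "evaluation_extras.json")
    except PipelineError:
        raise
    except Exception as exc:  # halt with the failing stage named; partial outputs remain
        done = list(manifest["stages"])
        raise PipelineError(f"pipeline failed after stages {done}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
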