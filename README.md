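# seedtrace

Analysis pipeline for **multifocal prostate cancer transcriptomes with matched
lymph-node metastases**: it discovers genes deregulated along the progression
from adjacent-normal tissue (AN) through the primary tumour focus (CAN) to the
metastasis (MET), infers which primary focus most likely *seeded* the
metastasis, and builds Cox-weighted gene-expression signatures whose prognostic
value against biochemical recurrence (BCR) is evaluated with cutoff transfer
across cohorts. A synthetic-data module generates multifocal count matrices
and survival cohorts with known ground truth, so the entire pipeline is
testable without any download.

Intended users: computational biologists working on prognostic expression
signatures and tumour clonality, who need an auditable, fully scripted version
of this class of analysis.

## The statistics at the core

* **Differential expression on counts.** Negative-binomial model with variance
  μ + αμ²; TMM normalisation; dispersion α by conditional likelihood (common +
  moderated per-gene); a conditional exact test of equal group means given the
  gene total; Benjamini–Hochberg FDR.
* **Progression panel.** A gene enters the panel iff |log2FC| ≥ 2 with
  FDR < 0.05 *in the same direction* in both AN→CAN and CAN→MET. The
  per-sample progression score is log2(Σ panel expression + 1).
* **Seeding-focus call.** Per eligible patient (≥ 2 CAN foci, ≥ 1 MET),
  hierarchical clustering (Euclidean, complete linkage) of the patient's
  CAN+MET samples on the top-K variable transcripts for K ∈ {500, 100, 50};
  the call is resolved only if every K (and every MET) pairs the metastasis
  with the same single focus. Seeding vs non-seeding foci are then contrasted
  with the count pipeline (panels at FDR < 0.05 and FDR < 0.01).
* **Weighted signatures.** Panel genes jointly in a multivariate Cox model
  (Newton–Raphson on the partial likelihood, Efron ties); patient score
  = linear predictor / fitting-cohort SD; high-risk = top `cutoff_fraction`
  by score, the fraction chosen in a reference cohort and transferred as a
  quantile. Evaluation: uni/multivariate Cox with stepwise backward selection,
  Harrell's C with and without the score, Kaplan–Meier + log-rank, Wilcoxon
  against clinicopathological variables.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from seedtrace import synthetic_data as sd, diffexpr, io_prep, progression, seeding
from seedtrace import signature_eval as se

cfg = sd.SimulationConfig(n_genes=1000, n_clone_genes=150, seed=42)
expr, ann, truth = sd.gen_multifocal_counts(cfg)
ann = io_prep.collapse_an(io_prep.qc_filter(ann))
groups = ann.set_index("sample_id")["tissue_type"]

de_an_can = diffexpr.run_de(expr, groups, ("AN", "CAN")).table
de_can_met = diffexpr.run_de(expr, groups, ("CAN", "MET")).table
panel = progression.select_monotone(de_an_can, de_can_met)

call = seeding.call_seeding_focus(diffexpr.normalized_log2(expr), ann, "PT5")

beta = {g: -0.25 for g in panel.gene_ids}
vexpr, vclin, _ = sd.gen_survival_cohort(300, panel.gene_ids, beta,
                                         censoring_rate=0.5, seed=43)
model = se.fit_weighted_model(vexpr, panel, vclin, reference_cohort="demo")
scores = se.score_patients(model, vexpr, vclin)
model.cutoff_fraction, _ = se.choose_cutoff_fraction(scores, vclin)
report = se.evaluate_model(model, vexpr, vclin,
                           ["psa", "gleason_gt7", "stage_pt3", "margin_pos"])
```

Output of this exact script:

```
panel size: 49 | planted genes recovered: 49 / 50
mean progression score by tissue: {'AN': 13.04, 'CAN': 9.93, 'MET': 7.04}
PT5 seeding call: resolved CAN1 | truth: CAN1
score univariate HR 8.47 (6.39-11.23), p 6.6e-50
C-index with score 0.876, without 0.500
cutoff fraction 0.25, KM log-rank p 5.8e-55
```

Reading it: 49 of the 50 planted monotone genes are selected (no false
positives); the progression score falls monotonically from adjacent normal to
metastasis; the planted seeding focus of patient PT5 is recovered at all three
K values; and in an independent survival cohort whose hazard was driven by the
panel, the standardised signature score has a hazard ratio of 8.5 per score SD
and lifts the concordance index from 0.5 (no informative covariates) to 0.88.
The log-rank p accompanies an exploratory cutoff choice and is optimistic by
construction.

The same flow is available from the shell:

```bash
seedtrace run --out demo_run --seed 1        # full pipeline + manifest.json
seedtrace simulate --out sim --seed 1        # just the synthetic cohort
seedtrace de --expr sim/counts.tsv --annotation sim/annotation.tsv \
             --contrast AN:CAN --out de_an_can.tsv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This re-runs the full pipeline from scratch on synthetic cohorts derived from
the given seed — simulation, preparation, both differential contrasts,
progression-panel selection, seeding calls and differential expression,
signature fitting, cutoff choice and evaluation — and writes the results JSON
to `--out`.
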