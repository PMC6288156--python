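# Methods

`seedtrace` implements a transcriptome analysis for multifocal,
hormone-naive prostate cancer with matched lymph-node metastases: discovery of
progression-associated genes, identification of the metastasis-seeding tumour
focus within a patient, and construction/evaluation of Cox-weighted prognostic
expression signatures against biochemical recurrence (BCR). This note records
the models, the defaults and why, what the synthetic generators do and do not
emulate, and the numerically delicate choices.

## Data model

Samples carry one of five tissue labels: DAN (benign epithelium > 3 mm from
the nearest tumour focus), PAN (benign epithelium < 1 mm), CAN (a primary
tumour focus), MET (lymph-node metastasis) and LYMPH (non-malignant lymph
node). DAN and PAN expression profiles are nearly indistinguishable in
practice, so `io_prep.collapse_an` merges them into a single adjacent-normal
(AN) group before differential analysis; the operation is idempotent.

Expression travels as a genes × samples matrix of raw counts or FPKM
(`ExpressionMatrix`, TSV on disk). Clinical tables carry `time` (days to BCR
or last PSA test), `event` (BCR occurred) and the routine covariates: PSA
(ng/mL), Gleason group (> 7 vs ≤ 7), stage (pT3 vs pT2), surgical margin and
nodal status.

## Differential expression (counts)

The count model is negative binomial with variance μ + αμ²; α is the
dispersion.

* **Normalisation.** Trimmed mean of M-values (30% M-trim, 5% A-trim,
  delta-method weights) against the sample whose upper quartile is closest to
  the cohort mean. `norm_factors` returns library size × TMM factor rescaled
  to geometric mean 1 — the total per-sample scale a count column is divided
  by. Counts divided by these factors ("pseudo-counts", continuous) live on a
  common effective library size.
* **Dispersion.** Estimated by *conditional* likelihood on the equalised
  pseudo-counts: conditioning each group's counts on their sum removes the
  group mean from the likelihood, avoiding the downward bias of plug-in mean
  estimates. A common value is profiled over a log-spaced grid and refined;
  per-gene values maximise the gene's own conditional likelihood plus
  (prior df / residual df) × the genewise-average likelihood, shrinking noisy
  per-gene estimates toward the common value. Prior df defaults to 10.
* **Exact test.** For two groups with equalised libraries, group sums are
  NB(nᵢμ, α/nᵢ); conditioning on the total gives a mean-free split
  distribution. The two-sided p-value is the total conditional probability of
  splits no more likely than the observed one (a 1 + 1e−10 relative tolerance
  guards the equal-probability boundary). As α → 0 this converges to the
  binomial split test. All-zero genes get p = 1, log2FC = 0 by convention.
* **Fold change.** log2 of the ratio of group mean pseudo-counts with a prior
  count of 0.125 added to each mean. 0.125 is the convention of the standard
  count-DE tool; larger priors visibly compress fold changes of low-abundance
  transcripts, which matters because the progression rule thresholds |log2FC|.
* **Multiplicity.** Benjamini–Hochberg step-up (via statsmodels).
* A Welch t-test on log2 values (`welch_log_de`) is provided for FPKM-only
  cohorts where no raw counts exist.

## Progression model

A gene is *monotone progression-associated* if, in both the AN→CAN and
CAN→MET contrasts, |log2FC| ≥ 2 (inclusive) with FDR < 0.05 and the same
sign. The inclusive-≥, log2-scale reading of the threshold is a choice; the
alternative readings are not distinguishable from the source description.
The per-sample progression score is log2(Σ panel-gene expression +
pseudocount 1) — a plain sum, deliberately unweighted, so cohorts on
different platforms only need the gene subset they measure (coverage is
logged). Group comparisons use two-sided Welch t-tests.

## Seeding-focus calls

Eligibility: ≥ 2 CAN foci and ≥ 1 MET sample. For each K ∈ {500, 100, 50}
the patient's CAN+MET samples are clustered (complete linkage, Euclidean
distance on normalisation-corrected log2 counts; `1 − Pearson` and
average/Ward linkage are available) on the K most variable transcripts,
variance taken across the patient's own samples (a cohort-wide option
exists). The metastasis's partner is the CAN in the smallest dendrogram
cluster that contains the MET and at least one CAN; if that cluster holds
more than one CAN there is no unique partner and the K-level vote is
ambiguous. A call is **resolved** only when all K values and all MET samples
agree on a single focus — the operationalisation of "stringent clustering
criteria". Unresolved is a first-class outcome: it is what polyclonal seeding
or exchangeable foci should produce.

Two numerical details matter. Clustering must use depth-corrected log2
counts: raw library-size differences act as per-sample global offsets that
dominate Euclidean distances. And K is an absolute gene count calibrated to a
> 20,000-transcript assay; on a heavily down-sampled matrix K = 500 stops
being a "top variance" quantile.

Seeding differential expression contrasts the resolved seeding foci against
the non-seeding foci with the count pipeline above; the broad panel is
FDR < 0.05, the strict panel FDR < 0.01 (nested by construction).

## Survival statistics

Written in-package rather than delegated, so every quantity is auditable
against a brute-force oracle in the tests (lifelines is used in tests as an
independent cross-check only):

* **Cox proportional hazards** by Newton–Raphson on the partial likelihood,
  Efron tie correction by default (Breslow optional), covariates centred for
  numerical stability, step-halving, convergence at max |score| < 1e−8 or 50
  iterations. Monotone likelihoods (complete separation) and divergent
  coefficients (|β| > 15) are flagged `converged=False` instead of raising.
  Wald standard errors come from the observed information; an optional L2
  penalty (`ridge`) handles collinear panels.
* **Kaplan–Meier / log-rank**: product-limit estimator; k-sample
  observed-vs-expected chi-square with hypergeometric variance.
* **Harrell's C**: pairs are usable when the shorter time had an event; score
  ties count 0.5.
* **Wilcoxon rank-sum**: exact distribution for combined n ≤ 20 without
  ties, normal approximation with tie correction otherwise (scipy).

## Weighted signatures and evaluation

Panel genes are entered jointly into a multivariate Cox regression on log2
expression; the raw score is the linear predictor and the reported score
divides by the fitting cohort's raw-score SD, so hazard ratios are per score
SD and the fitting cohort has score SD exactly 1. Weights are refit in each
scored cohort — reproducing the source design — but this is *optimistic*:
for honest external validation, freeze a fitted `SignatureModel` (JSON) and
score a new cohort with it.

Risk groups: the top `cutoff_fraction` of patients by score are high-risk.
The fraction is chosen in a reference cohort by scanning 0.25–0.75 in steps
of 0.05 for the smallest log-rank p — an exploratory choice whose winning
p-value must not be quoted as confirmatory — and then transferred to other
cohorts as the same quantile, making the split invariant to monotone score
transformations.

`evaluate_model` runs: univariate Cox per covariate and for the score;
multivariate Cox seeded with the univariate-significant covariates
(p < 0.05) plus the score, pruned by stepwise backward elimination of the
least significant covariate at p ≥ 0.05 (the score is exempt so its
multivariate effect is always reported); Harrell's C for the final model with
and without the score on the identical patient set; Kaplan–Meier with
log-rank on transferred risk groups; and Wilcoxon of the score against each
binary covariate.

## Synthetic data: what it emulates, what it does not

`gen_multifocal_counts` reproduces the ten-patient discovery layout
(10 DAN, 13 PAN, 23 CAN, 9 MET, 2 LYMPH = 57 samples after QC; per-patient
design configurable). Counts are NB with α = 0.1, gene baselines lognormal
around 100 counts (log2 SD 1.5), library factors log-uniform on (0.5, 2) and
recorded in the ground truth. Three planted structures:

1. **Monotone genes** (default 50 at log2FC −3 per transition): mean × 2⁻³
   in CAN vs AN and again in MET vs CAN.
2. **Seeding genes** (default 20 at log2FC −2): shifted in exactly one
   designated CAN focus per patient and in that patient's MET samples.
3. **Clone markers** (300 genes per focus, |log2 effect| ~ U(1, 3), random
   sign): each focus's private transcriptional identity; the MET inherits the
   seeding focus's marker set. This is the package's own minimal model of
   intra-patient focus correlation — no quantitative model exists in the
   source — and it is what makes two empirical observations hold
   simultaneously in simulation: cohort-wide, tissue types cluster together
   (tissue shifts are shared across patients, so they dominate cohort-wide
   variance), while within a patient the MET sits closest to the focus that
   seeded it.

Not emulated: FFPE RNA degradation and mapping-rate artefacts, fusion
transcripts, allele-level clonality, intra-focus heterogeneity, and any
DAN-vs-PAN field effect (the two groups are generated identically). A green
recovery test therefore establishes that the pipeline finds the planted
structure under NB noise at realistic depth — not that it would survive
FFPE-grade degradation.

`gen_survival_cohort` draws lognormal expression, BCR times from an
exponential-baseline proportional-hazards model on centred log2 panel
expression, and independent exponential censoring whose rate is solved
numerically to hit the requested censored fraction in expectation. PSA,
Gleason and stage can be tied to the linear predictor through
`covariate_association` (0 = pure noise). Null calibration of the weighted
score is only meaningful with frozen weights scored on an independent
cohort: refitting weights inside the scored cohort makes the score's
univariate p anti-conservative by construction.

## Degenerate inputs and tie-breaking

Duplicate gene/sample ids, negative values and non-finite entries are
rejected at matrix construction. Top-variance ties break by gene-id lexical
order; equal-height dendrogram merges follow scipy's lower-index rule; risk
cutoff score ties break by patient id with a logged warning. Constant-count
matrices push the dispersion to its lower bound (1e−6) without crashing;
all-zero genes test at p = 1.

## Known limitations

The exact test assumes equalised libraries after TMM; extreme composition
bias outside the trimmed range will leak into fold changes. The dispersion
moderation weight (prior df 10) is a convention, not estimated from data.
Backward selection and cutoff-fraction scanning are both exploratory
procedures reproduced for fidelity; neither yields honest confirmatory
p-values, and the README and this note say so wherever they surface.
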