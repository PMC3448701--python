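# Methods

## Model and procedure

The screen treats each gene (probeset) independently as a candidate
covariate in a proportional-hazards model
h(t | x) = h0(t) · exp(β x), where x is the gene's log-scale expression
and t is right-censored follow-up time. The partial likelihood is
maximized with the Efron approximation for tied event times — the default
of `coxph` in the R survival package, so single fits agree with R to
machine precision — and the reported p is the two-sided Wald test
p = 2·Φ(−|β̂|/se(β̂)). The Wald p was preferred over the likelihood-ratio
p because it is the per-coefficient p printed in the standard `coxph`
summary table; both are asymptotically equivalent for the single-covariate
fits used here, and at the subsample sizes the package targets (≥ ~100
patients, ≥ ~50 events) their rejection rates at the 0.01 screening cutoff
are indistinguishable (both within half a percent of nominal in null
simulations).

One screening run consists of R resampling rounds (default 400; selection
counts typically saturate by ~200). Each round draws ⌊f·n⌋ patients
(f = 0.75) uniformly **without replacement within the round**; rounds are
independent draws, since hundreds of pairwise-disjoint 75% subsets cannot
exist. A gene is positive in a round when its fit converged and p < 0.01.
The selection statistic is the positive frequency over **all** rounds
(non-converged fits count as negatives, not missing, keeping frequencies
comparable across genes); genes at or above the frequency cutoff (default
0.75) are selected. A run is fully reproducible from its seed; subset
size ⌊f·n⌋ is deterministic by construction.

Per-round hold-out validation refits each round's positives on that
round's untouched 25%. An attempt passes when the hold-out Wald p < 0.05
**and** the hold-out coefficient keeps the screening-round sign — without
the sign condition, an effect that flips direction could "validate".
Hold-out sets with fewer than two events are skipped and not counted.
The aggregate pass rate is reported separately for all screening hits and
for selected genes; a selective screen shows a clear gap between the two.

## What resampling does and does not remove

Resampling dilutes *split-specific* overfitting: a gene that passes only
because of which patients landed in one training set will not pass in
most other subsamples. It does **not** remove *cohort-level* chance
association: a null gene that happens to correlate with survival in the
one observed cohort is "really" associated in every subsample of that
cohort and accumulates high frequency like a true positive. With G
independent null genes the smallest full-cohort p is of order 1/G, and a
gene with full-cohort |z| ≳ 3.4 passes the 0.01 cutoff in ≥ 75% of 75%
subsamples, so at G = 1000 roughly one null gene per cohort clears the
75% frequency filter in expectation (confirmed by simulation: mean ≈ 0.9
selected nulls per cohort at n = 150, 100 rounds). This is why the
per-round hold-out validation and, above all, replication across
independent cohorts (the overlap compilation) remain essential; frequency
filtering alone cannot certify a gene.

For the same reason the mean per-gene positive frequency on a null cohort
is compared to the nominal 0.01 using the empirical standard error over
independently generated cohorts, not a binomial one: within one cohort
the per-gene frequencies are strongly dependent (shared patients, shared
survival realization), and the binomial G·R-denominator SE would be
dishonestly small.

## Clustering and the "core" signature

Selected genes are clustered on d = 1 − ρ_Spearman (midranks for ties;
no centering or re-weighting of genes or arrays) with average (UPGMA)
linkage via scipy; a naive O(n³) reference implementation is kept in the
test suite as an independent oracle. The "center of the cluster" — in
practice picked by eye from a heatmap — is formalized as: among all
dendrogram subtrees with ≥ `min_size` leaves (default 10) whose members
all carry one prognostic direction, the largest whose mean pairwise
Spearman ρ is ≥ `min_mean_rho` (default 0.5), at most one per direction,
ties broken by higher mean ρ then earlier merge. The formalization is
deterministic; users who prefer manual selection can pass any gene list
directly to the signature stage. Dendrograms export to Cluster
3.0-compatible `.cdt`/`.gtr` text and JSON.

## Scoring and stratification

Signature genes are normalized per gene by median centering and division
by the raw MAD (median |x − median|, **without** the 1.4826 normality
factor — the factor cancels from MAD-based rankings and would only
rescale scores; omitting it keeps the arithmetic exactly reproducible).
The score is the plain sum over good-prognosis genes minus the sum over
poor-prognosis genes; a `mean` flag divides each sum by its list size for
unbalanced signatures. Normalization makes the score invariant to
per-gene positive affine transforms of the raw data and antisymmetric
under swapping the two lists.

Patients are split by 1-D k-means (k = 2, 10 seeded restarts); for
one-dimensional data the best-of-restarts solution coincides with the
optimal single-threshold split, which the test suite verifies against an
exhaustive scan. The split is evaluated with the two-group log-rank test,
Kaplan–Meier curves with Greenwood confidence bands (lifelines), and a
univariate Cox fit on the group indicator (hazard ratio of high vs low);
when a group has zero events the curves are still returned but the tests
are flagged unreliable.

## Enrichment conventions

Fisher's exact test is two-sided by the point-probability criterion (the
R `fisher.test` convention; one-sided available by flag), with the list
tested against the background universe − list. Fold is the percentage of
set members in the list over that in the background, +∞ when the set is
absent from the background, flagged degenerate when the set misses the
universe entirely. Per-chromosome tests report raw p and a Bonferroni
correction across chromosomes (clearly labeled; the raw p is what a
single-hypothesis reading would use). The universe is whatever gene set
the caller passes — normally the post-MAD-filter screen universe.

Copy-number calls on the rescaled log2 axis (−1/0/0.585 anchoring
1N/2N/3N): deletion below −1.5, copy loss below −0.7, otherwise normal;
"below" is strict, so values exactly at a threshold take the less-severe
call.

## Synthetic cohorts

`simulate_cohort` draws, per sample, one standard-normal latent factor
z_k per module; a module gene is loading·z_k + noise (Gaussian,
sd `noise_sd`), null genes are pure noise, and every gene gets a
N(8, 0.5) baseline so files look like RMA output (location is irrelevant
to Cox, ranks and MAD). Event times are exponential with rate
h0·exp(Σ_k β_k z_k [+ β_sex·male]), censoring is uniform on
(0, c_max) — chosen over Weibull alternatives for closed-form control of
the event fraction. Defaults (n = 200, one 50-gene module, loading 0.8 so
module genes have unit variance with noise_sd 0.6, |log-HR| 0.7 per
factor SD, h0 = 0.1, c_max = 20 giving ~55–60% events) describe a
mid-sized, mature single-disease cohort with a moderately strong
prognostic program. The sex scenario adds a few Y-chromosome genes
expressed only in males (bimodal, gap 3 log units) with survival driven
by sex itself.

The chromosome-dosage scenario plants a single-copy loss of one
chromosome in a fraction of patients (default 0.3): that chromosome's
genes become dosage-sensitive — expression = baseline − 0.5·loss + tight
residual noise (sd 0.2, giving an expression/copy-state correlation of
~0.77, typical of cis-dosage-responsive genes on arrays; with ordinary
gene-level noise of 0.6 the per-gene marginal effect would be ~0.12
log-HR per SD and undetectable at any realistic cohort size) — and
carriers' log hazard rises by 0.6. The default base cohort emulates an
aggressive-tumor setting: 188 patients, light censoring (~85% events),
screened at the 50% frequency cutoff appropriate for such cohorts.
Matching log2 copy-number values are emitted at the −1/0 anchors with
sd-0.1 noise.

What the generator does *not* emulate: probe-level and batch effects,
heavy-tailed or count noise, correlated censoring, clinical covariates,
competing risks, and module structure richer than single shared factors.
Passing recovery tests therefore demonstrate correctness of the
machinery under the assumed model, not performance on any real cohort.

## Numerical choices

- Batched Newton–Raphson for the univariate Cox fits: all genes are
  updated simultaneously from shared risk-set cumulative sums; covariates
  are centered per gene (the MLE is translation-invariant and the
  centered exponentials are well conditioned); steps are halved (≤ 12
  times) whenever the partial likelihood would decrease; convergence at
  |Δβ| ≤ 1e−9·(1+|β|), cap 40 iterations. Monotone likelihoods (perfectly
  concordant covariates) are detected by coefficient runaway
  (|β|·sd(x) > 100) and flagged non-converged with p = 1 — such genes
  count as screening negatives rather than spuriously significant.
- MAD variance filter keeps exactly ⌈(1−f)·G⌉ genes; ties at the cutoff
  are broken by input order (earlier row wins) for determinism.
- Duplicate gene ids in input files are an error by default (distinct
  probesets carry distinct ids); an opt-in policy collapses duplicates by
  keeping the max-MAD row. Missing values error by default, with opt-in
  per-gene mean imputation.
- Modal direction over a gene's positive rounds is "poor"/"good", "mixed"
  on an exact tie (such genes are excluded from signature construction),
  and "none" for genes never positive.

## Problem sizes in tests and the acceptance script

The shipped suites run screening at 1000–1050 genes × 150–200 patients ×
100 rounds (10 cohorts for the null-calibration check, one for recovery),
saturation at 200 rounds, and the dosage scenario at ~1040 genes × 188
patients; these sizes give stable estimates of the screen's operating
characteristics while keeping a full run to a couple of minutes on one
CPU. Oracle equivalences use exhaustive or naive references at small n
(≤ 12 genes for clustering, ≤ 200-margin tables for Fisher).

## Known limitations

Univariate screening only (no adjustment for clinical covariates, no
time-dependent effects, no competing risks); gene-axis clustering only
(sample ordering in exports is input order); identifier matching in the
overlap compilation is exact, with probeset→symbol mapping left to the
caller; the copy-number utilities assume the −1/0/0.585 rescaling has
already been performed with reference segments identified upstream.
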