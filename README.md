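# scor

Resampling-stabilized survival screening of gene-expression features
(SCoR: **S**urvival analysis using **Co**x regression and **R**andom
resampling).

## The problem

Single-split survival screens of microarray or RNA-seq cohorts are
notoriously unstable: the list of "prognostic genes" changes drastically
with the choice of training samples, and published signatures for the same
disease barely overlap. `scor` implements a screening procedure that
attacks this instability directly: instead of one Cox regression per gene
on one training set, each gene is tested on hundreds of random
subsamples of the cohort, and genes are ranked by how *consistently* they
pass — split-specific false positives are diluted across rounds while
genes with a stable association accumulate selection frequency. The
selected genes are then clustered to expose tight co-expressed blocks
(the biologically interpretable "core" of the signal), turned into a
multi-gene risk score, and tested for gene-set and chromosome enrichment.

It is aimed at computational biologists analyzing genes × samples
expression matrices with right-censored clinical follow-up (breast
cancer, glioblastoma, lung adenocarcinoma cohorts and the like).

## The method

For each resampling round *r* = 1…*R* (default *R* = 400, typically
saturating by ~200):

1. draw ⌊0.75·*n*⌋ patients uniformly without replacement;
2. for every gene *g*, fit the univariate Cox model
   *h*(*t* | *x*<sub>*g*</sub>) = *h*₀(*t*)·exp(*β*<sub>*g*</sub> *x*<sub>*g*</sub>)
   on the subsample (Efron tie handling, Newton–Raphson, all genes fit
   simultaneously by a vectorized solver);
3. mark *g* positive in round *r* if the two-sided Wald *p* < 0.01.

A gene's **selection frequency** is its positive fraction over all
rounds; genes with frequency ≥ 0.75 are selected. Each round's positives
are also refit on that round's held-out 25% (a pass needs *p* < 0.05 with
the same coefficient sign), giving an internal validation rate that is
markedly higher for selected genes than for the run-of-the-mill screening
hits.

Selected genes are clustered on 1 − Spearman ρ with average (UPGMA)
linkage, and the **core cluster** — the largest single-direction subtree
with mean pairwise ρ above a threshold — becomes the signature. Patients
are scored with

&nbsp;&nbsp;&nbsp;&nbsp;Multi-Gene Score = ∑ᵢ x̃ᵢ − ∑ⱼ x̃ⱼ,

summing median-centered, MAD-scaled expression over good-prognosis genes
*i* minus poor-prognosis genes *j*, split into high/low groups by 1-D
k-means (k = 2), and compared by log-rank test, Kaplan–Meier curves and a
Cox fit on the group label. Enrichment of a gene set in a candidate list
uses Fisher's exact test with fold = (% of set in list) / (% of set in
background).

A synthetic-cohort generator (`scor.simulate`) produces expression
matrices with planted correlated modules driving an exponential
proportional-hazards outcome under uniform censoring, plus sex-linked and
chromosome-dosage scenarios, so every stage is testable against known
ground truth. The package also ships a machine-readable compilation of 85
prognostic genes recurrently selected across eight public breast-cancer
cohorts (GSE1456, GSE2034, GSE2990, GSE3494, GSE7390, GSE11121, GSE12093,
NKI-295), 58 of them cell-division/proliferation genes.

## Worked example

```python
import scor

# generate a cohort: one 50-gene poor-prognosis module over 1000 null genes
cohort = scor.simulate_cohort(scor.SimConfig(
    n_samples=200, n_null_genes=1000,
    modules=[scor.ModuleSpec(size=50, latent_loading=0.8,
                             direction="poor", log_hazard_ratio_per_sd=0.7)],
    seed=11,
))

# resampled Cox screen with per-round hold-out validation
cfg = scor.ScorConfig(rounds=100, rng_seed=11)
result = scor.run_scor(cohort.expression, cohort.survival, cfg)
summary = scor.internal_validation(cohort.expression, cohort.survival, result)

# cluster the selected genes and extract the core signature
sub = cohort.expression.subset_genes(result.selected_genes)
dend = scor.average_linkage(scor.spearman_dissimilarity(sub), result.selected_genes)
core = scor.extract_core_cluster(dend, sub, result.directions())[0]

# score and stratify patients with the core signature
sig = scor.Signature(good_genes=[], poor_genes=core.gene_ids)
scores = scor.multi_gene_score(cohort.expression, sig)
groups = scor.kmeans_stratify(scores, seed=11)
strat = scor.evaluate_stratification(groups, cohort.survival)
```

prints (via the obvious `print` statements):

```
selected 50 genes; 50/50 from the planted module
hold-out validation: 67% of all hits, 78% of selected genes
core cluster: 50 poor-prognosis genes, mean pairwise Spearman rho = 0.59
high vs low score: HR = 0.31, log-rank p = 1.29e-09
```

All 50 planted genes — and no null genes — clear the 75% frequency
filter; the hold-out validation rate is higher for selected genes than
for screening hits at large; and the core-signature score splits the
cohort into groups with clearly different survival (the high-score group
is protective, HR < 1, because the signature contains only poor-prognosis
genes, so a high score means low module expression).

The same workflow is available from the shell:

```sh
scor simulate --n-samples 200 --null-genes 1000 --module 50,0.8,poor,0.7 \
     --seed 11 --out cohort/
scor pipeline --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
     --rounds 100 --seed 11 --out run/
```

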