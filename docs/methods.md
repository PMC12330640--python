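# Methods

This note documents the models, defaults and numerical choices behind
`ithkit`, and what the synthetic cohorts do and do not establish about real
data.

## Discovery model

The pipeline assumes each sample (a cell line or tumor) contains discrete
subpopulations over-expressing coherent gene programs, and that biologically
meaningful programs recur — across factorisation ranks within a sample and
across samples of a cohort.

1. **Normalisation.** Counts per cell are scaled to 10,000 and transformed
   with log2(x+1). The scheme is the standard single-cell convention and is
   configurable; within-cell ranks are preserved, all-zero genes stay zero.
2. **Gene filtering.** Within each sample, genes detected in fewer than 2%
   of cells are dropped before factorisation (configurable, logged). Genes
   with zero within-sample variance are also removed — they cannot load on
   any factor.
3. **Centering and clipping.** Each gene is centered on its mean across the
   sample's cells and negative residuals are set to zero, so NMF sees
   above-average *relative* expression only. Centering defaults to
   per-sample (the factorisation is per sample); a global option exists for
   pooled-cohort scoring. Scoring, by contrast, uses the signed centered
   values without clipping, because the background comparison is two-sided
   around each gene's mean.
4. **NMF.** scikit-learn's coordinate-descent solver with Frobenius loss,
   `nndsvd` initialisation (deterministic — reproducibility was preferred
   over the small bias a deterministic start can introduce), tol 1e-4,
   max_iter 500. Non-convergence at max_iter is logged with the achieved
   residual and the factors are still used: module extraction needs the
   ranking of top loadings, which stabilises long before the objective
   bottoms out. Ranks default to 6–9 → 30 modules per sample; each module
   is a factor's top-50 genes (ties broken by gene id). Both counts are
   configurable and recorded in run manifests.

## Module filter

Overlap between two equal-sized modules is the shared-gene fraction
|A∩B|/50, deliberately distinct from the Jaccard index used for clustering.
Defaults: a module must share ≥ 0.7 with a module of the same sample at a
different rank (robustness); within a sample, modules overlapping a kept
module > 0.8 are greedily collapsed, keeping the module with more rank
supporters (ties broken by rank/factor order); retained modules must share
≥ 0.2 with a module of another surviving sample (recurrence), iterated to a
fixpoint. Two details make the filter idempotent, which would not hold for
a naive three-pass reading: retained modules carry their recorded
supporter count (so a collapse survivor does not lose its evidence on
re-filtering), and the recurrence step iterates until stable (so no module
is kept on the strength of a partner that itself gets dropped).

The thresholds are calibrated to a ~2,000-gene expressed-universe with
50-gene modules. On much smaller universes the 0.2 recurrence gate weakens
— deterministic NMF noise factors concentrate on the same high-variance
genes across samples and can slip through as spurious consensus clusters.
Raise `cross_min_overlap` (or work at the default gene scale) in that case.

## Clustering and signatures

Average-linkage hierarchical clustering on 1 − Jaccard, tree cut at
distance 0.9 by default; an explicit cluster-count override reproduces
fixed-count behaviour. Clusters below 2 members are discarded and logged.
Programs are numbered by descending size with deterministic tie-breaks.
Signature genes are those present in ≥ 25% of member modules — the
threshold is inclusive, so a gene in exactly 1 of 4 members qualifies.

## Scoring

Backgrounds are built by ranking genes on mean expression over the scored
cells, splitting them into 30 near-equal bins, and drawing, for each of the
1,000 background sets, one gene from the bin of each signature gene.
Backgrounds may contain repeats when bins collide; their means remain
well-defined. The empirical p uses an add-one correction with ≥ counting,
p = (count≥ + 1)/(N + 1): the uncorrected "proportion of backgrounds above
the signature" yields p = 0 (and an undefined −log10) whenever a cell beats
all backgrounds, while the corrected form is a valid permutation p-value
with a floor of 1/(N+1). Scores are −log10(p) min-max rescaled to [0, 1]
per program across all scored cells; an alternative fixed rescale by the
attainable maximum −log10(1/(N+1)) is available via config (`rescale="pmin"`).
When every cell scores identically the rescale is degenerate; scores are
defined as 0 with a warning.

The bulk rank score is the mean gene percentile (rank − 0.5)/G over
signature genes, with average ranks on ties — the unidirectional core of
the singscore approach, without its bidirectional dispersion component.

## Annotation

The observed statistic is the Jaccard index between a program signature and
each reference meta-program, computed on the full gene sets as given;
restricting sets to the expression matrix applies only to the score
correlation (which needs expression values), so matrix content cannot
inflate the set similarity. The null draws size-matched random gene sets
from the expressed-gene universe and records each draw's best Jaccard over
the whole catalogue; the significance threshold is the nearest-rank
quantile at the configured confidence (default 0.999). With 100
permutations that quantile is the sample maximum — the tool warns and
recommends ≥ 1,000 draws. An alternative interpretation of the null
(shuffling gene–program assignments) can be selected via `perm_mode` in the
CLI config. Pearson is the default score correlation; Spearman is
available. The null RNG is a dedicated child stream of the user seed so
that sibling components seeded with the same integer cannot replay the
null draws.

## Phenotype association

A sample is "enriched" in a program when at least one of its retained
modules belongs to that program's cluster; an alternative score-based rule
(assign each sample to its highest-mean-score program) is provided.
Incidence tables are compared with the two-sided Fisher exact test under
the point-probability convention (sum over all fixed-margin tables whose
probability does not exceed the observed one); a zero margin returns p = 1
with a warning. Quantile stratification uses nearest-rank cutoffs with
boundary ties included on the high/low side, giving reproducible integer
group sizes.

## Drug screen

Pearson correlation between biomarker expression and per-compound AUC on
pairwise-complete lines, requiring ≥ 20 complete pairs per compound
(mirroring common practice for screens with missingness); two-sided p from
the t transform with n − 2 df; Benjamini–Hochberg q-values over tested
compounds. Lower AUC means more sensitive, so candidate vulnerabilities of
biomarker-high lines are the most negative correlations.

## Synthetic cohorts

The generator emulates a panel of 16 cell lines × 300 cells × 2,000 genes
with 6 planted 50-gene programs. Counts are Poisson with log-normal
per-gene baselines (background genes: log-mean log 0.5, sd 0.75; program
genes drawn brighter, log-mean log 4, sd 0.3, so the planted shift is not
drowned by detection noise at low rates). Each program is expressed by a
fixed half of the samples (at least 2, guaranteeing the recurrence the
consensus step assumes); within an expressing sample each cell activates
the program independently with probability 0.3; the designated
anticorrelated pair (programs 0 and 1, standing in for hEMT/EpiSen) is
never co-active in one cell. Active cells multiply their program genes'
rates by 2^1.5 (an additive 1.5 log2-unit shift; the measured group-mean
difference on log2(1+count) lands ~10% lower due to Poisson/log
compression). Phenotypes are affine in the sample's phenotype-program
active-cell fraction plus truncated Gaussian noise on the [0, 100] % scale.
The drug screen plants hits as AUC = −effect·z(expr) + √(1−effect²)·noise,
giving exact r = −1 at effect 1 with no noise.

Not emulated: doublets, ambient RNA, batch effects, library-size gradients,
gene-gene correlation outside programs, dose–response curve shape. Passing
recovery tests therefore shows the algorithmic chain is correct under its
own assumptions, not that real cohorts of this size will yield equally
clean programs.

## Problem sizes

The test and acceptance runs use the default cohort (16 × 300 × 2,000) for
end-to-end discovery, 500 cells × 200 backgrounds for scoring calibration,
200 replicates × 1,000 permutations for annotation calibration, and
200 × 500 screens — sizes chosen so a full from-scratch run completes in a
few minutes on one CPU while every statistical check retains power.
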