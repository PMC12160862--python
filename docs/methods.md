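# Methods

This note documents the models implemented in `stromascape`, the
parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Synthetic cohort generator

The generator (`stromascape.synthetic`) emulates the structure of an
integrated multi-sample tumor scRNA-seq cohort: samples labelled
malignant or non-malignant, each containing epithelial cells, reference
(normal) epithelial cells, and two fibroblast subtypes (an
ECM-remodeling subtype and a generic one; default fractions
0.45/0.15/0.2/0.2).

Counts for cell *c*, gene *g* are negative-binomial with mean

    mu_cg = depth_c * rate_g * effects_cg,        Var = mu + a * mu^2

where `rate_g = base_mean * LogNormal(0, 0.5)` is a per-gene baseline,
`depth_c ~ LogNormal(0, 0.3)` a per-cell depth factor, and `a`
(default 0.5) the overdispersion — values in the range typical of
droplet scRNA-seq. Three kinds of multiplicative effects can be
planted, each recoverable as a ratio of group means:

- **Programs**: 50-gene modules multiplied by `effect` in a Bernoulli
  fraction of epithelial cells of the active samples.
- **CNV segments**: contiguous gene-rank intervals on one of 22
  pseudo-chromosomes (genes assigned to chromosomes in index order;
  coordinates are 0-based half-open gene ranks, since the CNV smoother
  operates on gene order, not base pairs), multiplied by `fold` in an
  affected cell set (default: epithelial cells of malignant samples).
- **Ligand-receptor axis**: the ligand in sender-type cells and every
  receptor subunit in receiver-type cells of malignant samples.
  Axis genes get their baseline pinned to `base_mean` rather than the
  log-normal draw: the axis emulates a well-expressed secreted ligand
  (POSTN-like), and pinning makes the planted effect — not the
  baseline lottery — determine the axis's expression level.

A configurable share of counts (defaults 5% / 0.5%) lands on genes
prefixed `MT-` and `HB` so the mitochondrial and hemoglobin QC filters
are exercised. Survival records are exponential,
T ~ Exp(h0 · exp(βx)), with independent exponential censoring whose
rate is matched to the cohort's mean hazard to hit a target censored
fraction approximately.

Not emulated: doublets, ambient RNA, batch effects, spatial
coordinates, gene-gene correlation beyond the planted modules, and
library-size/cell-type confounding. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
model, not robustness to every artifact of real data.

## QC and normalization

Cells are kept with 300-8,000 detected genes (count ≥ 1), UMI total
< 40,000, mitochondrial fraction < 10% and hemoglobin fraction < 1%;
samples retaining < 500 cells are dropped entirely. Each removed cell
is attributed to the first rule it violates (gene floor, gene cap, UMI
cap, mito, hemoglobin, sample size) so the QC report balances exactly.
Hemoglobin genes are matched by the `HB` prefix minus an explicit
exclusion list (HBEGF, HBS1L, HBP1).

Normalization scales each cell to 10,000 counts (the community
convention; the upstream workflow does not state a factor) followed by
log1p. HVG selection ranks genes by dispersion (variance/mean of the
normalized values) z-scored within 20 equal-occupancy mean-expression
bins, ties broken by gene name; constant genes are never selected.
These are this package's defaults, not inferences about any upstream
author's settings.

## Meta-program discovery

Per sample, the cells × genes normalized matrix is made non-negative by
centering each gene and clipping negatives to zero — so NMF factors
capture above-average co-expression — and factorized at every
K ∈ [3, 10] (scikit-learn NMF, seeded random initialization per
(sample, K), ≤ 200 iterations, tol 1e-4). Each factor keeps its top-50
genes by loading: 52 programs per sample.

Robustness selection keeps a program iff it shares ≥ 35/50 genes with a
program of a different K in the same sample (stability) and ≥ 10/50
genes with a program of ≥ 1 other sample (recurrence); within a sample,
programs sharing > 40/50 genes collapse to the most recurrent one (ties
to lower K, then factor index). The thresholds (35/10/10/2) are
exposed in `RobustnessParams` and are this package's defaults.

Retained programs are clustered by average-linkage hierarchical
clustering on 1 − Jaccard, cut at distance 0.75 (or a fixed cluster
count). Clusters need ≥ 3 members from ≥ 2 distinct samples — a
meta-program is by definition recurrent across samples. The consensus
list ranks member genes by (frequency across members, mean loading,
name) and takes 50.

Benchmark: with 5 disjoint 50-gene programs planted at effect 4 in 25%
of epithelial cells of every sample (10 samples × 500 cells, 1,500
genes, NMF on the top 1,000 HVGs), the pipeline recovers 5/5 programs
at consensus-to-truth Jaccard ≈ 0.98 in ~25 s.

## Signature scoring

`module_score` follows the binned-control convention of per-cell
signature scoring: genes are binned into 24 equal-occupancy bins of
mean expression, 100 control genes per set gene are sampled (seeded,
without replacement, set genes excluded) from the matching bins, and
the score is set mean minus pooled control mean — zero-centered for
random sets and invariant to adding a constant to every gene.

`rank_set_score` is a transparent rank-based single-sample score used
where a GSVA-style sample-wise enrichment would otherwise appear: the
set's mean rank within the subject's profile, centered at (G+1)/2 and
scaled by (G−1)/2, lying in [−1, 1] with expectation 0 and invariance
to monotone transformations. It deliberately replaces the KS-like GSVA
kernel with a simpler statistic; it is not a GSVA reimplementation.

Stratification labels subjects strictly above the median (or a chosen
percentile) as "high"; ties at the cutoff go to "low" — a
deterministic, conservative convention. All-equal scores are rejected
as a degenerate cutoff.

## CNV malignancy

The profile is a transparent reimplementation of the moving-average
core of inferCNV-style analysis (no HMM or denoising): per gene,
cell minus reference-mean log-normalized expression, clipped to ±3;
a centered moving average of 101 genes within each chromosome (window
truncated at chromosome ends, never crossing a boundary); per-cell
median recentering. Score = mean squared smoothed deviation;
threshold = empirical 90th percentile (linear interpolation) of the
reference cells' scores, with a strict `>` call — so ~10% of reference
cells exceed their own threshold by construction, which bounds the
specificity achievable on normal-like cells near 0.9.

Benchmark: fold-2 gains over three 150-gene segments carried by 30% of
epithelial cells (4 samples × 500 cells, 2,200 genes over 10
pseudo-chromosomes) give sensitivity ≈ 1.00 and specificity ≈ 0.90.

## Ligand-receptor crosstalk

The communication score replaces a Hill-function mass-action model with
the mean-product convention: mean ligand expression in the sender
cluster times the minimum over receptor subunits of the subunit mean in
the receiver cluster (the subunit minimum encodes limiting-subunit
complex formation). Significance comes from an explicit permutation
null — cluster labels permuted across cells, 1,000 permutations by
default, add-one correction so p ≥ 1/(n+1). A pair with a missing gene
scores 0 with p 1 and a flag rather than erroring, so pair tables can
be applied across datasets.

Because the score compares raw cluster means, chance cluster-level
covariates (e.g. depth composition) shift all pairs of a given cluster
coherently; the calibration benchmark therefore measures type-I error
on fully label-permuted data, the condition the permutation null
actually tests. Observed null rejection at α = 0.05 is 0.05 ± 0.01
over 500 pairs, and a planted effect-4 axis ranks first among all 180
scored (pair, sender, receiver) triples against 14 random decoy pairs.

Sample stratification by sender-derived ligand sums raw counts (the
literal reading of "summed expression") over sender-type cells per
sample and splits at the 75th percentile, strictly-above = high.

## Pseudobulk DE and enrichment

Pseudobulk sums raw counts per sample over one cell type; conservation
is exact and asserted. Gene filters drop genes with total count ≤ 1 or
detection in < 2 samples. The group test is Welch's t on log2(CPM+1)
with fold change log2((mean CPMₐ+1)/(mean CPM_b+1)) — a fully
specified substitute for a negative-binomial GLM whose thresholds
(|log2FC| ≥ 1, P < 0.05, both applied verbatim) define the DEG flag; a
Benjamini-Hochberg column is emitted for information but does not
enter the flag. Power for planted 4-fold genes at 6 vs 6 samples is
~1.0.

Preranked enrichment uses the weighted KS running sum (weight 1 on
|metric|) over genes sorted by the ranking metric (descending log2FC by
default), with a gene-permutation null (random same-size sets,
seeded): NES = ES / mean |same-sign null ES|,
p = (1 + #{same-sign null ≥ |ES|}) / (1 + #same-sign null). Gene
permutation (rather than phenotype permutation) is this package's
choice; ES is bounded in [−1, 1] by construction.

## Clinical statistics

- Composite IHC score: area bins resolved as half-open intervals
  [0,5], (5,25], (25,50], (50,75], (75,100] → 0-4 (the published bin
  labels overlap at their edges; this is the one consistent
  resolution), times intensity 0-3. Category boundaries also overlap
  in print ("low 3-6", "high ≥ 6"); a composite of 6 is assigned
  "high", matching the dichotomized high = score ≥ 6 analyses.
- Pearson chi-square without continuity correction (Yates available as
  an option, off by default). This reproduces the published
  173-patient table's p-values for age (0.357), vascular invasion
  (0.003), distant metastasis (0.002) and nervous invasion (0.421) to
  three decimals, and p < 0.001 for lymph-node metastasis and TNM
  stage. The printed tumor-differentiation p (0.006) is not reproduced
  by the uncorrected Pearson statistic on the printed 3×2 counts (it
  gives a smaller value); the variant used for that row is unstated
  upstream, so it is not part of the benchmark.
- Kaplan-Meier, log-rank and Cox PH are delegated to lifelines behind
  this module's interface. lifelines handles ties by Efron's method;
  the continuous synthetic fixtures used here have essentially no
  ties, where Efron and Breslow coincide. The log-rank statistic is
  cross-checked in the tests against a hand-computed
  observed-minus-expected oracle on a no-ties fixture. Calibration:
  null rejection ≈ 0.05-0.06 at n = 200 (the asymptotic chi-square
  reference is very slightly liberal in finite samples); the Cox 95%
  CI covers a true HR of 2 in ≈ 95% of replicates at n = 500.
- Assay formulas: tumor volume 0.5 × length × width², wound healing
  (1 − current/initial) × 100%, colony rate colonies/seeded × 100%.
  A current wound area above the initial reports negative healing with
  a warning rather than erroring.

## Benchmark sizes and determinism

All benchmark configurations (`stromascape.benchmarks`) are chosen to
give stable operating characteristics at desk scale: 10 × 500 cells
for MP recovery, 2,000 epithelial cells for the CNV classifier, 500
null pairs × 1,000 permutations for crosstalk calibration, 1,000
log-rank replicates at n = 200 and 200 Cox replicates at n = 500, and
3 pseudobulk cohorts of 12 × 150 cells. Every stochastic step takes an
explicit seed; identical configuration and seed give byte-identical
cohorts and results. Stochastic benchmark quantities (rejection rates,
coverage) carry binomial noise of about ±0.01-0.02 at these sizes.

## Known limitations

- The robustness thresholds, cluster cut and MP count are exposed
  parameters, not estimates of any published analysis's settings; on
  real cohorts they require tuning against the Jaccard heatmap.
- The CNV module is not a substitute for subclonal or allele-specific
  CNV inference; it reports a single genome-wide burden score.
- The crosstalk score inherits the magnitude-confounding of mean-
  product scores: cross-pair comparisons are only meaningful between
  genes of comparable expression scale.
- The Welch pseudobulk test loses power relative to count-model DE at
  very low counts; the gene filters mitigate but do not remove this.
- Functional annotation of meta-programs (GO/KEGG naming) is left to
  user-supplied gene sets; no live database queries are performed.
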