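# Methods

`mastsig` implements, as a reusable and tested pipeline, the derivation of
minimal cytokine-activated mast-cell gene signatures from a multi-condition
priming experiment and their application to bulk, pseudobulk and
single-cell expression data. This note records the models, the parameters
that matter, what the synthetic-data generators do and do not emulate, and
the numerical and design choices made where the design was genuinely open.

## Differential expression (`mastsig.de`)

Counts K_gj for gene g in sample j are modeled as negative binomial with
mean s_j q_gj and dispersion alpha_g, Var = mu + alpha mu^2. Size factors
s_j are median-of-ratios: the per-gene reference is the geometric mean
across samples over genes positive everywhere, and s_j is the median of
K_gj / ref_g. Per gene, a GLM with log link, log s_j offsets and a design
of condition (5 levels, unstimulated reference) plus donor (paired design
default; the donor covariate can be dropped for unpaired data) is fitted
by IRLS.

Dispersion estimation is a simplified analogue of the established bulk
workflow:

1. gene-wise Cox–Reid-adjusted profile maximum likelihood under the full
   design (bounded 1-D search over log alpha, alternated twice with the
   mean fit). Estimating under the full design keeps paired-donor
   structure out of the dispersion; a plain method-of-moments estimate on
   condition groups inflated dispersions (donor variance leaked in) and
   made the Wald test conservative, while a moments estimate on full-design
   residuals was too noisy at n = 20 and inflated type-I error to ~0.10 —
   both were measured on the null simulation and rejected in favor of the
   CR-MLE;
2. a log-linear trend of dispersion versus mean normalized expression,
   least squares over informative genes (mean > 1, estimate above the
   floor of 1e-8);
3. shrinkage of log alpha toward the trend with weight
   prior_var / (prior_var + sampling_var), sampling_var = trigamma(df/2),
   prior_var the excess spread of residuals around the trend (floored at
   0.05).

Wald statistics for a condition coefficient are referred to a
t distribution with the design's residual degrees of freedom (n − p = 12
for the 20-sample paired design) rather than a normal — a small-sample
correction for the estimated dispersion. Under the null simulation
(10^4 genes, no planted effects) this combination gives type-I error
≈ 0.045 at nominal 0.05 with near-uniform p-values; with the normal
reference it was ≈ 0.07.

Benjamini–Hochberg adjustment is step-up over the tested genes; all-zero
or non-converged genes are reported NA and excluded from the family. No
independent filtering and no log-fold-change shrinkage are applied — both
are unstated in the source design, and the minimal defensible model is
kept. Exact replication of DESeq2 (outlier replacement, independent
filtering) is out of scope; the pipeline's claims are calibration and
recovery properties, not bit-identical output.

Significant genes (q < 0.05) per cytokine-vs-unstimulated contrast are
partitioned into condition-unique (significant in exactly one condition),
shared (≥ 2) and core (all) sets; `shared_fraction` is |shared| / |union|.

## Signature selection (`mastsig.selection`)

Condition-unique DEGs are features of a multinomial elastic net over the
five condition labels. The glmnet parameterization is used: objective
(1/n) NLL + lambda [(1−alpha)/2 ||b||₂² + alpha ||b||₁], with the
published operating point alpha = 0.5, lambda = 0.007976564 as defaults,
mapped onto scikit-learn's saga solver via C = 1/(n lambda). Features are
log2 median-of-ratios-normalized counts, standardized per gene with
statistics computed on the training split only (prevents leakage; the
source procedure does not state this). The split is stratified per class:
ceil(fraction · n_c) samples to train (70/30 default ⇒ 3 of 4 per class).

A gene enters the signature of its *exclusivity class* — the condition
whose unique-DEG list contains it — if any of its class coefficients
exceeds 1e-8 in magnitude (numerical floor for coordinate-descent/saga
solutions). The elastic net only decides inclusion, never class identity,
because the feature set is restricted to genes unique to one condition.
The unstimulated class can be dropped after evaluation (`drop_classes`),
mirroring the removal of the weakest signature from downstream analyses.

Selection is *minimal* by construction: with redundant informative
markers the L1 component keeps a subset sufficient for classification.
On the default planted simulation the selected set has precision ≈ 0.94
against planted truth but recall ≈ 0.6; R glmnet run on identical input
selects essentially the same set, so this is a property of the method,
not of the solver.

Evaluation statistics are exact where the design allows: Clopper–Pearson
intervals from beta quantiles; the accuracy-vs-no-information-rate test
as the exact binomial upper tail at p0 = max class frequency; Cohen's
kappa from the confusion matrix; multiclass AUC as the Hand–Till M
(mean over unordered class pairs of the averaged conditional AUCs, ties
counted one half) plus one-vs-all AUCs, computed on class-probability
scores (whether the original evaluation used probabilities or binarized
predictions is unstated; probabilities are the default as the richer
statistic). The independent validation classifier is a small feed-forward
network (one hidden layer of 8 logistic units, lbfgs, seeded); the
validation role needs only a compact net, and the architecture is
configurable.

## GSVA engine (`mastsig.gsva`)

The enrichment score follows the published gene-set variation analysis
definition, implemented from scratch: per gene a kernel-smoothed CDF
across samples (Gaussian kernel, bandwidth sd/4, for log-scale input;
Poisson kernel with lambda = x + 0.5 for raw counts; or the plain ECDF
for a purely rank-based pipeline); per sample, genes ordered by
decreasing smoothed density with position weight |p/2 − i|; a weighted
Kolmogorov–Smirnov random walk with in-set increments w_i^tau normalized
over the set (tau = 1 default) and out-of-set increments 1/(p − |S|).
`max_diff` (default, matching the cited tool version's behavior) reports
max positive deviation + min negative deviation, bounded in [−1, 1];
`two_sided_max` reports the single largest-magnitude deviation. Ties in
the density ordering break by gene order (stable sort). The engine is
validated against an independently coded plain-loop oracle to 1e-10.
Kernel/tau/score-mode were not stated for the original analysis; defaults
follow the tool's documented defaults.

Pseudobulk aggregation sums cell counts per sample/donor; groups with
fewer than 10 cells are flagged (not dropped) because their scores are
unstable. Normalization is log2(CPM + prior), prior 1.

Group comparisons of scores use per-signature OLS plus empirical-Bayes
variance moderation: residual variances are shrunk toward a prior whose
degrees of freedom d0 and scale s0² come from a method-of-moments fit of
the scaled-F model on log variances (trigamma inversion by Newton
iteration); posterior variance (d0 s0² + df s²)/(d0 + df); moderated t
with df + d0 degrees of freedom. With only 4–5 signatures the prior is
weakly estimated — the function warns below 10 features but proceeds,
since the original analysis moderates across exactly that many rows.

Because GSVA is rank-based and per-sample, scores are *relative*:
elevating one gene block necessarily depresses the scores of other sets
in the same samples. Tests and examples account for this (a planted shift
is asserted to dominate, not to leave other sets exactly null).

## Single-cell scoring and phases (`mastsig.cells`, `mastsig.phases`)

Cells are normalized as ln(1 + count/total · 10⁴) (natural log — the
single-cell convention; bulk/pseudobulk normalization uses log2, and the
bases are deliberately documented here). A cell's signature score is the
mean normalized expression over the signature's genes; the reported
"logFC" of a score contrast is the *difference of group means*, the only
dimensionally coherent default for means of logged expression (a log2
ratio-of-means variant is not provided by default). Cluster markers use
the two-sided Wilcoxon rank-sum test, exact for tie-free comparisons with
both sides ≤ 8 cells and the tie-corrected normal approximation (no
continuity correction) otherwise; marker log2FC compares mean expm1
expression with pseudocount 1. Disease-vs-healthy score contrasts are
Welch t-tests on per-cell scores (the source wording compares "cells";
per-sample aggregation can be done upstream via pseudobulk), BH-adjusted
in one family across the full signature × disease grid.

Pseudotime analytics: "natural" binning is read as 1-D Fisher–Jenks
optimal breaks (exact dynamic program minimizing within-bin sum of
squares) since the source phrase is ambiguous; equal-width and
equal-count binning are selectable. Phases are per-trajectory tertiles at
the 1/3 and 2/3 pseudotime quantiles (by cell count, the equal-count
reading), ties toward the earlier phase; trajectories with < 3 cells or
constant pseudotime fall back to "early" with a warning. Trajectory
utilization per (trajectory, disease) is a two-sided Fisher exact test on
[[disease on/off], [healthy on/off]] with the conventional two-sided
definition (sum of table probabilities ≤ observed), healthy cells pooled
across samples; BH across all pairs. Phase-level mean scores mask groups
with fewer than 5 cells (the threshold used in the source figures);
masking is inclusive at 5 and never alters unmasked values. A complete
zero-filled (disease, trajectory, phase, cluster) contingency table
supports alluvial exports.

`centroid_mst_pseudotime` is a deliberately simple convenience for data
without trajectory output: an MST over cluster centroids, one trajectory
per root-to-leaf path, cell pseudotime = normalized projected arc
position near its cluster's segment. Cells in clusters on shared branch
segments appear in every trajectory containing their cluster. It is not a
principal-curve method and makes no attempt at curve smoothing.

## Cohort scores (`mastsig.cohort`)

For a bulk cohort, each signature gene's log-normalized expression is
standardized across *all* subjects (not within groups — unstated in the
source; across-all is the symmetric choice) using the sample (n−1)
standard deviation, appropriate for small cohorts. Subject scores are
mean z over the signature's genes; groups are compared with two-sided
Welch t-tests, and signature pairs with Spearman correlation (tie-
corrected ranks) and OLS regression. Scores are invariant to per-gene
affine rescaling by construction. The standardization input is log-scale
normalized expression (the source says "normalized counts" without a
scale; log is chosen for variance stability, and median-of-ratios
normalization is preferred over CPM because it is far more robust to the
composition shift a planted global elevation induces — CPM roughly
doubled the false-positive rate on unplanted signatures in simulation).

## Synthetic data (`mastsig.simulate`)

Generators emulate the three study designs at desk scale; all are
bit-reproducible under a seed, and every parameter is a dataclass field.

* **Bulk priming** (default 2000 genes): 4 donors × 5 conditions
  (unstim, IFNG, IL33, IL4IL13, TGFB), NB counts with baseline
  log-normal means (median ≈ 100), dispersions log-uniform on
  [0.01, 0.3] (typical bulk range), donor effects N(0, 0.2) on the
  natural-log scale shared across conditions (the paired structure),
  library factors uniform on [0.5, 2]. Planted effects: 50
  condition-unique DEGs per cytokine and 100 shared DEGs (each affected
  in a random subset of ≥ 2 cytokines), |log2FC| uniform on [1, 3] with
  random sign. These sizes keep the DEG fraction (~15%) below the real
  experiment's (~50% of expressed genes) while giving every stage
  hundreds of true positives to recover.
* **Tissue cells**: diseases split evenly; trajectory drawn per disease
  from its utilization probabilities; pseudotime uniform on [0, 1];
  cluster = trajectory × pseudotime tertile so phase analytics are
  exactly checkable; expression from per-gene log-normal relative
  abundances with per-disease additive shifts of signature-gene
  log-means, multiplied by log-normal library sizes, NB-sampled
  (dispersion 0.5) with independent Bernoulli dropout (default 0.1) —
  dropout stresses zero-count behavior without claiming to replicate any
  particular zero fraction.
* **Cohort**: 20 "high" vs 17 "low" subjects; genes = signature genes
  plus 500 background genes; the named signatures (default IL33 and
  TGFB) elevated by effect_size (default 1 log2 unit) in the high group.

What the generators do *not* emulate: batch effects, ambient RNA, UMI
chemistry, gene–gene correlation beyond the planted block structure,
mean–variance trends estimated from real data, doublets, or realistic
cluster geometry. Passing recovery tests therefore demonstrates that the
algorithms do what they claim under their own model assumptions — not
that those assumptions hold in any particular tissue dataset.

## Problem sizes and tolerances

The test suite exercises the pipeline at reduced scale chosen as
adequate for each statistical claim: null calibration on 10^4 genes
(Monte Carlo s.e. ≈ 0.002 on a 0.05 rate), selection recovery over 20
seeded replicates of the default bulk simulation, cohort power over 50
replicates at the 20/17 design, GSVA/Fisher/BH/rank-sum equivalence
against enumeration oracles on exhaustively checkable sizes (6×4
matrices, 2×2 tables with N ≤ 200, vectors ≤ 100, groups ≤ 8). Numerical
tolerances: GSVA oracle agreement 1e-10; exact statistics to printed
precision; calibration bands [0.03, 0.07] at nominal 0.05.

## Known limitations

* The Wald t-reference and CR-MLE dispersions are calibrated for the
  default paired design; very small designs (< 8 samples) remain
  anticonservative, as any plug-in dispersion method is.
* Elastic-net signatures are minimal, hence low-recall against an
  exhaustive truth list (see above); they are evaluated for
  discriminative sufficiency, not completeness.
* Library-size normalization leaves a small composition bias when a gene
  block shifts globally in one group; median-of-ratios reduces but does
  not eliminate it.
* The MST pseudotime convenience orders clusters, not cells, and should
  not substitute for principal-curve trajectory inference in real
  analyses.
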