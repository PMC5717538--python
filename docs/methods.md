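# Methods

## Data model and preprocessing

Each disease contributes one `ExpressionStudy`: a genes × samples matrix
with a *disease* arm and a *control* arm (≥ 2 samples each) and per-sample
batch labels. Probe-level matrices are collapsed to gene level with the
MaxMean rule — per gene, keep the probe with the highest mean across
samples, ties to the lexicographically smallest probe id. Multi-batch
studies are merged by restricting to the common genes and standardizing
each gene within each batch (mean 0, sd 1, n−1 denominator) before
concatenation. This is a deliberately simple, transparent stand-in for
empirical-Bayes batch correction: it removes additive per-batch offsets
exactly, which is the only batch structure the synthetic generator
produces, but it does not model batch-specific variance inflation or
gene–batch interactions the way ComBat-style methods do. Finally, every
gene row is z-transformed across all samples of the study (arms pooled)
and studies are restricted to their common gene universe, ordered
lexicographically. All downstream statistics are location-contrast based,
so pooled-arm standardization does not bias them; it only fixes scale.

## Differential gene activity

The DGA score is a regularized two-sample t. Per arm, genes are ranked by
arm mean (ties broken by gene id) and a gene's background sd σ_bg is the
mean of the per-gene sample sds over a window of `window` genes centred
on its rank (clamped at the ends so the window always spans exactly
`window` genes). The regularized variance per arm is

    σ̃² = (v0·σ_bg² + (n − 1)·s²) / (v0 + n − 1),   v0 = max(c − n, 0)

and t = (m_disease − m_control)/√(σ̃²_d/n_d + σ̃²_c/n_c). Positive scores
mean up-regulation in disease.

Defaults: `window = 101`, `confidence c = 10`. These are the customary
defaults of Bayesian-regularized t tools for microarray data; with 10 or
more samples per arm v0 = 0 and the statistic is exactly Welch's t, which
is also the tested reduction. Two deliberate choices where conventions
differ: variances are regularized **per arm** (not pooled), and the
denominator uses v0 + n − 1 pseudo-count weighting so that the v0 = 0
limit is exact — some published implementations use v0 + n − 2, which
shifts scores by a factor that is irrelevant downstream (all significance
is permutation-based and the permuted scores shift identically). If both
regularized variances vanish the score is defined as 0 and flagged. No
t-distribution p-values are attached anywhere.

## Disease similarity

Similarity between diseases i and j is the partial Pearson correlation of
their DGA columns controlling for all other diseases, computed from the
precision matrix of the disease correlation matrix:
pcor_ij = −Ω_ij/√(Ω_ii·Ω_jj). This requires more genes than diseases
(trivially true here) and a non-singular correlation matrix; duplicated
disease columns raise an explicit singularity error naming the offending
pairs. The implementation is cross-checked in the tests against the
three-variable recursion formula and a regression-residual construction.

**Permutation null.** Disease/control labels are shuffled independently
within each study (arm sizes preserved), DGA is recomputed, and all
pairwise partial correlations are pooled into a single background
distribution; 100 permutations by default. One pooled null — rather than
per-pair nulls — is used because a single background of disease
correlations is being estimated; with D diseases it holds
n_perm · D(D−1)/2 values. Pair p-values are one-sided upper tail with
add-one smoothing, p = (1 + #{null ≥ observed})/(N + 1), so p ∈ (0, 1];
the raw-count variant (which can return 0) is available via a flag.
Shuffling is within-study, so arm imbalance and study-specific structure
are preserved under the null.

**Clustering.** Diseases are clustered by complete linkage on the
distance 1 − pcor, implemented with a deterministic tie-break (exact ties
merge the lexicographically smallest cluster-id pair) and verified
against SciPy's agglomeration on tie-free inputs. The tree is cut at
h* = 1 − q where q is the (1 − α) quantile of the pooled null
correlations: subtrees entirely below h* are clusters whose internal
similarities exceed the level-α background. Singletons are reported as
unclustered (label 0).

## Network modules and activity scores

Edge lists are STRING-style (node, node, combined score). Scores on a
0–1000 scale are auto-detected (any value > 1) and divided by 1000; the
threshold filter is strict (score > 0.85 by default); duplicate
undirected edges keep the maximum score; self-loops are dropped.

MCL runs on the column-stochastic weighted adjacency with added
self-loops (weight 1): alternate expansion (matrix power, default 2) and
inflation (entrywise power, default 2.0, then column re-normalization),
pruning entries below 1e−5, until the iterate changes by less than 1e−6
or 200 iterations (non-convergence yields a warning and the last
iterate). Clusters are read from attractor rows (positive diagonal);
attractors with overlapping supports are merged, nodes covered by several
clusters go to the cluster with the largest converged weight (ties to the
lowest module id), so the output is always a partition. Inflation 2.0 and
self-loop weight 1 were chosen because planted-partition modules at
p_within/p_between ≈ 18 are recovered essentially perfectly and the
module-size spread on random graphs is broad; the method's sensitivity to
inflation is the usual MCL granularity trade-off.

Module activity of module i in disease k (PMA for protein modules, FMA
for curated functional sets — one code path) is the arithmetic mean of
the DGA scores of the module's genes inside the measured universe.
Modules are first filtered to ≥ 3 surviving genes. Significance is
two-sided via |activity| against a **matched** per-module per-disease
permutation null (same shuffles as the correlation null), because the
null spread of a mean depends strongly on module size; p-values use the
same add-one formula.

**Signature extraction** is two-step: (1) modules with p < α in strictly
more than half the diseases; (2) among those, modules whose mean over all
diseases of |activity| is at or above the median of that summary. The
summary is taken over all diseases by default; "mean over significant
diseases only" is available via `summary_over="significant"` since the
phrase "mean activity of significant modules across diseases" admits both
readings. Cluster-associated modules apply the same two-step rule
restricted to a cluster's diseases, requiring significance in every
member by default (majority via a flag); cluster-unique sets and the
shared-by-all set are plain set algebra on those associations.

## Association and drug statistics

Disease-gene overlap uses the exact hypergeometric upper tail
P(X ≥ |A∩B|) with population = universe, defaulting to the union of all
lists plus the measured genes; all D(D−1)/2 pairs are evaluated with raw
p-values (no multiple-testing correction, matching the reported
26-of-190-style counts this mirrors). Concordance between the
expression-significant and gene-overlap-significant pair sets is a
one-sided (enrichment) Fisher exact test, computed from the same
hypergeometric tail. Druggable-target over-representation in signature
genes reuses the overlap test verbatim. Drug mapping lists every approved
drug with at least one target inside the given modules' gene union — all
module genes, not only druggable-category genes, a deliberate choice to
keep the candidate list inclusive before manual triage.

## Synthetic data: what it emulates and what it does not

The generator plants: disease clusters sharing signed effect-gene
programs (each cluster's genes get a ±1 sign, fixed per cluster, times
`effect_size` z-units added to the disease arm only); independent
programs for unclustered diseases (true-negative pairs); additive
per-batch per-gene offsets (normal, sd 0.5); a weighted planted-partition
network whose first modules are subsets of the cluster effect programs
(so dysregulated programs appear as modules); disease-gene lists with an
exact intra-cluster overlap fraction and zero inter-cluster overlap; 23
functional sets, the first of which copy the planted programs; and a drug
table with a configurable fraction of drugs targeting module genes.
Noise is i.i.d. unit normal per gene and sample — no gene–gene
correlation beyond the planted programs, no heavy tails, no
probe-level artifacts, no missing values. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under
the stated design, not robustness to real microarray pathologies
(which the regularization and permutation machinery address but the
simulations do not stress). Defaults — 6 diseases in two clusters of 3,
500 genes, 50 effect genes per cluster, effect size 2.0, 10 samples per
arm — describe a small design at which recovery should be (and is)
essentially exact; per-study sample sizes in real compendia of this kind
are free parameters, and 10 per arm is a realistic mid-range value for
public case/control muscle studies.

All generators are pure functions of (config, seed); the pipeline fans a
single run seed out to per-stage child seeds via
`child = (seed·1000 + stage_index) mod 2³¹` so stages can be rerun in
isolation.

## Numerical choices and degenerate inputs

- Sample sds use the n−1 denominator throughout; constant genes z-map to
  all-zero rows and are flagged.
- Quantiles use NumPy's default linear interpolation.
- Partial correlations are symmetrized and clipped to [−1, 1] against
  rounding; the singularity guard triggers at condition number > 1e12.
- MCL columns that prune to zero are re-seeded on the diagonal; column
  stochasticity is preserved to 1e−9 per iterate.
- Linkage heights are non-decreasing by construction (complete linkage is
  monotone); the tree cut uses height ≤ h*.
- Manifest hashes serialize floats at 12 significant digits.

## Problem sizes used in the self-checks

The bundled recovery experiments run the full pipeline at the default
design over 20 seeds (disease-cluster ARI), MCL on 3 × 10-node planted
graphs over 20 seeds, module-detection power at 200 genes over 50 seeds
with 99 permutations, and null calibration with 20 pure-noise diseases,
1,000 genes and 100 permutations (190 pairs). These sizes make the whole
suite comfortably reproducible on a laptop while leaving the planted
effects comfortably inside the detectable regime.

## Known limitations

- The batch stand-in only removes additive offsets; real batch variance
  structure needs a dedicated correction upstream.
- The pooled correlation null assumes pairs are exchangeable under the
  null; strongly heterogeneous study sizes could make extreme pairs
  over- or under-called relative to per-pair nulls.
- MCL granularity depends on inflation; no automatic selection is
  attempted.
- Partial correlation requires a well-conditioned disease correlation
  matrix; compendia with near-duplicate diseases need manual merging.
- Curated functional gene sets and drug–target tables are user-supplied
  inputs; the bundled generators produce synthetic stand-ins only.
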