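# Methods

This note documents the models and numerical choices behind `snpnets`,
what the synthetic-data generator does and does not emulate, and the
known limits of the approach.

## Association mapping

Each (SNP, ROI) pair within a comparison cohort is fitted by ordinary
least squares of the ROI trait on `[intercept, dosage, age, sex,
education]`. The additive dosage codes minor-allele counts 0/1/2; the
p-value is the two-sided t-test on the dosage coefficient. Choices:

- **Intercept** is always included; without it the covariate block could
  not absorb the trait mean.
- **Diagnosis is not a covariate.** The cohort definition (case ∪
  control labels) selects the subjects; within-cohort adjustment uses
  age, sex and education only. Users who want additional adjustment can
  filter or pre-residualize their phenotype table.
- **Missing dosages** are dropped pairwise per SNP, maximizing usable
  subjects per fit, as in common GWAS practice.
- **Degenerate fits** (zero-variance dosage in the cohort, or fewer
  usable subjects than parameters in the map-wide builder) are recorded
  as p = 1 (map entry 0) with an aggregated warning, never a crash. The
  single-pair `fit_snp_qt` raises instead when subjects are insufficient,
  since the caller asked for that specific fit.
- **−log₁₀ p is capped at 300** to guard against floating-point
  underflow of extreme p-values.
- The map-wide builder solves the normal equations once per SNP for all
  ROI responses simultaneously (the design matrix is shared), using a
  pseudoinverse so rank-deficient designs (e.g. a constant covariate
  inside a small cohort) behave exactly like the statsmodels path used
  for single fits, with residual dof = n − rank(X).

Row normalization divides each SNP row by its Euclidean norm, so each
SNP becomes a unit direction over the brain; all-zero rows are left as
zeros and flagged rather than producing NaNs.

## Similarity networks

Pearson and Spearman (average ranks on ties) correlations and cosine
similarity compare row *directions*; Manhattan and Euclidean distances
are magnitude-sensitive. Correlations/cosine are normalized by absolute
value. Distances map to similarities by a Gaussian RBF centered at
distance 0 with σ = (d_max − d_min)/3, where the extremes are taken over
**all** entries of the distance matrix *including the zero diagonal* —
hence d_min = 0 and the kernel is genuinely centered at zero; an
implementation that excluded the diagonal would use the smallest
off-diagonal distance instead and produce different weights. If all
distances are equal the transform is defined as the constant 1.

Undefined raw scores (constant row under a correlation, zero row under
cosine) become weight 0 — maximal dissimilarity — with a logged warning;
the diagonal is forced to exactly 1 after every transform, which the
silhouette distances (1 − s) and the positive-denominator guard of the
cut objective both rely on.

## Multigraph min-max cut

With A_v the weight matrix of view v and D_v = diag(row sums), the
objective over indicators q_k (one per cluster, QᵀQ = I) is

    J = Σ_v Σ_k (q_kᵀ D_v q_k) / (q_kᵀ A_v q_k).

For hard indicators each ratio equals 1 + cut(C_k)/within(C_k), so
J ≥ m·K with equality iff no between-cluster weight exists; this bound
is asserted in the tests. "Diagonal matrix of A" is read as the *degree*
matrix: the alternative (diag entries of A, identically 1 here) would
make the objective constant.

The solver:

1. **Initialization** — spectral embedding (top-K eigenvectors, rows
   normalized) of the view-averaged symmetrically normalized adjacency,
   clustered by seeded k-means; the resulting indicator, smoothed by
   +0.2 and projected, starts the descent. A deterministic, documented
   start is required because gradient descent on this ratio objective is
   local.
2. **Projected gradient descent** on the relaxed objective with an
   ε = 1e−12 denominator guard (relaxed columns can have near-zero
   support mid-descent). Steps use backtracking (halving, up to 40
   times) and are accepted only if the objective does not increase, so
   the recorded trace is non-increasing by construction. The projection
   clips negatives and applies symmetric orthogonalization twice before
   column renormalization. Convergence: relative objective change below
   `tol` (default 1e−6) or `max_iter` (default 1000).
3. **Discretization** by row-argmax (ties to the lowest cluster index,
   for determinism).
4. **Empty-cluster repair** — clusters are explicitly required to be
   nonempty: while any cluster is empty, the node whose transfer least
   increases the objective over nonempty clusters is moved in, one at a
   time, never emptying its source.
5. **Local polish** — greedy best single-node moves on the hard
   objective until a local optimum, with move deltas computed
   incrementally from per-cluster degree and within-weight totals. This
   closes the gap between the relaxed optimum and the best hard
   partition on small unstructured instances (verified against the
   exhaustive solver within 5%).

The reported `Q` is the final hard indicator with unit-normalized
columns — the nearest exactly nonnegative, column-orthonormal matrix to
the partition — and `hard_objective_` is the objective of that
partition. `solve_exhaustive` enumerates all partitions into exactly K
nonempty blocks (restricted-growth strings; refuses S > 15 or K > 3) and
serves as the independent oracle, never as the production path.

## Silhouette selection

Similarities become distances by d = 1 − s. Per node, a(i) is the mean
intra-cluster distance excluding self, b(i) the minimum over other
clusters of the mean distance, s(i) = (b − a)/max(a, b); members of
singleton clusters score 0 (the standard convention). For each K the
single multigraph partition per cohort is scored against *all* measures'
distance matrices, giving a measures × cohorts grid (5 × 5 = 25 cells in
the default design) whose mean is the averaged silhouette. The selected
K is the smallest whose averaged score is within `tolerance` (default
0.01) of the maximum — an explicit operationalization of preferring
fewer clusters when scores are similar, since the aim is a high-level
grouping. A single-graph comparison mode re-clusters every network
separately and scores it against itself, producing a report of identical
shape.

## Synthetic cohorts

The generator emulates the shape of an imaging-genetics study:
genotypes g_ij ~ Binomial(2, MAF_j) with per-SNP MAF uniform in
`maf_range` (default 0.05–0.5); covariates age ~ N(75, 6),
sex ~ Bernoulli(0.5), education ~ N(16, 2); diagnosis labels AD / LMCI /
EMCI / HC drawn independently of genotype in the proportions of a
971-subject cohort (202/218/296/255) — independence is deliberate, since
cohort splitting, not disease genetics, is what downstream stages
exercise. Each planted SNP cluster owns a disjoint ROI block (default
size n_rois/(K+1), leaving a null remainder), and every ROI in that
block receives `effect_size` × (cluster allele-count sum) plus covariate
effects (defaults 0.03/yr age, 0.25 sex, −0.05/yr education) plus
N(0, noise_sd²) noise. One integer seed drives all randomness.

Not emulated: linkage disequilibrium, population stratification,
genotype–diagnosis dependence, and realistic inter-ROI covariance.
Passing tests therefore demonstrate correct mechanics and recovery of
planted structure, not performance on real LD-structured genomes.

A fast fixture, `generate_association_map`, fabricates the SNP × ROI
map directly (per-cluster column templates plus half-normal noise) so
network and clustering tests need not run regressions.

### A note on planted-recovery limits

Because every signature ROI carries the *same* allele-sum signal, all
membership information about one SNP is funneled through a single
statistic — its sample correlation with its cluster's allele sum — whose
expected t-value is bounded by √(n·v_j/V_cluster) regardless of effect
size (the other cluster members act as correlated background; v denotes
dosage variance). At n = 500 with 27-SNP clusters this cap is ≈ 4.3, so
a small per-seed probability remains that some SNP's association row
points at the wrong block and is — correctly, given the data —
misassigned. Recovery benchmarks therefore use a strong-signal setting
(per-allele effect twice the noise SD on a common-variant panel,
MAF 0.2–0.5, where effect strength = α²·2·MAF(1−MAF) is bounded away
from zero) and report recovery *rates*; perfect recovery in every seed
is not information-theoretically guaranteed under this design.

## Problem sizes

The test and acceptance experiments run at the study's native SNP/ROI
shape (54 × 116, five comparison cohorts, five measures, K = 2…9) with
500-subject cohorts; the exhaustive-oracle comparisons use 8-node
two-view instances, the enumeration bound of the oracle. The acceptance
script runs a 5-seed recovery experiment; the test suite runs the full
20-seed version.
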