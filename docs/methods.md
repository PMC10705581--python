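# Methods

## Model and hypotheses

The data matrix x ∈ ℝ^{n×q} is modelled as a realization of X with
independent rows X_i ~ N_q(μ_i, Σ), with the feature covariance Σ known,
symmetric and positive definite (validated by eigendecomposition with a
relative tolerance of 1e−8 on the smallest eigenvalue). A clustering
algorithm 𝒞 partitions the rows; for two estimated clusters Ĝ, Ĝ′ and a
feature j the null hypothesis is that the feature-j population means,
averaged within each cluster, are equal. The contrast ν̂ has entries 1/|Ĝ| on
Ĝ, −1/|Ĝ′| on Ĝ′, zero elsewhere; ‖ν̂‖² = 1/|Ĝ| + 1/|Ĝ′|, and the test
statistic φ_obs = [xᵀν̂]_j is the observed difference in cluster means with
null standard deviation √(Σ_jj‖ν̂‖²).

Because Ĝ, Ĝ′ are functions of x, the test must control the *selective*
type-I error rate: the probability of rejecting, given that this particular
hypothesis was selected. The selective p-value conditions on the clustering
output and on the part of X orthogonal (in the appropriate metric) to the
statistic. What remains random is the scalar statistic itself, which under
the null follows N(0, Σ_jj‖ν̂‖²) truncated to the set of values compatible
with the observed clustering. Concretely, moving the statistic to φ maps the
data to

x′(φ, j) = x + (φ − φ_obs) (ν̂/‖ν̂‖²) (Σ_j/Σ_jj)ᵀ,

so only rows in Ĝ ∪ Ĝ′ move, the tested feature's mean difference becomes
exactly φ, and every other feature j′ co-moves with slope Σ_jj′/Σ_jj. The
truncation set is Ŝ_j = {φ : 𝒞(x′(φ, j)) = 𝒞(x)}, and the two-sided p-value
is P(|Z| ≥ |φ_obs| | Z ∈ Ŝ_j) for the truncated Gaussian Z.

With an estimated Σ̂ (sample covariance, or covariance of within-cluster
residuals with denominator n − K) the p-value is a plug-in quantity; results
are labelled with the covariance mode, and finite-sample exactness is only
guaranteed for known Σ. No finite-sample correction for estimation error is
attempted.

## Truncation set for hierarchical clustering

Dissimilarity is the **squared** Euclidean distance throughout, and cluster
linkage values for average, centroid and Ward linkage are maintained by the
Lance–Williams recurrences appropriate to squared-distance input. (This is
why the library implements agglomeration itself: standard implementations
define centroid/Ward on unsquared Euclidean input. The test suite checks the
merge sequences and heights against scipy through the corresponding
height-squaring transform.) Cutting after n − K merges defines the
K-cluster partition; merge ties are broken by the lexicographically smallest
(cluster-id, cluster-id) pair so that re-clustering is a deterministic
function of the data, and the same rule is used by the brute-force oracle.

Along the perturbation line, a pairwise squared distance is the explicit
quadratic

‖x′_i(φ) − x′_k(φ)‖² = ‖(x_i − x_k) + ((ν̂_i − ν̂_k)/‖ν̂‖²)(φ − φ_obs) w‖²,
w = Σ_j/Σ_jj,

computable in constant time per pair after precomputing ‖w‖² and the row
inner products ⟨x_i, w⟩. Two structural facts make the set exactly
computable:

1. ν̂ is constant on each cluster of the final cut, so every within-cluster
   distance — and hence every linkage value between two sub-clusters of the
   same final cluster — is *constant in φ*.
2. A merge across two final clusters can never be undone, so if it happens
   within the first n − K steps the cut partition changes.

Consequently the perturbed data reproduce the observed partition **iff** at
every step of the observed merge sequence, no candidate pair of clusters
lying in two different final clusters attains a linkage value below that
step's observed merge height (the scheduled within-cluster merges, having
constant values, then proceed identically). Each such event is one quadratic
inequality in φ. Since a cluster pair's linkage value does not change while
both clusters exist, the inequalities are deduplicated per coexisting pair
using the maximum merge height over the pair's coexistence window, giving
O(n²) inequalities for all four linkages; centroid-linkage inversions are
handled automatically because the window maximum, not the last height, is
used. Single linkage (a minimum of pairwise distances, not a Lance–Williams
linear combination) is expanded to one inequality per cross-final-cluster
*row* pair against the largest cut height — also O(n²).

Conditioning is on the K-cluster partition, not on the merge order: the
characterization above shows the two coincide along this particular
perturbation family.

## Truncation set for k-means

Lloyd's algorithm is run from initial centroids equal to K distinct data
rows drawn by a recorded seed; iterate t = 0 assigns rows to the nearest
initial centroid, and subsequent iterations alternate mean updates and
nearest-centroid assignments until the assignment repeats (ties go to the
smallest cluster label). The conditioning event is that *every* intermediate
assignment c⁽ᵗ⁾, t = 0..T, is reproduced — conditioning only on the final
partition would require enumerating exponentially many assignment paths.
Under a fixed previous assignment the perturbed centroids are affine in φ
(initial centroids are perturbed rows; later centroids are means of
perturbed rows), so "row i prefers its recorded cluster over cluster k at
iteration t" is a single quadratic inequality; there are n(T+1)(K−1) of
them. Random-row initialization (not k-means++) is used deliberately: the
conditioning event must be a deterministic function of (x, seed), and the
perturbation must move the initial centroids through the same rows. If a
mean update empties a cluster the run aborts with an explicit error and the
experiment drivers re-seed (and count re-seeds); perturbed re-runs need no
special handling because an empty-cluster path necessarily differs from the
recorded trace and is excluded by the inequalities themselves.

## Interval algebra and numerics

Each quadratic inequality is solved exactly, with explicit handling of
vanished leading coefficients (|a| ≤ 1e−10 · max(|a|,|b|,|c|,1), likewise
b — distance-difference quadratics frequently cancel their leading terms in
theory but not in floating point) and of zero/negative discriminants
(relative tolerance on b² − 4ac). Solution sets are closed intervals —
conditioning events are closed by continuity of the clustering criteria, and
the boundary has measure zero under the Gaussian reference. All sets are
intersected in one endpoint sweep (O(N log N) in the total interval count);
adjacent intervals with gaps ≤ 1e−9 · (1 + |φ_obs|) are merged, and
membership checks use tolerance 1e−8 · (1 + |φ_obs|). All quadratics are
built in the centered parameter ψ = φ − φ_obs for conditioning-set stability
and shifted back at the end. The observed statistic must lie in its own
truncation set; a violation raises an internal error rather than returning a
wrong p-value.

The truncated-Gaussian CDF computes each interval's mass in log space from
scipy's log-CDF/log-survival functions, taking the side nearer the mean, and
accumulates across intervals with log-sum-exp; the selective p-value is
formed directly as (mass of Ŝ ∩ {|φ| ≥ |φ_obs|}) / (mass of Ŝ) in log space.
Supports dozens of standard deviations into a tail therefore remain exact:
with a strong signal the conditioning set's true mass is routinely below the
smallest positive double, which is legitimate and representable as a log
mass. The degenerate-support error fires only on genuine log-space
underflow, which would contradict the self-membership contract.

## Synthetic designs

The generator draws independent rows N_q(μ_i, Σ) with the equicorrelated
covariance Σ = (1 − ρ)I + ρ𝟙𝟙ᵀ (positive definite for ρ ∈ [0, 1)); ρ
defaults to 0 and the experiments use ρ ∈ {0, 0.4, 0.8}. Designs, at the
default n = 150, q = 10:

- **null / two-group** (`fig1`, `null3`): 50 rows with mean 1 in feature 1,
  100 rows with mean 1 in feature q. Every middle feature 2..q−1 has equal
  means between any pair of estimated clusters, so tests of a random middle
  feature probe the selective type-I error rate. Conventionally clustered at
  K = 2 (`fig1`) or K = 3 (`null3`).
- **three-group signal** (`power3`): three groups of 50 with means −δ, 0, +δ
  on the last ⌈q/2⌉ features; δ ∈ {3,…,8} in the experiments.

The experiment drivers use separate seed streams for data generation,
pair/feature selection, and k-means initialization, so each can be varied
independently; a replicate's random cluster pair is uniform over the
estimated pairs and the random feature is uniform over 2..q−1 (type-I
experiments) or over all q features (power experiments, matching the
"randomly-chosen feature" convention — hence a conditional-power plateau
near 1/2, since half the features carry no signal). Conditional power is the
rejection fraction among replicates whose tested pair coincides, as sets,
with two true groups (set to zero when no replicate qualifies); detection
probability is the fraction of such replicates.

What the generator does *not* emulate about real expression data: counts are
generated Gaussian, not as sampled transcripts; the covariance is exactly
equicorrelated rather than gene-structured; and rows are exchangeable within
groups. Passing tests therefore demonstrate correctness of the selective
machinery under its stated model, not robustness to count noise,
normalization artifacts, or covariance misestimation — for real data the
plug-in covariance modes are available but carry no finite-sample guarantee.

## Problem sizes and design choices in the validation suite

The statistical acceptance tests use M = 500 replicates per (method, ρ) for
the null experiments (the ±3·binomial-SE band around the 0.05 level is then
[0.021, 0.079]) and M = 300 per cell for the power experiments at
δ ∈ {3, 5, 8}, ρ = 0.8; truncation sets are audited against brute-force
re-clustering on 401-point grids over φ_obs ± 10 for 20 seeded data sets
(n ≤ 30, q ≤ 5, all four linkages, k-means with K ∈ {2, 3}), excluding grid
points within tolerance of an interval boundary, where assignment
tie-breaking is indeterminate. Monotonicity of estimated conditional power
in δ is asserted up to 3 binomial standard errors of each successive
difference, the same sampling-error convention as the type-I band — methods
that reach their power plateau early (single linkage under high correlation)
fluctuate within Monte-Carlo noise.

## Known limitations

- Exactness requires known Σ; plug-in covariance results are labelled and
  approximate.
- Complete linkage and correlation-based dissimilarities are out of scope
  (their linkage values are not quadratics in φ).
- Multi-feature (vector) contrasts and selective confidence intervals are
  not implemented.
- A single seeded Lloyd run can land in split/merged local optima on
  well-separated data (~25% of runs on the strongly separated three-group
  design); the conditioning remains valid — the test is exact for the
  clusters actually found — but detection probability reflects it.
- The k-means p-value conditions on all iterates, which is more conditioning
  (hence typically less power) than the final-partition event it implies.
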