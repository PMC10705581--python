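# postclust

Selective inference for differences in single-feature means between clusters
that were estimated from the same data.

## The problem

A routine analysis in single-cell genomics (and in any clustering pipeline)
is: cluster the observations, then test which features differ between two of
the resulting clusters — e.g. which genes are "differentially expressed"
between two cell clusters. Because the clusters were chosen *by looking at
the same data*, the classical two-sample Z- or t-test is invalid: clustering
algorithms always produce separated groups, even from a single homogeneous
population, so the naive p-values pile up near zero and the type-I error
rate is badly inflated ("double dipping").

`postclust` implements an exact finite-sample correction for data modelled as
independent Gaussian rows X_i ~ N_q(μ_i, Σ) with known (or plug-in) feature
covariance Σ. For a pair of estimated clusters Ĝ, Ĝ′ and a feature j, the
null hypothesis is H₀: mean of feature j is equal across the two clusters,
i.e. ν̂ᵀμ_{·j} = 0 for the contrast ν̂ with entries 1/|Ĝ| on Ĝ and −1/|Ĝ′| on
Ĝ′. The test statistic is the observed difference in cluster means,
φ_obs = [xᵀν̂]_j.

## The method

The selective p-value conditions on the event that the clustering algorithm
produced the observed clusters, plus the sufficient-statistic remainder of
the data. Under these conditions the statistic follows a **truncated
Gaussian** N(0, Σ_jj‖ν̂‖²) restricted to the truncation set

    Ŝ_j = { φ ∈ ℝ : clustering x′(φ, j) reproduces the observed clusters },

where x′(φ, j) = x + (φ − φ_obs)(ν̂/‖ν̂‖²)(Σ_j/Σ_jj)ᵀ slides the tested mean
difference to φ while co-moving correlated features. The two-sided p-value is
P(|Z| ≥ |φ_obs| | Z ∈ Ŝ_j).

The package computes Ŝ_j **exactly** (no Monte Carlo) for:

- **hierarchical clustering** on squared Euclidean distances with single,
  average, centroid or Ward linkage, cut at K clusters — every conditioning
  event reduces to a quadratic inequality in φ via Lance–Williams updates on
  quadratic coefficient triples (O(n²) inequalities);
- **k-means** (seeded Lloyd iterations with data rows as initial centroids),
  conditioning on all intermediate assignments — n(T+1)(K−1) quadratic
  inequalities.

Supporting machinery: a numerically stable truncated-Gaussian CDF (log-space
tail masses, supports dozens of standard deviations out remain exact), an
interval-union algebra with an O(N log N) intersection sweep, plug-in
covariance estimators (sample / within-cluster residual), Benjamini–Hochberg
adjustment, CSV/TSV/MatrixMarket I/O and standard count preprocessing
(total-count normalization, log2(x+1), top-variance gene selection).

## Worked example

```python
import numpy as np
from postclust import equicorrelated_sigma, kmeans_trace, test_all

rng = np.random.default_rng(0)
mu = np.zeros((30, 2))
mu[:10] = [0.0, 2.5]; mu[10:20] = [2.5, 0.0]; mu[20:] = [-2.5, -2.5]
sigma = 0.2 * equicorrelated_sigma(2, 0.4)
x = mu + rng.multivariate_normal(np.zeros(2), sigma, size=30)

trace = kmeans_trace(x, K=3, seed=1)
print(test_all(x, sigma, trace, pairs=[(0, 1)]))
```

prints (abridged):

```
 cluster_a  cluster_b  feature      stat      p_naive  p_selective  n_intervals
         1          2        1  2.359322 4.063531e-32 2.031766e-32            1
         1          2        2 -2.477601 3.034917e-35 1.241009e-33            1
```

`stat` is the observed difference in cluster means, `p_naive` the (invalid)
two-sample Z p-value, `p_selective` the truncated-Gaussian p-value that
accounts for having chosen the clusters from the data. Here the groups are
genuinely separated, so both features remain highly significant after the
correction. On clusterings of *homogeneous* data the two columns diverge
dramatically: running `python examples/type1_error_under_the_null.py` gives

```
kmeans   rejection at alpha=0.05: naive 0.960, selective 0.045; KS uniformity p-value of selective p-values: 0.153
average  rejection at alpha=0.05: naive 0.760, selective 0.065; KS uniformity p-value of selective p-values: 0.643
```

— the naive test rejects a true null most of the time, the selective test at
its nominal 5%.

The `examples/` directory has one narrative script per capability
(quickstart, type-I error, power/detection), and the same functionality is
available from the shell:

```sh
postclust test --input expr.csv --method kmeans --k 2 --seed 1 --sigma sample --out results.tsv
postclust simulate --design null3 --method average --m 200 --rho 0.4 --out sim.tsv
postclust preprocess --input counts.csv --normalize --log2 --top-var 500 --out clean.csv
```

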