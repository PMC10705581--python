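"""Test feature mean differences between two estimated clusters.

Builds a small two-feature data set with three well-separated groups,
clusters it with seeded k-means (K=3), and tests whether the first two
estimated clusters differ in the mean of each feature — once with the naive
two-sample Z-test (which pretends the clusters were pre-specified) and once
with the selective test (which conditions on the clustering).  Because the
groups here are genuinely separated in both features, both p-values are
small; the selective one is the only one that would remain honest if the
clusters were noise.
"""

import numpy as np

from postclust import equicorrelated_sigma, kmeans_trace, test_all

rng = np.random.default_rng(0)
n_per = 10
mu = np.zeros((3 * n_per, 2))
mu[:n_per] = [0.0, 2.5]
mu[n_per : 2 * n_per] = [2.5, 0.0]
mu[2 * n_per :] = [-2.5, -2.5]
sigma = 0.2 * equicorrelated_sigma(2, 0.4)  # diagonal 0.2, off-diagonal 0.08
x = mu + rng.multivariate_normal(np.zeros(2), sigma, size=3 * n_per)

trace = kmeans_trace(x, K=3, seed=1)
print(f"k-means converged in T={trace.T} iterations; cluster sizes "
      f"{np.bincount(trace.labels)}")

frame = test_all(x, sigma, trace, pairs=[(0, 1)])
print(frame[["cluster_a", "cluster_b", "feature", "stat", "p_naive",
             "p_selective", "n_intervals"]].to_string(index=False))
print(
    "\nEach row tests one feature between clusters 1 and 2. 'stat' is the\n"
    "difference in cluster means, 'p_selective' the truncated-Gaussian\n"
    "p-value conditioned on the clustering (n_intervals = pieces of the\n"
    "truncation set). Small selective p-values here are real signal."
)
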