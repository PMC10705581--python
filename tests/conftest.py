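import numpy as np
import pytest


def canon(labels) -> tuple:
    """Canonical form of a label vector: relabel by order of first appearance."""
    seen = {}
    out = []
    for v in labels:
        v = int(v)
        if v not in seen:
            seen[v] = len(seen)
        out.append(seen[v])
    return tuple(out)


def same_partition(a, b) -> bool:
    return canon(a) == canon(b)


@pytest.fixture
def three_blob():
    """Factory for the well-separated three-cluster two-feature design.

    Three groups of ``per`` rows at means (0, sep), (sep, 0), (-sep, -sep)
    with feature covariance 0.2 * [[1, .4], [.4, 1]].
    """

    def make(per=10, sep=2.5, seed=0, q=2, rho=0.4, scale=0.2):
        rng = np.random.default_rng(seed)
        n = 3 * per
        mu = np.zeros((n, q))
        mu[:per, :2] = [0.0, sep]
        mu[per : 2 * per, :2] = [sep, 0.0]
        mu[2 * per :, :2] = [-sep, -sep]
        sigma = scale * ((1 - rho) * np.eye(q) + rho * np.ones((q, q)))
        x = mu + rng.multivariate_normal(np.zeros(q), sigma, size=n)
        return x, sigma

    return make
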