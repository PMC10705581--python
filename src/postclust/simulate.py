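"""Synthetic Gaussian data designs and the validation experiments.

Three mean designs over rows drawn i.i.d. ``N_q(mu_i, Sigma)`` with the
equicorrelated covariance ``Sigma = (1 - rho) I + rho 11'``:

* ``fig1`` / ``null3`` — the first third of the rows have mean 1 in the first
  feature; the remaining rows have mean 1 in the last feature.  Every middle
  feature (2..q-1, 1-based) has equal means between *any* pair of estimated
  clusters, so tests of those features probe the selective type-I error rate.
  (``fig1`` is conventionally clustered at K=2, ``null3`` at K=3.)
* ``power3`` — three equal thirds with means ``-delta``, ``0`` and ``+delta``
  on the last ``ceil(q/2)`` features; used for conditional power and
  detection probability.

The experiment drivers use two independent seed streams (data generation vs
pair/feature selection) so either can be varied alone, and a third stream for
k-means initialization; replicates whose k-means run empties a cluster are
re-seeded and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hierarchy import hclust_trace
from .kmeans import EmptyClusterError, kmeans_trace
from .model import GaussianModel, contrast_vector, perturbation_line, test_statistic, TestSpec
from .testing import naive_p, test_pair_feature

__all__ = [
    "SimulationConfig",
    "equicorrelated_sigma",
    "design_means",
    "generate",
    "cluster_data",
    "type1_experiment",
    "power_experiment",
    "Type1Result",
    "PowerResult",
]

DESIGNS = ("fig1", "null3", "power3")
HIER_METHODS = ("single", "average", "centroid", "ward")


def read_config(path) -> "SimulationConfig":
    """Parse a plain ``key = value`` file into a :class:`SimulationConfig`."""
    fields = {f.name: f.type for f in SimulationConfig.__dataclass_fields__.values()}
    kwargs = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = value if key == "design" else (
                float(value) if key in ("rho", "delta", "alpha") else int(value)
            )
    return SimulationConfig(**kwargs)


def qq_plot(pvalues: dict, path) -> None:
    """Quantile-quantile plot of p-value samples against Uniform(0, 1).

    ``pvalues`` maps a label to a 1-d sample; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for label, sample in pvalues.items():
        sample = np.sort(np.asarray(sample))
        unif = (np.arange(1, sample.size + 1) - 0.5) / sample.size
        ax.plot(unif, sample, marker=".", ls="", ms=3, label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("Uniform(0,1) quantiles")
    ax.set_ylabel("observed p-value quantiles")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated experiment."""

    n: int = 150
    q: int = 10
    rho: float = 0.0
    delta: float = 0.0
    design: str = "null3"
    M: int = 500
    alpha: float = 0.05
    seed: int = 0
    K: int = 3
    max_kmeans_reseeds: int = 50

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n % 3:
            raise ValueError("n must be divisible by 3 for the three-group designs")


def equicorrelated_sigma(q: int, rho: float) -> np.ndarray:
    """``Sigma_ij = 1{i=j} + rho 1{i!=j}``; positive definite for rho in [0, 1)."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    return (1.0 - rho) * np.eye(q) + rho * np.ones((q, q))


def design_means(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Mean matrix and true-group labels for the configured design."""
    n, q = config.n, config.q
    third = n // 3
    mu = np.zeros((n, q))
    if config.design in ("fig1", "null3"):
        mu[:third, 0] = 1.0
        mu[third:, q - 1] = 1.0
        labels = np.repeat([0, 1], [third, n - third])
    else:  # power3
        lo = q // 2  # first floor(q/2) features carry no signal
        mu[:third, lo:] = -config.delta
        mu[2 * third :, lo:] = config.delta
        labels = np.repeat([0, 1, 2], third)
    return mu, labels


def generate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one data matrix; returns ``(x, true_group_labels)``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu, labels = design_means(config)
    model = GaussianModel(mu=mu, sigma=equicorrelated_sigma(config.q, config.rho))
    return model.sample(rng), labels


def cluster_data(x, method: str, K: int, kmeans_rng: np.random.Generator | None = None,
                 max_reseeds: int = 50):
    """Cluster with the named method; returns ``(trace, n_reseeds)``.

    ``method`` is ``"kmeans"`` or a hierarchical linkage name.  k-means seeds
    are drawn from ``kmeans_rng``; empty-cluster failures are re-seeded.
    """
    if method == "kmeans":
        if kmeans_rng is None:
            kmeans_rng = np.random.default_rng(0)
        for attempt in range(max_reseeds):
            seed = int(kmeans_rng.integers(0, 2**31 - 1))
            try:
                return kmeans_trace(x, K, seed=seed), attempt
            except EmptyClusterError:
                continue
        raise EmptyClusterError(f"k-means failed {max_reseeds} re-seeds")
    if method in HIER_METHODS:
        return hclust_trace(x, method, K), 0
    raise ValueError(f"unknown clustering method {method!r}")


@dataclass(frozen=True)
class Type1Result:
    method: str
    rho: float
    alpha: float
    p_naive: np.ndarray
    p_selective: np.ndarray
    n_reseeds: int

    @property
    def naive_rejection_rate(self) -> float:
        return float(np.mean(self.p_naive <= self.alpha))

    @property
    def selective_rejection_rate(self) -> float:
        return float(np.mean(self.p_selective <= self.alpha))


def type1_experiment(config: SimulationConfig, method: str) -> Type1Result:
    """Global-null experiment: selective type-I error and naive inflation.

    Per replicate: draw the null design, estimate K clusters, pick a uniform
    random cluster pair and a uniform random middle feature (2..q-1,
    1-based), and compute the naive and selective p-values with the known
    equicorrelated covariance.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_data, rng_sel, rng_km = (np.random.default_rng(s) for s in ss.spawn(3))
    sigma = equicorrelated_sigma(config.q, config.rho)
    cfg = config
    p_naive = np.empty(cfg.M)
    p_sel = np.empty(cfg.M)
    reseeds = 0
    for m in range(cfg.M):
        x, _ = generate(cfg, rng_data)
        trace, nr = cluster_data(x, method, cfg.K, rng_km, cfg.max_kmeans_reseeds)
        reseeds += nr
        pair, feature = _pick_pair_feature(rng_sel, trace.labels, cfg.q)
        res = test_pair_feature(x, sigma, trace, pair, feature)
        p_naive[m] = res.p_naive
        p_sel[m] = res.p_selective
    return Type1Result(
        method=method,
        rho=cfg.rho,
        alpha=cfg.alpha,
        p_naive=p_naive,
        p_selective=p_sel,
        n_reseeds=reseeds,
    )


def _pick_pair_feature(rng: np.random.Generator, labels: np.ndarray, q: int):
    ks = np.unique(labels)
    pairs = [(int(a), int(b)) for i, a in enumerate(ks) for b in ks[i + 1 :]]
    pair = pairs[int(rng.integers(len(pairs)))]
    feature = int(rng.integers(1, q - 1))  # 0-based middle features
    return pair, feature


@dataclass(frozen=True)
class PowerResult:
    method: str
    rho: float
    delta: float
    alpha: float
    M: int
    n_detected: int
    n_rejected: int
    n_reseeds: int

    @property
    def detection_probability(self) -> float:
        return self.n_detected / self.M

    @property
    def conditional_power(self) -> float:
        """Rejections among detected replicates; zero when none detected."""
        return self.n_rejected / self.n_detected if self.n_detected else 0.0


def power_experiment(config: SimulationConfig, method: str) -> PowerResult:
    """Three-group signal experiment: conditional power and detection.

    A replicate counts as "detected" when both clusters of the randomly
    chosen tested pair coincide, as sets, with true groups; the conditional
    power is the rejection fraction among detected replicates (feature drawn
    uniformly from all q features, as in the overall experiment convention).
    """
    if config.design != "power3":
        raise ValueError("power_experiment requires the power3 design")
    ss = np.random.SeedSequence(config.seed)
    rng_data, rng_sel, rng_km = (np.random.default_rng(s) for s in ss.spawn(3))
    sigma = equicorrelated_sigma(config.q, config.rho)
    true_sets = None
    n_detected = n_rejected = reseeds = 0
    for m in range(config.M):
        x, true_labels = generate(config, rng_data)
        if true_sets is None:
            true_sets = {
                frozenset(np.nonzero(true_labels == g)[0]) for g in np.unique(true_labels)
            }
        trace, nr = cluster_data(x, method, config.K, rng_km, config.max_kmeans_reseeds)
        reseeds += nr
        ks = np.unique(trace.labels)
        pairs = [(int(a), int(b)) for i, a in enumerate(ks) for b in ks[i + 1 :]]
        pair = pairs[int(rng_sel.integers(len(pairs)))]
        feature = int(rng_sel.integers(config.q))
        ga = frozenset(np.nonzero(trace.labels == pair[0])[0])
        gb = frozenset(np.nonzero(trace.labels == pair[1])[0])
        detected = ga in true_sets and gb in true_sets
        if not detected:
            continue
        n_detected += 1
        res = test_pair_feature(x, sigma, trace, pair, feature)
        if res.p_selective <= config.alpha:
            n_rejected += 1
    return PowerResult(
        method=method,
        rho=config.rho,
        delta=config.delta,
        alpha=config.alpha,
        M=config.M,
        n_detected=n_detected,
        n_rejected=n_rejected,
        n_reseeds=reseeds,
    )
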