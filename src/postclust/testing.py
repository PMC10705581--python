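"""Selective and naive tests for a feature's mean difference between clusters.

``test_feature`` glues the pieces together: given the data, a feature
covariance, a recorded clustering (hierarchical dendrogram trace or k-means
iterate trace) and a (cluster pair, feature) choice, it computes the observed
mean-difference statistic, its null standard deviation
``sqrt(Sigma_jj * ||nu||^2)``, the truncation set along the perturbation
line, and both the naive two-sided Z p-value and the selective
truncated-Gaussian p-value.

The selective p-value is exact in finite samples when ``Sigma`` is known.
With an estimated covariance (``estimate_sigma``) it is a plug-in quantity
and results are labelled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .hier_truncation import hier_truncation_set
from .hierarchy import DendrogramTrace
from .intervals import IntervalUnion
from .kmeans import KMeansTrace, kmeans_truncation_set
from .model import (
    Contrast,
    InvalidSpecError,
    TestSpec,
    contrast_vector,
    perturbation_line,
    test_statistic,
    validate_covariance,
)
from .truncgauss import selective_p

__all__ = [
    "SelectiveTestResult",
    "naive_p",
    "test_feature",
    "test_pair_feature",
    "test_all",
    "estimate_sigma",
    "bh_adjust",
    "results_to_frame",
]


def naive_p(stat: float, null_sd: float) -> float:
    """Two-sided Z p-value treating the groups as pre-specified."""
    if not null_sd > 0:
        raise ValueError("null_sd must be positive")
    return float(2.0 * norm.sf(abs(stat) / null_sd))


@dataclass(frozen=True)
class SelectiveTestResult:
    """Outcome of one (cluster pair, feature) test."""

    spec: TestSpec
    stat: float
    null_sd: float
    truncation: IntervalUnion
    p_naive: float
    p_selective: float
    method: str
    cluster_a: int = -1
    cluster_b: int = -1
    sigma_mode: str = "known"

    @property
    def n_intervals(self) -> int:
        return self.truncation.n_intervals


def _truncation(x, trace, line) -> IntervalUnion:
    if isinstance(trace, DendrogramTrace):
        return hier_truncation_set(x, trace, line)
    if isinstance(trace, KMeansTrace):
        return kmeans_truncation_set(x, trace, line)
    raise TypeError(f"unsupported clustering trace {type(trace).__name__}")


def _method_name(trace) -> str:
    if isinstance(trace, DendrogramTrace):
        return f"hierarchical/{trace.linkage} (K={trace.K})"
    return f"kmeans (K={trace.K}, seed={trace.seed})"


def test_feature(
    x: np.ndarray,
    sigma: np.ndarray,
    trace,
    spec: TestSpec,
    sigma_mode: str = "known",
) -> SelectiveTestResult:
    """Selective test of equal feature means between two estimated clusters.

    ``spec``'s two groups must each be exactly one cluster of the trace's
    final partition (the conditioning event refers to that clustering).
    """
    x = np.asarray(x, dtype=float)
    n, q = x.shape
    spec.validate(n, q)
    validate_covariance(sigma)

    labels = trace.labels
    members = {k: frozenset(np.nonzero(labels == k)[0]) for k in np.unique(labels)}
    inv = {v: k for k, v in members.items()}
    if spec.group_a not in inv or spec.group_b not in inv:
        raise InvalidSpecError(
            "the tested groups are not clusters of the supplied clustering"
        )
    ka, kb = inv[spec.group_a], inv[spec.group_b]

    contrast = contrast_vector(n, spec)
    j = spec.feature
    stat = test_statistic(x, contrast, j)
    null_sd = float(np.sqrt(sigma[j, j] * contrast.nu_sq_norm))
    line = perturbation_line(x, np.asarray(sigma, dtype=float), contrast, j)
    trunc = _truncation(x, trace, line)
    return SelectiveTestResult(
        spec=spec,
        stat=stat,
        null_sd=null_sd,
        truncation=trunc,
        p_naive=naive_p(stat, null_sd),
        p_selective=selective_p(stat, null_sd, trunc),
        method=_method_name(trace),
        cluster_a=int(ka),
        cluster_b=int(kb),
        sigma_mode=sigma_mode,
    )


def test_pair_feature(
    x: np.ndarray,
    sigma: np.ndarray,
    trace,
    pair: tuple[int, int],
    feature: int,
    sigma_mode: str = "known",
) -> SelectiveTestResult:
    """Convenience wrapper: identify the groups by their cluster labels."""
    labels = trace.labels
    a, b = pair
    ga = np.nonzero(labels == a)[0]
    gb = np.nonzero(labels == b)[0]
    if ga.size == 0 or gb.size == 0:
        raise InvalidSpecError(f"cluster labels {a}, {b} not found in the clustering")
    return test_feature(x, sigma, trace, TestSpec(ga, gb, feature), sigma_mode=sigma_mode)


def test_all(
    x: np.ndarray,
    sigma: np.ndarray,
    trace,
    pairs=None,
    features=None,
    fdr_within: str = "all",
    sigma_mode: str = "known",
) -> pd.DataFrame:
    """Test many (pair, feature) combinations; returns a tidy frame.

    ``pairs=None`` tests every pair of clusters; ``features=None`` tests every
    feature.  BH adjustment is applied across all computed selective p-values.
    """
    x = np.asarray(x, dtype=float)
    q = x.shape[1]
    ks = sorted(int(k) for k in np.unique(trace.labels))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(ks) for b in ks[i + 1 :]]
    if features is None:
        features = list(range(q))
    results = [
        test_pair_feature(x, sigma, trace, pair, j, sigma_mode=sigma_mode)
        for pair in pairs
        for j in features
    ]
    return results_to_frame(results)


def estimate_sigma(x: np.ndarray, mode: str = "sample", labels=None) -> np.ndarray:
    """Plug-in feature covariance.

    ``sample``: empirical covariance of the rows (denominator n-1).
    ``residual``: covariance of rows after subtracting each row's cluster
    mean (denominator n - #clusters) — the convention for estimating Sigma
    from a clustering fit without absorbing between-cluster signal.

    The estimate is symmetrized and ridge-lifted to positive definite if its
    smallest eigenvalue is not safely positive.
    """
    x = np.asarray(x, dtype=float)
    n, q = x.shape
    if mode == "sample":
        if n < 2:
            raise ValueError("need at least 2 rows for the sample covariance")
        resid = x - x.mean(axis=0)
        denom = n - 1
    elif mode == "residual":
        if labels is None:
            raise ValueError("residual mode requires cluster labels")
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        resid = x.copy()
        for k in uniq:
            mask = labels == k
            resid[mask] -= x[mask].mean(axis=0)
        denom = n - uniq.size
        if denom < 1:
            raise ValueError(f"n={n} too small for {uniq.size} clusters")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    s = (resid.T @ resid) / denom
    s = 0.5 * (s + s.T)
    ev = np.linalg.eigvalsh(s)
    floor = 1e-8 * max(ev[-1], 1e-12)
    if ev[0] <= floor:
        s = s + (floor - ev[0] + floor) * np.eye(q)
    return s


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def results_to_frame(results: list[SelectiveTestResult]) -> pd.DataFrame:
    """One row per (pair, feature); indices are 1-based in this serialized form."""
    rows = []
    for r in results:
        rows.append(
            {
                "cluster_a": r.cluster_a + 1,
                "cluster_b": r.cluster_b + 1,
                "feature": r.spec.feature + 1,
                "stat": r.stat,
                "null_sd": r.null_sd,
                "p_naive": r.p_naive,
                "p_selective": r.p_selective,
                "n_intervals": r.n_intervals,
                "truncation_intervals": ";".join(
                    f"{lo:.10g},{hi:.10g}" for lo, hi in r.truncation
                ),
                "method": r.method,
                "sigma_mode": r.sigma_mode,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame.insert(
            frame.columns.get_loc("n_intervals"),
            "p_selective_bh",
            bh_adjust(frame["p_selective"].to_numpy()),
        )
    return frame
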