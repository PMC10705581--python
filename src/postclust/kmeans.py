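"""Lloyd's k-means with full iterate recording, and its conditioning set.

The final partition of k-means is not a simple function of the data, so the
selective test conditions on *every* intermediate assignment of the traced
run (iterations ``t = 0..T``), following the iterate-conditioning device of
Chen & Witten for k-means.  Initial centroids are data rows drawn without
replacement by a recorded seed; along the perturbation line those rows (and
every per-cluster mean under a fixed assignment) move affinely in ``phi``, so
each "row i stays assigned to its recorded cluster rather than cluster k"
event is a single quadratic inequality in ``phi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import IntervalUnion, intersect_leq_constraints
from .model import PerturbationLine

__all__ = ["KMeansTrace", "kmeans_trace", "kmeans_constraints", "kmeans_truncation_set", "EmptyClusterError"]


class EmptyClusterError(RuntimeError):
    """A centroid update produced an empty cluster; re-run with a new seed."""


class TruncationError(RuntimeError):
    pass


@dataclass(frozen=True)
class KMeansTrace:
    """All iterates of one seeded Lloyd run.

    ``assignments`` has shape (T+1, n): row ``t`` is the assignment after
    iteration ``t`` (row 0 = nearest initial centroid).  At convergence the
    last two rows coincide (or T = max_iter was hit).
    """

    K: int
    T: int
    assignments: np.ndarray
    init_indices: np.ndarray
    seed: int

    @property
    def labels(self) -> np.ndarray:
        """Final cluster assignment."""
        return self.assignments[-1]

    @property
    def clusters(self) -> list[np.ndarray]:
        return [np.nonzero(self.labels == k)[0] for k in range(self.K)]


def _nearest(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels; ties broken by the smallest cluster label."""
    d = (
        np.einsum("ij,ij->i", x, x)[:, None]
        - 2.0 * (x @ centroids.T)
        + np.einsum("kj,kj->k", centroids, centroids)[None, :]
    )
    return np.argmin(d, axis=1)  # argmin takes the first minimum: smallest label


def _centroids(x: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    out = np.empty((K, x.shape[1]))
    for k in range(K):
        mask = labels == k
        if not np.any(mask):
            raise EmptyClusterError(f"cluster {k} became empty")
        out[k] = x[mask].mean(axis=0)
    return out


def kmeans_trace(
    x: np.ndarray, K: int, seed: int, max_iter: int = 100
) -> KMeansTrace:
    """Run Lloyd's algorithm from seeded random-row initial centroids.

    Deterministic given ``(x, K, seed)``.  Raises :class:`EmptyClusterError`
    if a centroid update empties a cluster (caller re-seeds).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds n={n}")
    rng = np.random.default_rng(seed)
    init_indices = np.sort(rng.choice(n, size=K, replace=False))
    assignments = [_nearest(x, x[init_indices])]
    for _ in range(max_iter):
        cents = _centroids(x, assignments[-1], K)
        labels = _nearest(x, cents)
        assignments.append(labels)
        if np.array_equal(labels, assignments[-2]):
            break
    return KMeansTrace(
        K=K,
        T=len(assignments) - 1,
        assignments=np.vstack(assignments),
        init_indices=init_indices,
        seed=seed,
    )


def replay_lloyd(x: np.ndarray, init_indices: np.ndarray, K: int, T: int) -> np.ndarray:
    """Run exactly T Lloyd iterations from the given initial rows.

    Used as the brute-force oracle for the truncation set: returns the
    (T+1, n) iterate matrix, or None if a cluster empties along the way.
    """
    x = np.asarray(x, dtype=float)
    assignments = [_nearest(x, x[init_indices])]
    for _ in range(T):
        try:
            cents = _centroids(x, assignments[-1], K)
        except EmptyClusterError:
            return None
        assignments.append(_nearest(x, cents))
    return np.vstack(assignments)


def kmeans_constraints(
    x: np.ndarray, trace: KMeansTrace, line: PerturbationLine
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficient arrays of the ``quad(psi) <= 0`` iterate-preservation events.

    ``psi = phi - phi_obs``; exactly ``n (T+1) (K-1)`` triples.
    """
    x = np.asarray(x, dtype=float)
    n, q = x.shape
    K, T = trace.K, trace.T
    w = line.direction
    wn2 = float(w @ w)
    beta = line.contrast.nu / line.contrast.nu_sq_norm  # row motion per unit psi
    t_row = x @ w
    xn2 = np.einsum("ij,ij->i", x, x)

    con_a, con_b, con_c = [], [], []
    rows = np.arange(n)

    for t in range(T + 1):
        if t == 0:
            cents = x[trace.init_indices]
            alpha = beta[trace.init_indices]
        else:
            prev = trace.assignments[t - 1]
            cents = np.empty((K, q))
            alpha = np.empty(K)
            for k in range(K):
                mask = prev == k
                cents[k] = x[mask].mean(axis=0)
                alpha[k] = beta[mask].mean()
        t_cent = cents @ w
        cn2 = np.einsum("kj,kj->k", cents, cents)

        # quadratic coefficients of ||x'_i - m'_k||^2 in psi, for all (i, k)
        G = beta[:, None] - alpha[None, :]
        L = t_row[:, None] - t_cent[None, :]
        Aq = G * G * wn2
        Bq = 2.0 * G * L
        Cq = xn2[:, None] - 2.0 * (x @ cents.T) + cn2[None, :]

        c_t = trace.assignments[t]
        a_own = Aq[rows, c_t][:, None]
        b_own = Bq[rows, c_t][:, None]
        c_own = Cq[rows, c_t][:, None]
        # own-cluster distance <= competitor distance, all k != c_t[i]
        mask = np.ones((n, K), dtype=bool)
        mask[rows, c_t] = False
        con_a.append((a_own - Aq)[mask])
        con_b.append((b_own - Bq)[mask])
        con_c.append((c_own - Cq)[mask])

    return np.concatenate(con_a), np.concatenate(con_b), np.concatenate(con_c)


def kmeans_truncation_set(
    x: np.ndarray, trace: KMeansTrace, line: PerturbationLine
) -> IntervalUnion:
    """The set of ``phi`` whose perturbed data reproduce every Lloyd iterate.

    For each iteration ``t`` the centroids of the perturbed data under the
    *recorded* previous assignment are affine in ``phi``; requiring row ``i``
    to prefer its recorded cluster over each of the other ``K-1`` gives
    ``n (T+1) (K-1)`` quadratic inequalities, intersected in one sweep.
    """
    a, b, c = kmeans_constraints(x, trace, line)
    scale = 1.0 + abs(line.phi_obs)
    s_psi = intersect_leq_constraints(a, b, c, tol_merge=1e-9 * scale)
    s = s_psi.shift(line.phi_obs)
    if not s.contains(line.phi_obs, tol=1e-8 * scale):
        raise TruncationError("observed statistic not in its own k-means conditioning set")
    return s
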