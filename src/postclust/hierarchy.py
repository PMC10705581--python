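"""Agglomerative clustering on squared Euclidean distances with a merge trace.

The truncation-set computation needs (i) clustering that is an exactly
deterministic function of the data, and (ii) access to the full merge
sequence, with linkage values maintained by Lance–Williams updates *on the
squared distances* so that, along the perturbation line, every linkage value
stays an explicit quadratic in the perturbation parameter.  Neither is
available from library implementations (which define centroid/Ward on
unsquared Euclidean input), so the algorithm is implemented here; tests check
it against ``scipy.cluster.hierarchy`` through the appropriate height
transform.

Supported linkages: ``single``, ``average``, ``centroid``, ``ward`` (the
Lance–Williams coefficients for squared-distance input).  Merge ties are
broken by the lexicographically smallest (cluster-id, cluster-id) pair, so
re-clustering perturbed data is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DendrogramTrace", "hclust_trace", "squared_distances", "cut_labels"]

LINKAGES = ("single", "average", "centroid", "ward")


def squared_distances(x: np.ndarray) -> np.ndarray:
    """Dense n x n matrix of pairwise squared Euclidean distances."""
    x = np.asarray(x, dtype=float)
    sq = np.einsum("ij,ij->i", x, x)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


@dataclass(frozen=True)
class DendrogramTrace:
    """Record of a full agglomerative clustering run plus a K-cluster cut.

    ``merges_id[l]`` is the (id, id) pair merged at step ``l`` (leaves have
    ids ``0..n-1``; the cluster created at step ``l`` has id ``n + l``);
    ``merges_slot[l]`` is the same merge in terms of internal array slots
    (the merged cluster keeps the first slot, the second dies) — this is what
    the truncation replay consumes.  ``labels`` is the K-cluster cut: labels
    are 0..K-1 in order of first row appearance.
    """

    linkage: str
    n: int
    K: int
    merges_id: tuple
    merges_slot: tuple
    heights: np.ndarray
    labels: np.ndarray

    @property
    def clusters(self) -> list[np.ndarray]:
        """Row indices of each of the K cut clusters, by label."""
        return [np.nonzero(self.labels == k)[0] for k in range(self.K)]


def _lw_update(linkage: str, d_uk, d_vk, d_uv, na: float, nb: float, nk):
    """Lance–Williams squared-distance update for merging clusters of size na, nb."""
    if linkage == "single":
        return np.minimum(d_uk, d_vk)
    if linkage == "average":
        return (na * d_uk + nb * d_vk) / (na + nb)
    if linkage == "centroid":
        s = na + nb
        return (na * d_uk + nb * d_vk) / s - (na * nb) * d_uv / (s * s)
    if linkage == "ward":
        tot = na + nb + nk
        return ((na + nk) * d_uk + (nb + nk) * d_vk - nk * d_uv) / tot
    raise ValueError(f"unknown linkage {linkage!r}")


def hclust_trace(x: np.ndarray, linkage: str, K: int) -> DendrogramTrace:
    """Agglomerate to a full dendrogram and cut at ``K`` clusters.

    Dissimilarity is the squared Euclidean distance throughout.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if not (2 <= K <= n):
        raise ValueError(f"need n >= K >= 2, got n={n}, K={K}")

    d = squared_distances(x)
    np.fill_diagonal(d, np.inf)
    alive = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    ids = np.arange(n)
    members: list[list[int]] = [[i] for i in range(n)]

    merges_id = []
    merges_slot = []
    heights = np.empty(n - 1)
    labels = None

    for step in range(n - 1):
        sub = np.nonzero(alive)[0]
        dd = d[np.ix_(sub, sub)]
        h = dd.min()
        # all minimizing pairs; break ties by smallest (id, id) pair
        cand = np.argwhere(dd <= h)
        cand = cand[cand[:, 0] < cand[:, 1]]
        pair_ids = np.sort(ids[sub[cand]], axis=1)
        best = np.lexsort((pair_ids[:, 1], pair_ids[:, 0]))[0]
        u, v = sorted((sub[cand[best, 0]], sub[cand[best, 1]]))

        heights[step] = h
        merges_id.append(tuple(int(t) for t in sorted((ids[u], ids[v]))))
        merges_slot.append((int(u), int(v)))

        others = alive.copy()
        others[[u, v]] = False
        ok = np.nonzero(others)[0]
        if ok.size:
            d_new = _lw_update(linkage, d[u, ok], d[v, ok], d[u, v], sizes[u], sizes[v], sizes[ok])
            d[u, ok] = d_new
            d[ok, u] = d_new
        alive[v] = False
        d[v, :] = np.inf
        d[:, v] = np.inf
        d[u, u] = np.inf
        sizes[u] += sizes[v]
        ids[u] = n + step
        members[u] = members[u] + members[v]

        if step == n - K - 1:
            labels = _labels_from_members([members[s] for s in np.nonzero(alive)[0]], n)

    if labels is None:  # K == n: no merges before the cut
        labels = np.arange(n)

    return DendrogramTrace(
        linkage=linkage,
        n=n,
        K=K,
        merges_id=tuple(merges_id),
        merges_slot=tuple(merges_slot),
        heights=heights,
        labels=labels,
    )


def _labels_from_members(groups: list[list[int]], n: int) -> np.ndarray:
    """Labels 0..K-1 assigned in order of each cluster's smallest row index."""
    groups = sorted(groups, key=min)
    labels = np.empty(n, dtype=int)
    for k, g in enumerate(groups):
        labels[g] = k
    return labels


def cut_labels(trace: DendrogramTrace, K: int) -> np.ndarray:
    """Re-cut a recorded dendrogram at a (possibly different) level ``K``."""
    n = trace.n
    if not (1 <= K <= n):
        raise ValueError("invalid cut level")
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (u, v) in trace.merges_slot[: n - K]:
        parent[find(v)] = find(u)
    roots = np.array([find(i) for i in range(n)])
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        groups.setdefault(r, []).append(i)
    return _labels_from_members(list(groups.values()), n)
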