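"""Exact truncation sets for hierarchical clustering.

The truncation set is ``S_j = {phi : clustering x'(phi) and cutting at K
reproduces the observed K-cluster partition}``.  Along the perturbation line
only rows with different contrast entries move relative to one another, so
every pairwise squared distance is an explicit quadratic in ``phi`` — and all
distances *within* a final (cut) cluster are constant in ``phi``, because the
contrast is constant on each final cluster.

That constancy gives an exact characterization: the observed merge sequence
up to the cut is reproduced on ``x'(phi)`` if and only if, at every step, no
candidate pair of clusters lying in two *different* final clusters attains a
linkage value below the step's observed merge height.  (Within-final
candidate linkage values never change and already lost to the winner; a
cross-final merge, once made, can never be undone, so it would change the cut
partition.)  The set is therefore the intersection of one quadratic
inequality per coexisting cross-final cluster pair, with the threshold equal
to the maximum merge height over the pair's coexistence window — ``O(n^2)``
inequalities in total.

Linkage values for average, centroid and Ward linkage are Lance–Williams
combinations of squared distances, so the replay maintains them directly as
quadratic coefficient triples.  Single linkage (a minimum, not a linear
combination) is expanded to one inequality per cross-final *row* pair, which
is equivalent and also ``O(n^2)``.
"""

from __future__ import annotations

import numpy as np

from .hierarchy import DendrogramTrace, squared_distances
from .intervals import IntervalUnion, intersect_leq_constraints
from .model import PerturbationLine

__all__ = ["perturbed_pair_coeffs", "hier_constraints", "hier_truncation_set", "TruncationError"]


class TruncationError(RuntimeError):
    """The observed data failed its own conditioning event — an internal bug."""


def _pairwise_quadratics(x: np.ndarray, line: PerturbationLine):
    """Coefficient matrices (A, B, C) of all pairwise squared distances.

    In the centered parameter ``psi = phi - phi_obs``:
    ``||x'_i(psi) - x'_k(psi)||^2 = A[i,k] psi^2 + B[i,k] psi + C[i,k]``.
    """
    x = np.asarray(x, dtype=float)
    w = line.direction
    gamma = line.contrast.nu / line.contrast.nu_sq_norm
    wn2 = float(w @ w)
    t = x @ w
    dg = gamma[:, None] - gamma[None, :]
    ds = t[:, None] - t[None, :]
    A = dg * dg * wn2
    B = 2.0 * dg * ds
    C = squared_distances(x)
    return A, B, C


def perturbed_pair_coeffs(
    x: np.ndarray, line: PerturbationLine, i: int, k: int
) -> tuple[float, float, float]:
    """Quadratic coefficients (a, b, c) of ``||x'_i(phi) - x'_k(phi)||^2`` in ``phi``.

    Constant cost per pair after the O(nq) precomputation of row inner
    products with the perturbation direction.
    """
    if i == k:
        raise ValueError("need two distinct rows")
    x = np.asarray(x, dtype=float)
    w = line.direction
    gamma = (line.contrast.nu[i] - line.contrast.nu[k]) / line.contrast.nu_sq_norm
    diff = x[i] - x[k]
    a = gamma * gamma * float(w @ w)
    b_psi = 2.0 * gamma * float(diff @ w)
    c_psi = float(diff @ diff)
    # shift from psi = phi - phi_obs to phi
    p = line.phi_obs
    return (a, b_psi - 2.0 * a * p, a * p * p - b_psi * p + c_psi)


def _constraints_single(trace: DendrogramTrace, A, B, C):
    """One inequality per cross-final row pair: distance >= max cut height."""
    n = trace.n
    n_steps = n - trace.K
    if n_steps == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    theta = float(np.max(trace.heights[:n_steps]))
    cross = trace.labels[:, None] != trace.labels[None, :]
    iu = np.triu(cross, k=1)
    return A[iu], B[iu], C[iu] - theta


def _constraints_lw(trace: DendrogramTrace, A, B, C):
    """Replay the merge sequence on coefficient triples (average/centroid/ward).

    Collects, for every cross-final cluster pair that ever coexists during
    the first ``n - K`` steps, the inequality
    ``linkage_value(phi) >= max observed merge height over the window``.
    """
    n = trace.n
    n_steps = n - trace.K
    A, B, C = A.copy(), B.copy(), C.copy()
    theta = np.full((n, n), -np.inf)
    alive = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    final = trace.labels.astype(int).copy()  # final-cluster id per slot

    ca, cb, cc = [], [], []

    def emit(slot, others):
        """Record constraints for the dying pairs (slot, each of others)."""
        if others.size == 0:
            return
        keep = (final[others] != final[slot]) & np.isfinite(theta[slot, others])
        o = others[keep]
        if o.size == 0:
            return
        ca.append(A[slot, o])
        cb.append(B[slot, o])
        cc.append(C[slot, o] - theta[slot, o])

    for step in range(n_steps):
        h = trace.heights[step]
        sub = np.nonzero(alive)[0]
        # every candidate pair at this step must stay >= h
        blk = theta[np.ix_(sub, sub)]
        np.maximum(blk, h, out=blk)
        theta[np.ix_(sub, sub)] = blk

        u, v = trace.merges_slot[step]
        others = sub[(sub != u) & (sub != v)]
        # pairs (u, k) and (v, k) end their windows here; (u, v) is the
        # within-final winner and needs no constraint
        emit(u, others)
        emit(v, others)

        if others.size:
            na, nb, nk = sizes[u], sizes[v], sizes[others]
            for M in (A, B, C):
                d_new = _lw(trace.linkage, M[u, others], M[v, others], M[u, v], na, nb, nk)
                M[u, others] = d_new
                M[others, u] = d_new
        alive[v] = False
        sizes[u] += sizes[v]
        theta[u, :] = -np.inf
        theta[:, u] = -np.inf

    # surviving cross-final pairs (the K cut clusters)
    sub = np.nonzero(alive)[0]
    for ii, slot in enumerate(sub):
        others = sub[ii + 1 :]
        emit(slot, others)

    if not ca:
        return np.empty(0), np.empty(0), np.empty(0)
    return np.concatenate(ca), np.concatenate(cb), np.concatenate(cc)


def _lw(linkage, d_uk, d_vk, d_uv, na, nb, nk):
    if linkage == "average":
        return (na * d_uk + nb * d_vk) / (na + nb)
    if linkage == "centroid":
        s = na + nb
        return (na * d_uk + nb * d_vk) / s - (na * nb) * d_uv / (s * s)
    if linkage == "ward":
        tot = na + nb + nk
        return ((na + nk) * d_uk + (nb + nk) * d_vk - nk * d_uv) / tot
    raise ValueError(f"linkage {linkage!r} has no Lance-Williams triple update")


def hier_constraints(
    x: np.ndarray, trace: DendrogramTrace, line: PerturbationLine
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficient arrays of the ``quad(psi) >= 0`` conditioning inequalities.

    ``psi = phi - phi_obs``.  One triple per binding candidate-pair event;
    the truncation set is the intersection of their solution sets.
    """
    A, B, C = _pairwise_quadratics(x, line)
    if trace.linkage == "single":
        return _constraints_single(trace, A, B, C)
    return _constraints_lw(trace, A, B, C)


def hier_truncation_set(
    x: np.ndarray, trace: DendrogramTrace, line: PerturbationLine
) -> IntervalUnion:
    """The set of ``phi`` whose perturbed data re-cluster to the observed cut.

    Returns an :class:`IntervalUnion` in the original ``phi`` scale.  The
    observed statistic always belongs to the result; an empty result raises
    :class:`TruncationError`.
    """
    a, b, c = hier_constraints(x, trace, line)

    scale = 1.0 + abs(line.phi_obs)
    if a.size == 0:
        s_psi = IntervalUnion.reals()
    else:
        # constraint: quadratic >= theta  <=>  -(A psi^2 + B psi + (C - theta)) <= 0
        s_psi = intersect_leq_constraints(-a, -b, -c, tol_merge=1e-9 * scale)
    s = s_psi.shift(line.phi_obs)
    if not s.contains(line.phi_obs, tol=1e-8 * scale):
        raise TruncationError(
            "observed statistic not in its own hierarchical conditioning set"
        )
    return s
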