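"""Exact solution sets of quadratic inequalities and finite unions of intervals.

The conditioning events of the selective tests are intersections of many
solution sets of scalar quadratic inequalities in the perturbation parameter
``phi``.  This module provides the two primitives those computations need:

* :func:`solve_quadratic` — the exact solution set of ``a*phi^2 + b*phi + c``
  compared against zero, covering all degeneracies (linear, constant, zero or
  negative discriminant);
* :class:`IntervalUnion` and :func:`intersect_all` — a canonical finite union
  of disjoint closed intervals on the extended real line, with an
  endpoint-sweep intersection that is ``O(N log N)`` in the total number of
  intervals.

Intervals are closed: conditioning events are closed by continuity of the
clustering criteria, and the boundary has measure zero under the Gaussian
reference distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "QuadraticInequality",
    "IntervalUnion",
    "solve_quadratic",
    "solve_quadratics_leq",
    "intersect_all",
]

#: |a| below tol_coef * max(|a|,|b|,|c|,1) is treated as a vanished coefficient.
TOL_COEF = 1e-10


@dataclass(frozen=True)
class QuadraticInequality:
    """``a*phi**2 + b*phi + c  (<= or >=)  0``.

    ``sense`` is "le" (<= 0) or "ge" (>= 0).
    """

    a: float
    b: float
    c: float
    sense: str = "le"

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c):
            if not math.isfinite(v):
                raise ValueError("quadratic coefficients must be finite")
        if self.sense not in ("le", "ge"):
            raise ValueError(f"sense must be 'le' or 'ge', got {self.sense!r}")

    def __call__(self, phi: float) -> float:
        return (self.a * phi + self.b) * phi + self.c


class IntervalUnion:
    """A finite union of disjoint closed intervals, sorted by lower endpoint.

    The empty list encodes the empty set; the single pair ``(-inf, inf)``
    encodes the whole real line.  Construction canonicalizes: intervals are
    sorted and any two separated by a gap <= ``tol_merge`` are merged.
    """

    __slots__ = ("bounds",)

    def __init__(self, intervals: Iterable[Sequence[float]] = (), tol_merge: float = 0.0):
        arr = np.asarray(list(intervals), dtype=float)
        if arr.size == 0:
            self.bounds = np.empty((0, 2), dtype=float)
            return
        arr = arr.reshape(-1, 2)
        if np.any(np.isnan(arr)):
            raise ValueError("NaN interval endpoint")
        arr = arr[arr[:, 0] <= arr[:, 1]]
        if arr.shape[0] == 0:
            self.bounds = np.empty((0, 2), dtype=float)
            return
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        merged = [list(arr[0])]
        for lo, hi in arr[1:]:
            if lo <= merged[-1][1] + tol_merge:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        self.bounds = np.array(merged, dtype=float)

    # -- constructors ---------------------------------------------------
    @classmethod
    def empty(cls) -> "IntervalUnion":
        return cls(())

    @classmethod
    def reals(cls) -> "IntervalUnion":
        return cls([(-np.inf, np.inf)])

    # -- predicates -----------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.bounds.shape[0] == 0

    @property
    def is_reals(self) -> bool:
        return (
            self.bounds.shape[0] == 1
            and self.bounds[0, 0] == -np.inf
            and self.bounds[0, 1] == np.inf
        )

    @property
    def n_intervals(self) -> int:
        return self.bounds.shape[0]

    def contains(self, phi: float, tol: float = 0.0) -> bool:
        """Membership with endpoint tolerance ``tol``."""
        if self.is_empty:
            return False
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return bool(np.any((phi >= lo - tol) & (phi <= hi + tol)))

    # -- algebra ---------------------------------------------------------
    def shift(self, delta: float) -> "IntervalUnion":
        out = IntervalUnion.empty()
        out.bounds = self.bounds + delta
        return out

    def scale(self, c: float) -> "IntervalUnion":
        """Image under multiplication by a positive constant."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        out = IntervalUnion.empty()
        out.bounds = self.bounds * c
        return out

    def intersect(self, other: "IntervalUnion") -> "IntervalUnion":
        return intersect_all([self, other])

    def to_pairs(self) -> list[tuple[float, float]]:
        return [tuple(row) for row in self.bounds]

    # -- dunder ----------------------------------------------------------
    def __iter__(self):
        return iter(self.to_pairs())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalUnion):
            return NotImplemented
        return self.bounds.shape == other.bounds.shape and np.array_equal(
            self.bounds, other.bounds
        )

    def approx_equal(self, other: "IntervalUnion", tol: float = 1e-8) -> bool:
        if self.bounds.shape != other.bounds.shape:
            return False
        if self.bounds.size == 0:
            return True
        a, b = self.bounds, other.bounds
        finite = np.isfinite(a) & np.isfinite(b)
        if not np.array_equal(np.isfinite(a), np.isfinite(b)):
            return False
        if not np.array_equal(np.sign(a[~np.isfinite(a)]), np.sign(b[~np.isfinite(b)])):
            return False
        return bool(np.all(np.abs(a[finite] - b[finite]) <= tol))

    def __repr__(self) -> str:
        if self.is_empty:
            return "IntervalUnion(∅)"
        parts = ", ".join(f"[{lo:.6g}, {hi:.6g}]" for lo, hi in self.bounds)
        return f"IntervalUnion({parts})"


def _classify(a: float, b: float, c: float) -> tuple[bool, bool]:
    """Return (a_is_zero, b_is_zero) using the relative coefficient tolerance."""
    scale = max(abs(a), abs(b), abs(c), 1.0)
    return abs(a) <= TOL_COEF * scale, abs(b) <= TOL_COEF * scale


def solve_quadratic(q: QuadraticInequality) -> IntervalUnion:
    """Exact solution set of a quadratic inequality in one scalar variable.

    All inequalities are normalized to sense <= 0 before solving; finite
    roots produce closed endpoints.
    """
    a, b, c = q.a, q.b, q.c
    if q.sense == "ge":
        a, b, c = -a, -b, -c
    return _solve_leq(a, b, c)


def _solve_leq(a: float, b: float, c: float) -> IntervalUnion:
    a0, b0 = _classify(a, b, c)
    if a0 and b0:
        # constant: c <= 0 (tolerant so exactly-binding constraints pass)
        scale = max(abs(a), abs(b), abs(c), 1.0)
        return IntervalUnion.reals() if c <= TOL_COEF * scale else IntervalUnion.empty()
    if a0:
        r = -c / b
        return IntervalUnion([(-np.inf, r)]) if b > 0 else IntervalUnion([(r, np.inf)])
    disc = b * b - 4.0 * a * c
    tol_disc = TOL_COEF * max(b * b, abs(4.0 * a * c), 1e-300)
    if disc <= tol_disc:
        if a > 0:
            if disc >= -tol_disc:  # double root: single point
                r = -b / (2.0 * a)
                return IntervalUnion([(r, r)])
            return IntervalUnion.empty()
        return IntervalUnion.reals()
    sq = math.sqrt(disc)
    # numerically stable root pair
    t = -0.5 * (b + math.copysign(sq, b))
    r1, r2 = t / a, (c / t if t != 0.0 else 0.0)
    lo, hi = min(r1, r2), max(r1, r2)
    if a > 0:
        return IntervalUnion([(lo, hi)])
    return IntervalUnion([(-np.inf, lo), (hi, np.inf)])


def solve_quadratics_leq(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> list | None:
    """Vectorized solution sets of many ``a x^2 + b x + c <= 0`` constraints.

    Returns a list of ``(lo, hi)`` interval arrays, one union per constraint
    flattened into a single list of (constraint_index, lo, hi) triples packed
    as three arrays, or ``None`` if some constraint is unsatisfiable (empty
    overall intersection is then certain).

    Output: ``(idx, lo, hi)`` arrays suitable for the coverage sweep in
    :func:`_sweep_intersection`; constraints whose solution set is all of R
    are dropped (they never bind).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    n = a.shape[0]
    scale = np.maximum.reduce([np.abs(a), np.abs(b), np.abs(c), np.ones(n)])
    a0 = np.abs(a) <= TOL_COEF * scale
    b0 = np.abs(b) <= TOL_COEF * scale

    idx_list: list[np.ndarray] = []
    lo_list: list[np.ndarray] = []
    hi_list: list[np.ndarray] = []
    n_constraints = 0  # constraints contributing intervals (non-R)

    # constant cases
    const = a0 & b0
    if np.any(const & (c > TOL_COEF * scale)):
        return None  # some constraint is infeasible everywhere
    # constants with c<=tol are all of R: drop.

    # linear cases
    lin = a0 & ~b0
    if np.any(lin):
        i = np.nonzero(lin)[0]
        r = -c[i] / b[i]
        pos = b[i] > 0
        lo = np.where(pos, -np.inf, r)
        hi = np.where(pos, r, np.inf)
        idx_list.append(np.arange(n_constraints, n_constraints + i.size))
        lo_list.append(lo)
        hi_list.append(hi)
        n_constraints += i.size

    quad = ~a0
    if np.any(quad):
        i = np.nonzero(quad)[0]
        ai, bi, ci = a[i], b[i], c[i]
        disc = bi * bi - 4.0 * ai * ci
        tol_disc = TOL_COEF * np.maximum(np.maximum(bi * bi, np.abs(4.0 * ai * ci)), 1e-300)
        up = ai > 0

        # upward parabola, negative discriminant -> empty set -> infeasible
        if np.any(up & (disc < -tol_disc)):
            return None
        # downward parabola, disc <= tol -> all of R: drop
        keep_dn = ~up & (disc > tol_disc)
        keep_up = up  # disc >= -tol here

        with np.errstate(invalid="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
        t = -0.5 * (bi + np.where(bi >= 0, sq, -sq))
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = np.where(t != 0.0, t / ai, -bi / (2.0 * ai))
            r2 = np.where(t != 0.0, ci / np.where(t != 0.0, t, 1.0), -bi / (2.0 * ai))
        rlo = np.minimum(r1, r2)
        rhi = np.maximum(r1, r2)

        if np.any(keep_up):
            k = np.nonzero(keep_up)[0]
            idx_list.append(np.arange(n_constraints, n_constraints + k.size))
            lo_list.append(rlo[k])
            hi_list.append(rhi[k])
            n_constraints += k.size
        if np.any(keep_dn):
            k = np.nonzero(keep_dn)[0]
            new_idx = np.arange(n_constraints, n_constraints + k.size)
            # two intervals per constraint, same index
            idx_list.append(np.repeat(new_idx, 2))
            lo2 = np.empty(2 * k.size)
            hi2 = np.empty(2 * k.size)
            lo2[0::2] = -np.inf
            hi2[0::2] = rlo[k]
            lo2[1::2] = rhi[k]
            hi2[1::2] = np.inf
            lo_list.append(lo2)
            hi_list.append(hi2)
            n_constraints += k.size

    if n_constraints == 0:
        return [np.empty(0, dtype=int), np.empty(0), np.empty(0), 0]
    return [
        np.concatenate(idx_list),
        np.concatenate(lo_list),
        np.concatenate(hi_list),
        n_constraints,
    ]


def _sweep_intersection(
    lo: np.ndarray, hi: np.ndarray, n_required: int, tol_merge: float
) -> IntervalUnion:
    """Intersection of ``n_required`` interval unions by coverage counting.

    Each input union's intervals are internally disjoint, so a point lies in
    the intersection iff its coverage count equals ``n_required``.  Starts are
    processed before ends at equal coordinates, so closed-interval touching
    (including singleton solutions) is handled.
    """
    m = lo.size
    coords = np.concatenate([lo, hi])
    # starts get delta +1 and sort-priority 0; ends delta -1, priority 1
    deltas = np.concatenate([np.ones(m, dtype=np.int64), -np.ones(m, dtype=np.int64)])
    prio = np.concatenate([np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)])
    order = np.lexsort((prio, coords))
    coords = coords[order]
    deltas = deltas[order]
    counts = np.cumsum(deltas)

    out: list[tuple[float, float]] = []
    open_lo: float | None = None
    for x, cnt in zip(coords, counts):
        if cnt == n_required and open_lo is None:
            open_lo = x
        elif cnt < n_required and open_lo is not None:
            out.append((open_lo, x))
            open_lo = None
    if open_lo is not None:  # only possible if everything extends to +inf
        out.append((open_lo, np.inf))
    return IntervalUnion(out, tol_merge=tol_merge)


def intersect_all(sets: Sequence[IntervalUnion], tol_merge: float = 0.0) -> IntervalUnion:
    """Intersection of interval unions via an endpoint sweep, O(N log N)."""
    sets = list(sets)
    if not sets:
        return IntervalUnion.reals()
    non_trivial = [s for s in sets if not s.is_reals]
    if not non_trivial:
        return IntervalUnion.reals()
    if any(s.is_empty for s in non_trivial):
        return IntervalUnion.empty()
    if len(non_trivial) == 1:
        return non_trivial[0]
    lo = np.concatenate([s.bounds[:, 0] for s in non_trivial])
    hi = np.concatenate([s.bounds[:, 1] for s in non_trivial])
    return _sweep_intersection(lo, hi, len(non_trivial), tol_merge)


def intersect_leq_constraints(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, tol_merge: float = 0.0
) -> IntervalUnion:
    """Intersection of the solution sets of many ``<= 0`` quadratics at once."""
    packed = solve_quadratics_leq(a, b, c)
    if packed is None:
        return IntervalUnion.empty()
    idx, lo, hi, n_constraints = packed
    if n_constraints == 0:
        return IntervalUnion.reals()
    # drop intervals that are individually empty (lo > hi cannot occur here)
    del idx  # indices not needed: each union's intervals are disjoint by construction
    return _sweep_intersection(lo, hi, n_constraints, tol_merge)
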