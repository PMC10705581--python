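"""Numerically stable truncated-Gaussian CDF and the two-sided selective p-value.

Conditioning sets produced by the truncation machinery routinely sit many
standard deviations from the null mean, where naive CDF differences underflow
to 0/0.  All interval masses here are therefore computed in log space from
``scipy``'s log-CDF / log-survival functions, taking the side nearer the mean,
and accumulated with log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .intervals import IntervalUnion

__all__ = ["TruncatedGaussian", "trunc_cdf", "selective_p", "DegenerateSupportError"]


class DegenerateSupportError(ValueError):
    """The truncation set carries (numerically) no Gaussian mass."""


def _log1mexp(a: np.ndarray) -> np.ndarray:
    """log(1 - exp(a)) for a <= 0, stable near both ends."""
    a = np.minimum(a, -0.0)
    with np.errstate(divide="ignore"):
        return np.where(a < -0.6931471805599453, np.log1p(-np.exp(a)), np.log(-np.expm1(a)))


def _log_interval_mass(zlo: np.ndarray, zhi: np.ndarray) -> np.ndarray:
    """log P(zlo <= Z <= zhi) for standard normal Z, elementwise.

    Uses the survival function on the right half-line and the CDF on the
    left so that intervals deep in either tail keep full relative precision.
    """
    zlo = np.asarray(zlo, dtype=float)
    zhi = np.asarray(zhi, dtype=float)
    out = np.full(zlo.shape, -np.inf)
    bad = zhi < zlo
    right = (zlo >= 0) & ~bad  # both ends in the right tail
    left = (zhi <= 0) & ~bad  # both ends in the left tail
    mid = ~right & ~left & ~bad

    # -inf - -inf = nan below marks true log-space underflow; it propagates to
    # the total mass and triggers the degenerate-support error upstream
    with np.errstate(invalid="ignore"):
        if np.any(right):
            lo, hi = zlo[right], zhi[right]
            ls_lo = norm.logsf(lo)
            ls_hi = norm.logsf(hi)
            out[right] = ls_lo + _log1mexp(ls_hi - ls_lo)
        if np.any(left):
            lo, hi = zlo[left], zhi[left]
            lc_hi = norm.logcdf(hi)
            lc_lo = norm.logcdf(lo)
            out[left] = lc_hi + _log1mexp(lc_lo - lc_hi)
    if np.any(mid):
        lo, hi = zlo[mid], zhi[mid]
        # straddles the mean: mass >= Phi(min(|lo|,|hi|)) - 1/2, no underflow
        mass = 1.0 - norm.cdf(lo) - norm.sf(hi)
        with np.errstate(divide="ignore"):
            out[mid] = np.log(np.maximum(mass, 0.0))
    return out


@dataclass(frozen=True)
class TruncatedGaussian:
    """A ``N(mean, sd^2)`` distribution restricted to an interval union."""

    mean: float
    sd: float
    support: IntervalUnion

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("sd must be positive")
        if self.support.is_empty:
            raise DegenerateSupportError("empty truncation set")

    def _z(self, t) -> np.ndarray:
        return (np.asarray(t, dtype=float) - self.mean) / self.sd

    def log_mass(self) -> float:
        """log of the total Gaussian mass of the support.

        Arbitrarily small masses are routine (a strong signal puts the
        conditioning set far into the null tail) and remain representable in
        log space; the error fires only on true log-space underflow, which
        contradicts the contract that the observed statistic lies in its own
        conditioning set.
        """
        z = self._z(self.support.bounds)
        lm = float(logsumexp(_log_interval_mass(z[:, 0], z[:, 1])))
        if not np.isfinite(lm):
            raise DegenerateSupportError(
                f"truncation set carries no numerically representable mass (log mass {lm}); "
                "the observed statistic should always lie in its own conditioning set"
            )
        return lm


def trunc_cdf(t: float, tg: TruncatedGaussian) -> float:
    """CDF of the truncated Gaussian at ``t``: ``P(Z <= t, Z in S) / P(Z in S)``."""
    denom = tg.log_mass()
    b = tg.support.bounds
    zt = float(tg._z(t))
    zlo = tg._z(b[:, 0])
    zhi = np.minimum(tg._z(b[:, 1]), zt)
    keep = zhi >= zlo
    if not np.any(keep):
        return 0.0
    num = float(logsumexp(_log_interval_mass(zlo[keep], zhi[keep])))
    return float(min(1.0, np.exp(num - denom)))


def selective_p(z: float, sd: float, support: IntervalUnion) -> float:
    """Two-sided selective p-value: ``P(|Z| >= |z| | Z in S)`` for ``Z ~ N(0, sd^2)``.

    Computed directly as the mass of ``S ∩ {|phi| >= |z|}`` over the mass of
    ``S``, entirely in log space (more stable than ``1 - F(|z|) + F(-|z|)``
    when the support sits in a far tail).

    The observed statistic must belong to the support; a violation signals a
    bug in the upstream truncation-set computation and raises.
    """
    tg = TruncatedGaussian(mean=0.0, sd=sd, support=support)
    tol = 1e-8 * (1.0 + abs(z))
    if not support.contains(z, tol=tol):
        raise ValueError(
            f"observed statistic {z!r} lies outside the truncation set {support!r}"
        )
    denom = tg.log_mass()
    az = abs(z)
    b = support.bounds / sd
    za = az / sd

    # right tail: S ∩ [|z|, inf)
    rlo = np.maximum(b[:, 0], za)
    rhi = b[:, 1]
    # left tail: S ∩ (-inf, -|z|]
    llo = b[:, 0]
    lhi = np.minimum(b[:, 1], -za)
    zlos = np.concatenate([rlo, llo])
    zhis = np.concatenate([rhi, lhi])
    keep = zhis >= zlos
    if not np.any(keep):
        return 0.0
    num = float(logsumexp(_log_interval_mass(zlos[keep], zhis[keep])))
    return float(min(1.0, np.exp(num - denom)))
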