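"""Sampling model, cluster-pair contrasts, and the one-parameter perturbation.

The data are modelled as ``n`` independent rows ``X_i ~ N_q(mu_i, Sigma)``
with a known (or plugged-in) feature covariance ``Sigma``.  Testing whether
feature ``j`` has equal means between two groups ``G`` and ``G'`` is a test of
``nu' mu[:, j] = 0`` for the contrast vector ``nu`` with entries ``1/|G|`` on
``G``, ``-1/|G'|`` on ``G'`` and zero elsewhere.

The selective test conditions on everything about the data except the scalar
statistic ``phi = mean_G(x_j) - mean_G'(x_j)``.  Sliding that statistic while
holding the orthogonalized remainder fixed traces out the one-parameter family

    x'(phi) = x + (phi - phi_obs) * (nu / ||nu||^2) (Sigma_j / Sigma_jj)^T,

where ``Sigma_j`` is the j-th column of the covariance.  Every conditioning
event downstream (re-clustering agreement) is a constraint on ``phi`` along
this line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianModel",
    "TestSpec",
    "Contrast",
    "PerturbationLine",
    "contrast_vector",
    "contrast_from_labels",
    "test_statistic",
    "perturbation_line",
    "perturb_data",
]

#: relative eigenvalue tolerance for positive-definiteness checks
PD_TOL = 1e-8


class InvalidSpecError(ValueError):
    """Raised when a test specification is inconsistent with the data."""


@dataclass(frozen=True)
class GaussianModel:
    """Row-independent Gaussian sampling model: ``X_i ~ N_q(mu[i], sigma)``.

    Parameters
    ----------
    mu : (n, q) array
        Per-observation mean vectors, in the units of the data.
    sigma : (q, q) array
        Feature covariance, shared across observations; must be symmetric
        positive definite.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        validate_covariance(sigma)
        if mu.shape[1] != sigma.shape[0]:
            raise ValueError(
                f"mu has {mu.shape[1]} columns but sigma is {sigma.shape[0]}-dimensional"
            )

    @property
    def n(self) -> int:
        return self.mu.shape[0]

    @property
    def q(self) -> int:
        return self.mu.shape[1]

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One draw of the full data matrix."""
        chol = np.linalg.cholesky(self.sigma)
        z = rng.standard_normal(self.mu.shape)
        return self.mu + z @ chol.T


def validate_covariance(sigma: np.ndarray) -> None:
    """Check symmetry and positive definiteness via eigendecomposition."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(sigma, sigma.T, rtol=0, atol=1e-10 * (1 + np.abs(sigma).max())):
        raise ValueError("covariance must be symmetric")
    ev = np.linalg.eigvalsh(sigma)
    if ev[0] <= PD_TOL * max(ev[-1], 0.0):
        raise ValueError(f"covariance is not positive definite (min eigenvalue {ev[0]:.3g})")


@dataclass(frozen=True)
class TestSpec:
    """A tested cluster pair and feature, with 0-based indices.

    ``group_a`` / ``group_b`` are disjoint, non-empty index sets into the
    rows; ``feature`` indexes a column.  (The command-line interface uses
    1-based indices and converts at the boundary.)
    """

    group_a: frozenset
    group_b: frozenset
    feature: int

    def __init__(self, group_a, group_b, feature: int):
        object.__setattr__(self, "group_a", frozenset(int(i) for i in group_a))
        object.__setattr__(self, "group_b", frozenset(int(i) for i in group_b))
        object.__setattr__(self, "feature", int(feature))
        if not self.group_a or not self.group_b:
            raise InvalidSpecError("both groups must be non-empty")
        if self.group_a & self.group_b:
            raise InvalidSpecError("groups must be disjoint")

    def validate(self, n: int, q: int) -> None:
        idx = self.group_a | self.group_b
        if min(idx) < 0 or max(idx) >= n:
            raise InvalidSpecError(f"group indices out of range for n={n}")
        if not (0 <= self.feature < q):
            raise InvalidSpecError(f"feature {self.feature} out of range for q={q}")


@dataclass(frozen=True)
class Contrast:
    """The contrast vector encoding a difference in group means.

    ``nu[i] = 1/|G| for i in G, -1/|G'| for i in G', else 0``, so that
    ``nu @ x[:, j]`` is the difference in feature-``j`` group means.
    ``nu_sq_norm = 1/|G| + 1/|G'|`` exactly.
    """

    nu: np.ndarray
    nu_sq_norm: float


def contrast_vector(n: int, spec: TestSpec) -> Contrast:
    """Build the group-mean-difference contrast for ``n`` observations."""
    spec.validate(n, spec.feature + 1)
    nu = np.zeros(n)
    a = sorted(spec.group_a)
    b = sorted(spec.group_b)
    nu[a] = 1.0 / len(a)
    nu[b] = -1.0 / len(b)
    return Contrast(nu=nu, nu_sq_norm=1.0 / len(a) + 1.0 / len(b))


def contrast_from_labels(labels: np.ndarray, a: int, b: int, feature: int = 0) -> tuple[Contrast, TestSpec]:
    """Contrast for the pair of clusters labelled ``a`` and ``b``."""
    labels = np.asarray(labels)
    ga = np.nonzero(labels == a)[0]
    gb = np.nonzero(labels == b)[0]
    if ga.size == 0 or gb.size == 0:
        raise InvalidSpecError(f"cluster labels {a} and {b} must both be present")
    spec = TestSpec(ga, gb, feature)
    return contrast_vector(labels.size, spec), spec


def test_statistic(x: np.ndarray, contrast: Contrast, j: int) -> float:
    """Difference in group means of feature ``j``: ``nu @ x[:, j]``."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != contrast.nu.shape[0]:
        raise ValueError("row count does not match contrast length")
    return float(contrast.nu @ x[:, j])


@dataclass(frozen=True)
class PerturbationLine:
    """The one-parameter family ``x'(phi)`` along which conditioning happens.

    Attributes
    ----------
    phi_obs : float
        Observed statistic (difference in group means of the tested feature).
    direction : (q,) array
        ``Sigma[:, j] / Sigma[j, j]``; its j-th entry is exactly 1, so the
        tested feature's statistic moves one-for-one with ``phi`` while
        correlated features co-move proportionally.
    contrast : Contrast
    j : int
        Tested feature (0-based).
    """

    phi_obs: float
    direction: np.ndarray
    contrast: Contrast
    j: int


def perturbation_line(x: np.ndarray, sigma: np.ndarray, contrast: Contrast, j: int) -> PerturbationLine:
    """Construct the perturbation family for testing feature ``j``."""
    sigma = np.asarray(sigma, dtype=float)
    direction = sigma[:, j] / sigma[j, j]
    phi_obs = test_statistic(x, contrast, j)
    return PerturbationLine(phi_obs=phi_obs, direction=direction, contrast=contrast, j=j)


def perturb_data(x: np.ndarray, line: PerturbationLine, phi: float) -> np.ndarray:
    """Evaluate ``x'(phi)``.

    Satisfies: the statistic of the perturbed data in the tested feature is
    ``phi``; at ``phi = phi_obs`` the original matrix is returned; rows with a
    zero contrast entry never move; and for any other feature ``j'`` the
    statistic shifts by ``(phi - phi_obs) * Sigma[j, j'] / Sigma[j, j]``.
    """
    x = np.asarray(x, dtype=float)
    nu = line.contrast.nu
    step = (phi - line.phi_obs) / line.contrast.nu_sq_norm
    return x + step * np.outer(nu, line.direction)
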