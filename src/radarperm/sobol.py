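"""Polynomial-chaos projection and Sobol' sensitivity indices.

The adaptive estimator needs to know how sensitive the fitness surface is
to each parameter.  Hierarchical collocation alone cannot say, but a
polynomial-chaos (PC) expansion can: projecting the current interpolant
onto an orthonormal shifted-Legendre basis (uniform measure on [0, 1]^d)
turns its variance into a sum of squared coefficients, and summing the
squares over the tuples involving a given dimension yields that
dimension's total-effect Sobol' index.  Total-effect (rather than
first-order) indices are used for steering so a dimension active only
through interactions is never starved of refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from numpy.polynomial import legendre

__all__ = ["PCExpansion", "SobolIndices", "project_to_pc", "sobol_from_pc"]

DEFAULT_ORDER = 8
DEFAULT_QUADRATURE_POINTS = 12


@dataclass(frozen=True)
class PCExpansion:
    """Truncated PC expansion in orthonormal shifted Legendre polynomials.

    ``coefficients`` maps per-dimension degree tuples (total degree <=
    ``order``) to expansion coefficients.  The zero tuple carries the mean
    under the uniform measure; the total variance is the sum of the squared
    non-constant coefficients.
    """

    dimension: int
    order: int
    coefficients: dict[tuple[int, ...], float]

    @property
    def mean(self) -> float:
        return self.coefficients[(0,) * self.dimension]

    @property
    def total_variance(self) -> float:
        return sum(
            c**2 for k, c in self.coefficients.items() if any(d > 0 for d in k)
        )


@dataclass(frozen=True)
class SobolIndices:
    """Per-dimension total-effect Sobol' indices, plus a max-normalised copy."""

    total_index: np.ndarray
    normalized_index: np.ndarray


def _shifted_legendre(degree: int, x: np.ndarray) -> np.ndarray:
    """Orthonormal Legendre polynomial of ``degree`` on [0, 1]."""
    coeffs = np.zeros(degree + 1)
    coeffs[degree] = 1.0
    return np.sqrt(2 * degree + 1) * legendre.legval(2.0 * x - 1.0, coeffs)


def project_to_pc(
    interpolant,
    order: int = DEFAULT_ORDER,
    quadrature_level: int = DEFAULT_QUADRATURE_POINTS,
) -> PCExpansion:
    """Project a function on [0, 1]^d onto the PC basis by quadrature.

    ``interpolant`` is anything exposing ``dimension`` and an
    ``evaluate((n, d) array) -> (n,)`` method.  Coefficients are computed
    with a tensor Gauss-Legendre rule of ``quadrature_level`` points per
    dimension (exact for polynomial integrands up to degree
    ``2 * quadrature_level - 1``); all tuples with total degree <= ``order``
    are retained.
    """
    if order < 1:
        raise ValueError("PC order must be >= 1")
    d = interpolant.dimension
    # Gauss-Legendre on [0, 1]: rescale the [-1, 1] rule.
    x, w = legendre.leggauss(quadrature_level)
    x01 = (x + 1.0) / 2.0
    w01 = w / 2.0

    grids = np.meshgrid(*([x01] * d), indexing="ij")
    points = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([w01] * d), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)

    values = np.atleast_1d(interpolant.evaluate(points))

    # 1D basis values at quadrature points, per degree: (order+1, q)
    psi_1d = np.array([_shifted_legendre(n, x01) for n in range(order + 1)])

    coefficients: dict[tuple[int, ...], float] = {}
    weighted = weights * values
    for degrees in product(range(order + 1), repeat=d):
        if sum(degrees) > order:
            continue
        basis = np.ones(points.shape[0])
        for k, n in enumerate(degrees):
            if n > 0:
                basis = basis * psi_1d[n][_axis_index(points.shape[0], quadrature_level, d, k)]
        coefficients[degrees] = float(weighted @ basis)
    return PCExpansion(dimension=d, order=order, coefficients=coefficients)


def _axis_index(n_points: int, q: int, d: int, axis: int) -> np.ndarray:
    """Indices into a per-axis 1D array for the flattened tensor grid."""
    idx = np.arange(n_points)
    return (idx // q ** (d - 1 - axis)) % q


def sobol_from_pc(expansion: PCExpansion) -> SobolIndices:
    """Total-effect Sobol' indices from a PC expansion.

    ``total_index[i]`` is the squared-coefficient mass of every tuple with
    nonzero degree in dimension i, divided by the total variance, so
    interaction terms count toward every participating dimension.  The
    normalised copy divides by the largest index; a zero-variance
    expansion yields all-ones (no dimension preferred).
    """
    d = expansion.dimension
    var = expansion.total_variance
    if var <= 0:
        ones = np.ones(d)
        return SobolIndices(total_index=ones.copy(), normalized_index=ones)
    total = np.zeros(d)
    for k, c in expansion.coefficients.items():
        if all(deg == 0 for deg in k):
            continue
        for i, deg in enumerate(k):
            if deg > 0:
                total[i] += c**2
    total /= var
    return SobolIndices(total_index=total, normalized_index=total / total.max())


def first_order_indices(expansion: PCExpansion) -> np.ndarray:
    """First-order Sobol' indices (variance from each dimension alone)."""
    d = expansion.dimension
    var = expansion.total_variance
    if var <= 0:
        return np.ones(d)
    first = np.zeros(d)
    for k, c in expansion.coefficients.items():
        active = [i for i, deg in enumerate(k) if deg > 0]
        if len(active) == 1:
            first[active[0]] += c**2
    return first / var
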