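"""B-spline bases and difference penalties for Bayesian P-splines.

The nonlinear age effect is modelled as a penalized B-spline: a basis of
``n_interior_knots + degree + 1`` B-splines on equidistant knots spanning
the observed age range, with a Gaussian random-walk prior on the
coefficients whose precision is ``tau * K`` for the r-th order difference
penalty K = D_r' D_r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "PenaltyMatrix", "build_bspline_basis",
           "difference_penalty"]


@dataclass(frozen=True)
class SplineBasis:
    degree: int
    n_interior_knots: int
    knot_vector: np.ndarray  # full knot vector incl. boundary extension
    basis_matrix: np.ndarray  # n_obs x m
    penalty_order: int = 2

    @property
    def n_basis(self) -> int:
        return self.basis_matrix.shape[1]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Basis matrix at new points (clipped to the knot span interior)."""
        return _design(np.asarray(x, dtype=float), self.knot_vector,
                       self.degree)


def _design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(x, lo, np.nextafter(hi, lo))
    B = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
    # right-boundary points belong to the last interval; restore exact hi
    at_hi = x >= hi
    if np.any(at_hi):
        row = BSpline.design_matrix(
            np.array([np.nextafter(hi, lo)]), knots, degree,
            extrapolate=False).toarray()[0]
        B[at_hi] = row
        # exact partition of unity at the right boundary
        B[at_hi, -1] += 1.0 - row.sum()
    return B


def build_bspline_basis(
    ages: np.ndarray, degree: int = 3, n_interior_knots: int = 20,
    penalty_order: int = 2,
) -> SplineBasis:
    """Equidistant-knot B-spline basis over the observed age range.

    ``n_interior_knots`` counts the knots strictly inside (min, max); the
    boundary knots are repeated ``degree + 1`` times (clamped), giving
    ``m = n_interior_knots + degree + 1`` basis functions whose rows sum to
    one (partition of unity).
    """
    ages = np.asarray(ages, dtype=float)
    if n_interior_knots < 1:
        raise ValueError("n_interior_knots must be >= 1")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    lo, hi = float(ages.min()), float(ages.max())
    if hi <= lo:
        raise ValueError("degenerate age range: all ages equal")
    interior = np.linspace(lo, hi, n_interior_knots + 2)[1:-1]
    knots = np.concatenate([
        np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])
    return SplineBasis(
        degree=degree,
        n_interior_knots=n_interior_knots,
        knot_vector=knots,
        basis_matrix=_design(ages, knots, degree),
        penalty_order=penalty_order,
    )


@dataclass(frozen=True)
class PenaltyMatrix:
    matrix: np.ndarray
    order: int

    @property
    def rank(self) -> int:
        return self.matrix.shape[0] - self.order


def difference_penalty(m: int, order: int = 2) -> PenaltyMatrix:
    """K = D_r' D_r with D_r the r-th order difference operator on R^m.

    K is symmetric positive semidefinite of rank m - r; polynomials of
    degree < r in the coefficient index are in its null space, so the
    random-walk prior exp(-tau/2 * beta' K beta) penalizes departures from
    an order-(r-1) polynomial trend.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if m <= order:
        raise ValueError(f"need m > order, got m={m}, order={order}")
    D = np.diff(np.eye(m), n=order, axis=0)
    return PenaltyMatrix(matrix=D.T @ D, order=order)
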