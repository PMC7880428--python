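"""B-spline bases for penalised-spline (P-spline) smooth terms.

Smooth covariate effects f(x) are expanded in cubic B-splines over an
equidistant knot grid, f(x) = sum_m beta_m B_m(x), and the coefficients get
a second-order random-walk prior (see :func:`geoadditive.penalties.rw2_penalty`):
the classic P-spline pairing of a rich basis with a curvature penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .penalties import rw2_penalty  # noqa: F401  (conventional import site)

__all__ = ["SplineBasis", "bspline_basis"]


@dataclass(frozen=True)
class SplineBasis:
    """An equidistant B-spline basis on a covariate domain.

    ``knots`` is the full (extended) knot vector; ``n_basis`` equals
    n_interior_knots + degree + 1.
    """

    knots: np.ndarray
    degree: int
    n_basis: int
    domain: tuple[float, float]

    def design(self, x) -> np.ndarray:
        """Evaluate the basis at new points (rows sum to one on the domain)."""
        x = np.asarray(x, dtype=float)
        if np.any(np.isnan(x)):
            raise ValueError("NaN in covariate; apply listwise deletion first")
        lo, hi = self.domain
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            raise ValueError(f"values outside the spline domain [{lo}, {hi}]")
        x = np.clip(x, lo, hi)
        # evaluate just inside the right boundary: the basis is right-open there
        eps = 1e-9 * max(hi - lo, 1.0)
        x = np.where(x >= hi, hi - eps, x)
        d = BSpline.design_matrix(x, self.knots, self.degree, extrapolate=False)
        return np.asarray(d.todense())


def bspline_basis(
    x,
    n_interior_knots: int = 20,
    degree: int = 3,
    domain: tuple[float, float] | None = None,
) -> tuple[SplineBasis, np.ndarray]:
    """Build an equidistant B-spline basis spanning the range of ``x``.

    The knot grid places ``n_interior_knots`` knots strictly inside
    [min x, max x] and extends the equidistant grid by ``degree`` knots on
    each side, so the basis functions form a partition of unity on the whole
    domain (every design row sums to 1).

    Returns the basis plus the n-by-M design matrix at ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("x must be a non-empty 1-d vector")
    if np.any(~np.isfinite(x)):
        raise ValueError("x must be finite (apply listwise deletion upstream)")
    if n_interior_knots < 1:
        raise ValueError("need at least one interior knot")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    lo, hi = domain if domain is not None else (float(x.min()), float(x.max()))
    if not hi > lo:
        raise ValueError("degenerate covariate domain (all values equal?)")
    h = (hi - lo) / (n_interior_knots + 1)
    knots = lo + h * np.arange(-degree, n_interior_knots + 2 + degree)
    n_basis = n_interior_knots + degree + 1
    basis = SplineBasis(knots=knots, degree=degree, n_basis=n_basis, domain=(lo, hi))
    return basis, basis.design(x)
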