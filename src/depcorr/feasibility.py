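"""Feasibility of trivariate correlation structures.

A non-degenerate trivariate normal distribution with correlations
(rho12, rho1y, rho2y) exists iff the 3x3 correlation matrix is positive
definite, which reduces to the determinant condition

    P = 1 - rho1y^2 - rho2y^2 - rho12^2 + 2*rho1y*rho2y*rho12 > 0.

This module decides feasibility, gives the admissible open interval for
rho2y at fixed (rho12, rho1y), and the admissible range of the common
correlation under the null rho1y = rho2y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PopulationCorrelations",
    "correlation_determinant",
    "is_feasible",
    "rho2y_bounds",
    "diagonal_range",
    "correlation_grid",
]


def _check_range(value: float, name: str) -> None:
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [-1, 1], got {value}")


@dataclass(frozen=True)
class PopulationCorrelations:
    """Population correlations (rho12, rho1y, rho2y) of (X1, X2, Y)."""

    rho12: float
    rho1y: float
    rho2y: float

    def __post_init__(self) -> None:
        for name in ("rho12", "rho1y", "rho2y"):
            _check_range(getattr(self, name), name)

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 correlation matrix in variable order (X1, X2, Y)."""
        return np.array(
            [
                [1.0, self.rho12, self.rho1y],
                [self.rho12, 1.0, self.rho2y],
                [self.rho1y, self.rho2y, 1.0],
            ]
        )


def correlation_determinant(rho12, rho1y, rho2y):
    """Determinant of the 3x3 correlation matrix (vectorized).

    Positive exactly when the matrix is positive definite, i.e. when a
    non-degenerate trivariate normal with these correlations exists.
    """
    rho12 = np.asarray(rho12, dtype=float)
    rho1y = np.asarray(rho1y, dtype=float)
    rho2y = np.asarray(rho2y, dtype=float)
    return 1.0 - rho1y**2 - rho2y**2 - rho12**2 + 2.0 * rho1y * rho2y * rho12


def is_feasible(p, rho1y=None, rho2y=None) -> bool | np.ndarray:
    """True iff a non-degenerate trivariate normal exists (strict P > 0).

    Accepts either a :class:`PopulationCorrelations` or the three
    correlations ``is_feasible(rho12, rho1y, rho2y)``; the latter form is
    vectorized over arrays.
    """
    if isinstance(p, PopulationCorrelations):
        det = correlation_determinant(p.rho12, p.rho1y, p.rho2y)
        return bool(det > 0.0)
    det = correlation_determinant(p, rho1y, rho2y)
    out = det > 0.0
    return bool(out) if np.isscalar(det) or det.ndim == 0 else out


def rho2y_bounds(rho12: float, rho1y: float) -> tuple[float, float]:
    """Open interval of rho2y values compatible with (rho12, rho1y).

    The bounds are rho12*rho1y -/+ sqrt((1-rho12^2)(1-rho1y^2)); the
    interval is never empty for interior rho12, rho1y.  At a boundary input
    (|rho| = 1) the interval degenerates to a point and a ValueError is
    raised.
    """
    _check_range(rho12, "rho12")
    _check_range(rho1y, "rho1y")
    if abs(rho12) == 1.0 or abs(rho1y) == 1.0:
        raise ValueError(
            "rho2y interval degenerates to a point when |rho12| = 1 or |rho1y| = 1"
        )
    half_width = np.sqrt((1.0 - rho12**2) * (1.0 - rho1y**2))
    centre = rho12 * rho1y
    return (centre - half_width, centre + half_width)


def diagonal_range(rho12: float) -> float:
    """Bound b such that rho1y = rho2y = rho is feasible iff |rho| < b.

    Setting rho1y = rho2y = rho in P > 0 gives (1 - rho12)(1 + rho12 -
    2 rho^2) > 0, hence b = sqrt((1 + rho12)/2).  rho12 = -1 yields b = 0
    (no non-degenerate null exists); rho12 = 1 yields b = 1.
    """
    if not -1.0 <= rho12 <= 1.0:
        raise ValueError(f"rho12 must lie in [-1, 1], got {rho12}")
    return float(np.sqrt((1.0 + rho12) / 2.0))


def correlation_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive arithmetic sequence lo, lo+step, ..., hi.

    Values are rounded to 1e-10 so that step sequences hit stated endpoints
    exactly (e.g. -0.9 to 0.9 in steps of 0.15 yields exactly 13 values).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    count = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(count), 10)
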