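"""Orthonormal Legendre polynomial basis over a standardized days-in-milk interval.

The random-regression test-day model expresses every lactation curve — the
population-mean curve, each animal's additive-genetic deviation, and its
permanent-environment deviation — as a linear combination of orthonormal
Legendre polynomials evaluated on days in milk (DIM) mapped affinely onto
[-1, 1].  Persistency measures and 270-day yield are then *linear contrasts*
of the regression coefficients: a weight vector ``w`` such that ``w @ coeffs``
equals the measure's value on the EBV curve, and ``w @ K @ w`` its variance
under a coefficient covariance ``K``.

The basis is orthonormal: phi_j(x) = sqrt((2j+1)/2) * P_j(x), with P_j the
classical Legendre polynomial, so that the continuous inner product of
phi_i and phi_j over [-1, 1] is the Kronecker delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "LegendreBasis",
    "ContrastVector",
    "standardize_day",
    "eval_basis",
    "point_contrast",
    "window_mean_vector",
    "mean_deviation_contrast",
    "pm1_contrast",
    "pm2_contrast",
    "pm3_contrast",
    "total270_contrast",
]

#: Contrast labels understood by downstream variance propagation.
PM1 = "PM1"
PM2 = "PM2"
PM3 = "PM3"
TOTAL270 = "TOTAL270"


@dataclass(frozen=True)
class LegendreBasis:
    """Orthonormal Legendre basis of ``order`` functions on DIM ``[day_min, day_max]``.

    ``order`` counts basis functions, i.e. polynomial degrees 0 .. order-1.
    The default interval [5, 270] is the edited-data DIM range.
    """

    order: int
    day_min: int = 5
    day_max: int = 270

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"basis order must be >= 1, got {self.order}")
        if self.day_min >= self.day_max:
            raise ValueError(
                f"day_min must be < day_max, got [{self.day_min}, {self.day_max}]"
            )

    def standardize(self, t):
        return standardize_day(t, self)

    def row(self, t) -> np.ndarray:
        """Basis row(s) phi_0..phi_{order-1} evaluated at integer day(s) ``t``."""
        return eval_basis(self.standardize(t), self.order)

    def grid(self, day_lo: int | None = None, day_hi: int | None = None) -> np.ndarray:
        """Matrix of basis rows on the inclusive integer-day grid."""
        lo = self.day_min if day_lo is None else day_lo
        hi = self.day_max if day_hi is None else day_hi
        return self.row(np.arange(lo, hi + 1))


@dataclass(frozen=True)
class ContrastVector:
    """Weights over basis coefficients defining a linear functional of a curve.

    ``scale_convention`` records whether window aggregations are per-day means
    (``"mean"``) or raw sums over days (``"sum"``); heritabilities are invariant
    to the choice as long as all three variance components use the same one.
    """

    weights: np.ndarray
    label: str
    scale_convention: str = "mean"

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.weights.ndim != 1:
            raise ValueError("contrast weights must be a 1-D vector")
        if self.scale_convention not in ("mean", "sum"):
            raise ValueError(f"unknown scale convention {self.scale_convention!r}")

    @property
    def order(self) -> int:
        return self.weights.shape[0]

    def apply(self, coeffs: np.ndarray) -> float | np.ndarray:
        """Value of the contrast on one coefficient vector (or a stack of them)."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape[-1] != self.order:
            raise ValueError(
                f"coefficient vector of length {coeffs.shape[-1]} does not match "
                f"contrast order {self.order}"
            )
        return coeffs @ self.weights


def standardize_day(t, basis: LegendreBasis):
    """Affine map of DIM onto [-1, 1]: x = -1 + 2 (t - day_min) / (day_max - day_min)."""
    t = np.asarray(t)
    if np.any(t < basis.day_min) or np.any(t > basis.day_max):
        bad = np.atleast_1d(t)[(np.atleast_1d(t) < basis.day_min) | (np.atleast_1d(t) > basis.day_max)]
        raise ValueError(
            f"day(s) {bad.tolist()} outside basis range [{basis.day_min}, {basis.day_max}]"
        )
    span = basis.day_max - basis.day_min
    return -1.0 + 2.0 * (t - basis.day_min) / span


def eval_basis(x, order: int) -> np.ndarray:
    """Orthonormal Legendre rows phi_j(x) = sqrt((2j+1)/2) P_j(x), j = 0..order-1.

    Returns shape ``(order,)`` for scalar ``x``, ``(len(x), order)`` otherwise.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    x_arr = np.asarray(x, dtype=float)
    if np.any(np.abs(x_arr) > 1 + 1e-12):
        raise ValueError(f"standardized day outside [-1, 1]: {x_arr}")
    vander = npleg.legvander(np.atleast_1d(x_arr), order - 1)
    scale = np.sqrt((2.0 * np.arange(order) + 1.0) / 2.0)
    out = vander * scale
    if x_arr.ndim == 0:
        return out[0]
    return out


def point_contrast(day_a: int, day_b: int, basis: LegendreBasis) -> ContrastVector:
    """Contrast for EBV(day_a) - EBV(day_b); with (257, 80) this is the PM3 measure."""
    w = basis.row(day_a) - basis.row(day_b)
    return ContrastVector(w, label=PM3 if (day_a, day_b) == (257, 80) else "POINT")


def window_mean_vector(day_lo: int, day_hi: int, basis: LegendreBasis) -> ContrastVector:
    """Per-day mean of basis rows over the inclusive integer-day window [day_lo, day_hi]."""
    if day_lo > day_hi:
        raise ValueError(f"inverted window [{day_lo}, {day_hi}]")
    w = basis.grid(day_lo, day_hi).mean(axis=0)
    return ContrastVector(w, label="WINDOW_MEAN")


def mean_deviation_contrast(
    day_lo: int, day_hi: int, ref_day: int, basis: LegendreBasis,
    scale_convention: str = "mean",
) -> ContrastVector:
    """Per-day mean deviation of the window [day_lo, day_hi] from ``ref_day``.

    With (53, 247, 248) this is the PM2 measure on the per-day scale:
    (1/n) sum_t [phi(x(t))] - phi(x(ref_day)), n = day_hi - day_lo + 1.
    The raw-sum variant multiplies everything by n.
    """
    if day_lo > day_hi:
        raise ValueError(f"inverted window [{day_lo}, {day_hi}]")
    n = day_hi - day_lo + 1
    w = basis.grid(day_lo, day_hi).mean(axis=0) - basis.row(ref_day)
    if scale_convention == "sum":
        w = w * n
    label = PM2 if (day_lo, day_hi, ref_day) == (53, 247, 248) else "MEAN_DEV"
    return ContrastVector(w, label=label, scale_convention=scale_convention)


# Persistency-measure windows.  PM1 contrasts late lactation (days 226-270,
# 45 days) against the region around peak (days 44-62, 19 days); the true
# window lengths are used as divisors.  PM2 integrates days 53-247 as a
# deviation from day 248; PM3 is the single-day difference 257 - 80.
PM1_LATE = (226, 270)
PM1_EARLY = (44, 62)
PM2_WINDOW = (53, 247, 248)
PM3_DAYS = (257, 80)


def pm1_contrast(basis: LegendreBasis) -> ContrastVector:
    """PM1: mean EBV over days 226-270 minus mean EBV over days 44-62."""
    w = (
        window_mean_vector(*PM1_LATE, basis).weights
        - window_mean_vector(*PM1_EARLY, basis).weights
    )
    return ContrastVector(w, label=PM1)


def pm2_contrast(basis: LegendreBasis, scale_convention: str = "mean") -> ContrastVector:
    """PM2: deviation of days 53-247 from day 248 (per-day by default)."""
    return mean_deviation_contrast(*PM2_WINDOW, basis, scale_convention=scale_convention)


def pm3_contrast(basis: LegendreBasis) -> ContrastVector:
    """PM3: EBV at day 257 minus EBV at day 80."""
    return point_contrast(*PM3_DAYS, basis)


def total270_contrast(basis: LegendreBasis, scale_convention: str = "sum") -> ContrastVector:
    """270-day yield contrast: sum (default) or per-day mean of EBVs over days 5-270."""
    w = window_mean_vector(basis.day_min, basis.day_max, basis).weights
    n = basis.day_max - basis.day_min + 1
    if scale_convention == "sum":
        w = w * n
    return ContrastVector(w, label=TOTAL270, scale_convention=scale_convention)


def standard_contrasts(basis: LegendreBasis, total_convention: str = "sum") -> dict[str, ContrastVector]:
    """The four contrasts reported by the analysis, keyed by label."""
    return {
        PM1: pm1_contrast(basis),
        PM2: pm2_contrast(basis),
        PM3: pm3_contrast(basis),
        TOTAL270: total270_contrast(basis, scale_convention=total_convention),
    }
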