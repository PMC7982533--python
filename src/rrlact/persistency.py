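"""Persistency measures, analytic variance propagation, and genetic trends.

Three persistency measures of the EBV curve are used, each a linear
contrast ``w`` of the additive regression coefficients (small absolute
values = high persistency):

* PM1 — mean EBV over days 226-270 minus mean EBV over days 44-62;
* PM2 — per-day mean deviation of days 53-247 from day 248;
* PM3 — EBV(257) - EBV(80);

plus the 270-day total yield (sum of daily EBVs, days 5-270).  Variances
propagate analytically: sigma2_a = w' Ka w, sigma2_pe = w' Kpe w, and the
residual variance of a measure follows from independent daily residuals
(e.g. 2 sigma2_e for PM3, 266 sigma2_e for the 270-day sum).  Heritability
is sigma2_a / (sigma2_a + sigma2_pe + sigma2_e,m); genetic correlations are
normalized coefficient-covariance quadratic forms.  Genetic trend is the
ordinary least-squares regression of annual mean EBV on calving year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rrlact.basis import (
    PM1_EARLY,
    PM1_LATE,
    PM2_WINDOW,
    ContrastVector,
    LegendreBasis,
    standard_contrasts,
)
from rrlact.model import ModelSolution

__all__ = [
    "pm_value",
    "genetic_variance",
    "pe_variance",
    "residual_variance_of_measure",
    "heritability",
    "genetic_correlation",
    "genetic_trend",
    "build_report",
    "GeneticParamReport",
    "TrendResult",
]

MEASURES = ("PM1", "PM2", "PM3")


def residual_multiplier(label: str, convention: str = "mean") -> float:
    """Sum of squared daily weights of a measure, for residual propagation.

    PM1: 1/45 + 1/19; PM2 per-day: 1/195 + 1 (sum scale: 195 + 195^2);
    PM3: 2; TOTAL270: 266 on the sum scale, 266/266^2 = 1/266 on the mean scale.
    """
    n1_late = PM1_LATE[1] - PM1_LATE[0] + 1    # 45
    n1_early = PM1_EARLY[1] - PM1_EARLY[0] + 1  # 19
    n2 = PM2_WINDOW[1] - PM2_WINDOW[0] + 1      # 195
    if label == "PM1":
        return 1.0 / n1_late + 1.0 / n1_early
    if label == "PM2":
        per_day = 1.0 / n2 + 1.0
        return per_day if convention == "mean" else n2 + n2**2
    if label == "PM3":
        return 2.0
    if label == "TOTAL270":
        return 266.0 if convention == "sum" else 1.0 / 266.0
    raise ValueError(f"unknown measure {label!r}")


def pm_value(solution: ModelSolution, animal, measure: str, basis: LegendreBasis) -> float:
    """Value of a persistency measure (or TOTAL270) for one animal's EBV curve."""
    contrasts = standard_contrasts(basis)
    if measure not in contrasts:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(contrasts)}")
    return float(contrasts[measure].apply(solution.coefficients(animal)))


def _quadratic_form(contrast: ContrastVector, K: np.ndarray, name: str) -> float:
    K = np.asarray(K, float)
    if K.shape != (contrast.order, contrast.order):
        raise ValueError(
            f"{name} of shape {K.shape} does not match contrast order {contrast.order}"
        )
    return float(contrast.weights @ K @ contrast.weights)


def genetic_variance(contrast: ContrastVector, Ka: np.ndarray) -> float:
    """sigma2_a of a measure: w' Ka w (kg^2)."""
    return _quadratic_form(contrast, Ka, "Ka")


def pe_variance(contrast: ContrastVector, Kpe: np.ndarray) -> float:
    """sigma2_pe of a measure: w' Kpe w (kg^2)."""
    return _quadratic_form(contrast, Kpe, "Kpe")


def residual_variance_of_measure(measure: str, sigma_e2_pooled: float, convention: str = "mean") -> float:
    """Residual variance of a measure under independent daily residuals."""
    if sigma_e2_pooled <= 0:
        raise ValueError("pooled residual variance must be positive")
    return residual_multiplier(measure, convention) * sigma_e2_pooled


def heritability(sigma_a2: float, sigma_pe2: float, sigma_e2_m: float) -> float:
    """h^2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e,m)."""
    if min(sigma_a2, sigma_pe2, sigma_e2_m) < 0:
        raise ValueError("variance components must be non-negative")
    denom = sigma_a2 + sigma_pe2 + sigma_e2_m
    if denom == 0:
        raise ZeroDivisionError("all variance components are zero")
    return sigma_a2 / denom


def genetic_correlation(c1: ContrastVector, c2: ContrastVector, Ka: np.ndarray) -> float:
    """r_a = (w1' Ka w2) / sqrt((w1' Ka w1)(w2' Ka w2))."""
    v1 = genetic_variance(c1, Ka)
    v2 = genetic_variance(c2, Ka)
    if v1 <= 0 or v2 <= 0:
        raise ZeroDivisionError("genetic correlation undefined for a zero-variance contrast")
    cov = float(c1.weights @ np.asarray(Ka, float) @ c2.weights)
    return cov / np.sqrt(v1 * v2)


@dataclass
class TrendResult:
    """OLS regression of annual mean EBV on calving year."""

    slope: float
    se: float
    p_value: float
    n_years: int
    annual_means: pd.Series

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def genetic_trend(values: pd.DataFrame, value_col: str = "value", year_col: str = "year",
                  weighted: bool = False) -> TrendResult:
    """Genetic trend: slope of annual mean EBV (or PM value) on calving year.

    ``values`` has one row per animal with its measure value and calving year.
    Unweighted annual means by default; ``weighted=True`` regresses on
    animal-level values directly (years weighted by their animal counts).
    """
    years = values[year_col]
    if years.nunique() < 3:
        raise ValueError("genetic trend needs at least 3 distinct calving years")
    annual = values.groupby(year_col)[value_col].mean()
    if weighted:
        res = stats.linregress(years.to_numpy(float), values[value_col].to_numpy(float))
    else:
        res = stats.linregress(annual.index.to_numpy(float), annual.to_numpy(float))
    if np.isnan(res.pvalue):  # perfectly constant response: no trend
        return TrendResult(slope=0.0, se=0.0, p_value=1.0,
                           n_years=int(years.nunique()), annual_means=annual)
    return TrendResult(
        slope=float(res.slope), se=float(res.stderr), p_value=float(res.pvalue),
        n_years=int(years.nunique()), annual_means=annual,
    )


@dataclass
class GeneticParamReport:
    """Variance components, heritabilities and genetic correlations per measure."""

    variances: pd.DataFrame       # rows: measure; columns sigma2_a, sigma2_pe, sigma2_e, sigma2_p, h2
    correlations: pd.DataFrame    # genetic correlation matrix among measures + TOTAL270

    def __post_init__(self) -> None:
        h2 = self.variances["h2"]
        if ((h2 < -1e-12) | (h2 > 1 + 1e-12)).any():
            raise ValueError("heritabilities outside [0, 1]")


def build_report(
    Ka: np.ndarray,
    Kpe: np.ndarray,
    sigma_e2_pooled: float,
    basis_a: LegendreBasis,
    basis_p: LegendreBasis | None = None,
    total_convention: str = "sum",
) -> GeneticParamReport:
    """Full genetic-parameter report for PM1-PM3 and 270-day yield.

    Contrasts are built at each component's own order (Ka at ``basis_a``,
    Kpe at ``basis_p``, defaulting to the same basis).  Residual variances
    use the independent-daily-residual multipliers; the per-measure scale
    conventions match the contrast definitions, so heritabilities are
    convention-invariant.
    """
    basis_p = basis_a if basis_p is None else basis_p
    ca = standard_contrasts(basis_a, total_convention=total_convention)
    cp = standard_contrasts(basis_p, total_convention=total_convention)
    labels = list(ca)
    rows = []
    for lab in labels:
        conv = ca[lab].scale_convention if lab in ("PM2", "TOTAL270") else "mean"
        va = genetic_variance(ca[lab], Ka)
        vp = pe_variance(cp[lab], Kpe)
        ve = residual_variance_of_measure(lab, sigma_e2_pooled, convention=conv)
        rows.append({
            "measure": lab, "sigma2_a": va, "sigma2_pe": vp, "sigma2_e": ve,
            "sigma2_p": va + vp + ve, "h2": heritability(va, vp, ve),
        })
    variances = pd.DataFrame(rows).set_index("measure")
    corr = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, li in enumerate(labels):
        for j in range(i + 1, len(labels)):
            lj = labels[j]
            r = genetic_correlation(ca[li], ca[lj], Ka)
            corr.iloc[i, j] = corr.iloc[j, i] = r
    return GeneticParamReport(variances=variances, correlations=corr)
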