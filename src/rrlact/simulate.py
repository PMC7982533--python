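"""Synthetic pedigreed test-day data with known (co)variance structure.

Generates data with exactly the statistical structure the random-regression
test-day model assumes, standing in for the confidential national buffalo
recording data: a multi-generation random-mating pedigree, additive-genetic
and permanent-environment regression-coefficient vectors drawn from
N(0, A (x) Ka) and N(0, I (x) Kpe), and test-day fat-yield records

    y = ecotype + year-season + herd-test-date + age polynomial
        + fixed curve + phi' a_animal + phi' pe_animal-lactation + e,

with the residual variance allowed to differ over nine DIM classes.  Herd
test schedules (a shared date grid per herd) create genuine herd-test-date
contemporary groups and realistic 4-9 tests per lactation.  Ground truth
(coefficient vectors, all effect tables) is returned for recovery testing.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rrlact.basis import LegendreBasis
from rrlact.pedigree import Pedigree, _mendelian_variances, validate_and_sort

__all__ = [
    "SimConfig",
    "simulate_pedigree",
    "simulate_true_effects",
    "simulate_records",
    "apply_filters",
    "simulate_dataset",
    "residual_class",
    "RESIDUAL_CLASS_EDGES",
]

#: DIM class edges of the 9 summary classes (5-30, 31-60, ..., 241-270).
RESIDUAL_CLASS_EDGES = np.array([5, 31, 61, 91, 121, 151, 181, 211, 241, 271])

#: Calving-age windows (months) by parity of the edited data.
CALVING_AGE_WINDOWS = {1: (24, 60), 2: (39, 76), 3: (54, 100)}


def residual_class(dim) -> np.ndarray:
    """0-based DIM class index (9 classes) of integer day(s) in [5, 270]."""
    dim = np.asarray(dim)
    return np.clip(np.searchsorted(RESIDUAL_CLASS_EDGES, dim, side="right") - 1, 0, 8)


def _default_ka() -> np.ndarray:
    return np.array(
        [[0.012, 0.002, 0.001],
         [0.002, 0.006, 0.0015],
         [0.001, 0.0015, 0.004]]
    )


def _default_kpe() -> np.ndarray:
    return np.array(
        [[0.014, 0.002, 0.001],
         [0.002, 0.007, 0.001],
         [0.001, 0.001, 0.004]]
    )


def _default_sigma_e2() -> np.ndarray:
    # mild early-to-late heterogeneity over the 9 DIM classes, kg^2
    return np.array([0.034, 0.033, 0.032, 0.031, 0.030, 0.029, 0.029, 0.028, 0.028])


@dataclass
class SimConfig:
    """Generator settings.

    Data-structure constants (DIM range, tests per animal, ecotypes, seasons,
    calving-age windows, calving years) default to the edited-data layout;
    population sizes default to a desk-scale population.  ``ka``/``kpe`` are
    implied by the shapes of ``Ka``/``Kpe``.
    """

    n_founders: int = 60
    n_generations: int = 1
    offspring_per_generation: int = 400
    prop_male_founders: float = 0.25
    n_herds: int = 20
    n_ecotypes: int = 3
    years: tuple[int, int] = (1996, 2012)
    n_seasons: int = 4
    parities: tuple[int, ...] = (1,)
    tests_per_animal: tuple[int, int] = (4, 9)
    dim_range: tuple[int, int] = (5, 270)
    test_interval_days: int = 30
    Ka: np.ndarray = field(default_factory=_default_ka)
    Kpe: np.ndarray = field(default_factory=_default_kpe)
    sigma_e2: float | np.ndarray = field(default_factory=_default_sigma_e2)
    mean_curve: tuple[float, ...] = (0.672, -0.004, -0.02)  # LP coefficients, kg
    ecotype_sd: float = 0.03
    ys_sd: float = 0.03
    htd_sd: float = 0.05
    age_coeffs: tuple[float, float, float] = (0.0, 0.02, -0.01)  # on scaled age
    calving_age_windows: dict = field(default_factory=lambda: dict(CALVING_AGE_WINDOWS))
    trend_per_year: float = 0.0  # injected genetic gain, kg/day of flat EBV per year
    founders_recorded: bool = False
    clip_years: bool = True  # keep calving years inside the configured range
    seed: int = 0

    def __post_init__(self) -> None:
        self.Ka = np.asarray(self.Ka, dtype=float)
        self.Kpe = np.asarray(self.Kpe, dtype=float)
        for name, K in (("Ka", self.Ka), ("Kpe", self.Kpe)):
            if K.ndim != 2 or K.shape[0] != K.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(K, K.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(K) <= 0):
                raise ValueError(f"{name} must be positive definite")
        se = np.atleast_1d(np.asarray(self.sigma_e2, dtype=float))
        if np.any(se <= 0):
            raise ValueError("sigma_e2 must be positive")
        lo, hi = self.tests_per_animal
        if not (4 <= lo <= hi <= 9):
            raise ValueError("tests_per_animal must lie within [4, 9]")
        dlo, dhi = self.dim_range
        if not (5 <= dlo < dhi <= 270):
            raise ValueError("dim_range must lie within [5, 270]")

    @property
    def ka(self) -> int:
        return self.Ka.shape[0]

    @property
    def kpe(self) -> int:
        return self.Kpe.shape[0]

    def sigma_e2_by_class(self) -> np.ndarray:
        se = np.atleast_1d(np.asarray(self.sigma_e2, dtype=float))
        if se.size == 1:
            return np.full(9, se[0])
        if se.size != 9:
            raise ValueError("sigma_e2 must be a scalar or a length-9 vector")
        return se


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None):
    """Random-mating multi-generation pedigree.

    Returns ``(Pedigree, meta)`` where ``meta`` has one row per animal with
    sex, generation, and birth year (founders spread over the earliest years,
    each later generation shifted by a fixed generation interval).
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    y0, y1 = config.years
    n_years = y1 - y0 + 1
    gen_interval = max(1, n_years // (config.n_generations + 1))

    ids, sires, dams, sexes, gens, byears = [], [], [], [], [], []
    next_id = 1
    males, females = [], []
    n_m = max(1, int(round(config.n_founders * config.prop_male_founders)))
    for i in range(config.n_founders):
        sex = "M" if i < n_m else "F"
        ids.append(next_id); sires.append(0); dams.append(0)
        sexes.append(sex); gens.append(0)
        byears.append(y0 + int(rng.integers(0, max(1, gen_interval))))
        (males if sex == "M" else females).append(next_id)
        next_id += 1
    for g in range(1, config.n_generations + 1):
        new_m, new_f = [], []
        for _ in range(config.offspring_per_generation):
            s = int(rng.choice(males))
            d = int(rng.choice(females))
            sex = "M" if rng.random() < 0.5 else "F"
            ids.append(next_id); sires.append(s); dams.append(d)
            sexes.append(sex); gens.append(g)
            by = y0 + g * gen_interval + int(rng.integers(0, max(1, gen_interval)))
            byears.append(min(y1, by) if config.clip_years else by)
            (new_m if sex == "M" else new_f).append(next_id)
            next_id += 1
        # next generation mates among the new cohort (fall back to parents if a sex is empty)
        males = new_m or males
        females = new_f or females

    ped = validate_and_sort(zip(ids, sires, dams))
    meta = pd.DataFrame(
        {"animal": ids, "sex": sexes, "generation": gens, "birth_year": byears}
    ).set_index("animal")
    return ped, meta


def recorded_animals(config: SimConfig, ped: Pedigree, meta: pd.DataFrame) -> list:
    """Animals that produce test-day records (non-founders, or all)."""
    if config.founders_recorded or config.n_generations == 0:
        return list(ped.animals)
    return [a for a in ped.animals if meta.loc[a, "generation"] > 0]


def simulate_true_effects(
    ped: Pedigree,
    Ka: np.ndarray,
    Kpe: np.ndarray,
    rng: np.random.Generator,
    recorded: list,
    parities: tuple[int, ...] = (1,),
):
    """Draw true additive and permanent-environment coefficient vectors.

    Additive vectors follow N(0, A (x) Ka) (animal-major ordering), sampled by
    the pedigree recursion a_i = (a_s + a_d)/2 + m_i with Mendelian-sampling
    variance d_i * Ka.  Permanent-environment vectors are iid N(0, Kpe) per
    recorded animal and parity.  (Genetic-trend injection happens at record
    simulation, where calving years are known.)
    """
    Ka = np.asarray(Ka, float)
    Kpe = np.asarray(Kpe, float)
    ka, kpe = Ka.shape[0], Kpe.shape[0]
    try:
        La = np.linalg.cholesky(Ka)
        Lp = np.linalg.cholesky(Kpe) if np.any(Kpe) else np.zeros_like(Kpe)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Ka/Kpe must be positive (semi)definite") from exc
    n = len(ped)
    _, d = _mendelian_variances(ped.sire_idx, ped.dam_idx, ped.inbreeding())
    a = np.zeros((n, ka))
    z = rng.standard_normal((n, ka))
    for i in range(n):
        mean = np.zeros(ka)
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si >= 0:
            mean += 0.5 * a[si]
        if di >= 0:
            mean += 0.5 * a[di]
        a[i] = mean + np.sqrt(d[i]) * (La @ z[i])
    a_df = pd.DataFrame(a, index=list(ped.animals))
    pe = {}
    for p in parities:
        pe_mat = rng.standard_normal((len(recorded), kpe)) @ Lp.T
        pe[p] = pd.DataFrame(pe_mat, index=list(recorded))
    return a_df, pe


def _herd_schedules(config: SimConfig, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Per-herd test-date grids (day numbers on a continuous calendar)."""
    y0, y1 = config.years
    horizon = (y1 - y0 + 3) * 365  # room for late calvings + 270 DIM
    out = {}
    for h in range(1, config.n_herds + 1):
        offset = int(rng.integers(0, config.test_interval_days))
        out[h] = np.arange(offset, horizon, config.test_interval_days)
    return out


def simulate_records(
    config: SimConfig,
    ped: Pedigree,
    effects,
    meta: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the test-day record table with ground-truth sidecar columns.

    Returns a DataFrame with the external record schema plus ``true_*``
    columns (genetic value, pe value, residual class) used only by tests.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    a_df, pe = effects
    basis_a = LegendreBasis(config.ka, *config.dim_range)
    basis_p = LegendreBasis(config.kpe, *config.dim_range)
    basis_f = LegendreBasis(3, *config.dim_range)
    se2 = config.sigma_e2_by_class()
    y0, y1 = config.years

    eco_eff = rng.normal(0.0, config.ecotype_sd, config.n_ecotypes)
    eco_eff -= eco_eff.mean()  # contemporary-group effects are deviations
    herd_eco = rng.integers(1, config.n_ecotypes + 1, config.n_herds + 1)  # herd -> ecotype
    schedules = _herd_schedules(config, rng)

    recorded = list(pe[config.parities[0]].index)
    herd_of = {a: int(rng.integers(1, config.n_herds + 1)) for a in recorded}

    # pass 1: lay out lactations and test days (no effect values yet)
    base = []
    for parity in config.parities:
        pe_df = pe[parity]
        lo_age, hi_age = config.calving_age_windows[parity]
        for animal in recorded:
            herd = herd_of[animal]
            byear = int(meta.loc[animal, "birth_year"])
            age = float(rng.uniform(lo_age, hi_age))
            cyear = byear + int(age // 12)
            if config.clip_years and cyear > y1:
                cyear = y1
            season = int(rng.integers(1, config.n_seasons + 1))
            cday = (cyear - y0) * 365 + (season - 1) * 91 + int(rng.integers(0, 91))
            sched = schedules[herd]
            dims = sched[
                (sched >= cday + config.dim_range[0]) & (sched <= cday + config.dim_range[1])
            ] - cday
            n_lo, n_hi = config.tests_per_animal
            n_tests = int(rng.integers(n_lo, n_hi + 1))
            if len(dims) > n_tests:
                dims = np.sort(rng.choice(dims, n_tests, replace=False))
            age_s = (age - (lo_age + hi_age) / 2) / ((hi_age - lo_age) / 2)
            a_vec = a_df.loc[animal].to_numpy().copy()
            if config.trend_per_year != 0.0 and parity == config.parities[0]:
                # genetic gain of g kg/day of flat EBV per calving year:
                # drift the constant coefficient (phi_0 = sqrt(1/2))
                a_vec[0] += config.trend_per_year / np.sqrt(0.5) * (cyear - y0)
            p_vec = pe_df.loc[animal].to_numpy()
            for dim in dims:
                dim = int(dim)
                base.append((animal, parity, dim, herd, cday + dim, cday, age, age_s,
                             cyear, season, a_vec, p_vec))
    if not base:
        return pd.DataFrame(columns=_RECORD_OUTPUT_COLUMNS)

    # pass 2: draw centered effect tables over the observed levels, compose y
    ys_levels = sorted({(r[8], r[9]) for r in base})
    ys_draw = rng.normal(0.0, config.ys_sd, len(ys_levels))
    ys_eff = dict(zip(ys_levels, ys_draw - ys_draw.mean()))
    htd_levels = sorted({(r[3], r[4]) for r in base})
    htd_draw = rng.normal(0.0, config.htd_sd, len(htd_levels))
    htd_eff = dict(zip(htd_levels, htd_draw - htd_draw.mean()))

    c0, c1, c2 = config.age_coeffs
    rows = []
    for animal, parity, dim, herd, tdate, cday, age, age_s, cyear, season, a_vec, p_vec in base:
        klass = int(residual_class(dim))
        gval = float(basis_a.row(dim) @ a_vec)
        pval = float(basis_p.row(dim) @ p_vec)
        e = rng.normal(0.0, np.sqrt(se2[klass]))
        yld = (
            eco_eff[herd_eco[herd] - 1]
            + ys_eff[(cyear, season)]
            + htd_eff[(herd, tdate)]
            + c0 + c1 * age_s + c2 * age_s**2
            + float(np.asarray(config.mean_curve) @ basis_f.row(dim))
            + gval + pval + e
        )
        rows.append(
            (animal, parity, dim, yld, herd, _date_str(y0, tdate), _date_str(y0, cday),
             age, int(herd_eco[herd]), cyear, season, gval, pval, klass)
        )
    return pd.DataFrame(rows, columns=_RECORD_OUTPUT_COLUMNS)


_RECORD_OUTPUT_COLUMNS = [
    "animal", "parity", "dim", "yield_kg", "herd", "test_date",
    "calving_date", "age_months", "ecotype", "year", "season",
    "true_genetic", "true_pe", "residual_class",
]


def _date_str(y0: int, day: int) -> str:
    d = _dt.date(y0, 1, 1) + _dt.timedelta(days=int(day))
    return d.isoformat()


def apply_filters(records: pd.DataFrame, config: SimConfig):
    """Edited-data filters: DIM range, 4-9 surviving tests, calving-age windows.

    Returns ``(filtered, log)`` where ``log`` counts records removed per reason.
    Idempotent: filtering a filtered table removes nothing further.
    """
    log = {"dim_out_of_range": 0, "calving_age_out_of_window": 0, "test_count_out_of_range": 0}
    df = records.copy()
    dlo, dhi = config.dim_range
    bad_dim = (df["dim"] < dlo) | (df["dim"] > dhi)
    log["dim_out_of_range"] = int(bad_dim.sum())
    df = df[~bad_dim]

    windows = config.calving_age_windows
    lo = df["parity"].map(lambda p: windows[p][0])
    hi = df["parity"].map(lambda p: windows[p][1])
    bad_age = (df["age_months"] < lo) | (df["age_months"] > hi)
    log["calving_age_out_of_window"] = int(bad_age.sum())
    df = df[~bad_age]

    counts = df.groupby(["animal", "parity"])["dim"].transform("size")
    bad_n = (counts < 4) | (counts > 9)
    log["test_count_out_of_range"] = int(bad_n.sum())
    df = df[~bad_n]
    return df.reset_index(drop=True), log


def simulate_dataset(config: SimConfig):
    """End-to-end generation: pedigree, effects, filtered records.

    Returns ``(records, ped, truth)`` where ``truth`` bundles the generating
    coefficient tables for recovery tests.  Fully deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ped, meta = simulate_pedigree(config, rng)
    recorded = recorded_animals(config, ped, meta)
    a_df, pe = simulate_true_effects(
        ped, config.Ka, config.Kpe, rng, recorded, parities=config.parities,
    )
    records = simulate_records(config, ped, (a_df, pe), meta, rng)
    if config.trend_per_year != 0.0:
        # mirror the calving-year drift applied at record simulation into the
        # truth table so recovery studies see the drifted breeding values
        first = records[records["parity"] == config.parities[0]]
        cyear = first.groupby("animal")["year"].first()
        drift = config.trend_per_year / np.sqrt(0.5) * (cyear - config.years[0])
        a_df.loc[drift.index, 0] += drift
    records, log = apply_filters(records, config)
    truth = {"a": a_df, "pe": pe, "meta": meta, "filter_log": log, "config": config}
    return records, ped, truth
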