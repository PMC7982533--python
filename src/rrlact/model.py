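"""Design matrices and BLUP solving for the random-regression test-day model.

The observation model for a test-day record at days in milk t is

    y = ecotype + year-season + herd-test-date + sum_f c_f age^f
        + sum_r beta_r phi_r(x(t)) + phi(x(t))' a_animal + phi(x(t))' pe_animal + e

with a ~ N(0, A (x) Ka), pe ~ N(0, I (x) Kpe), e ~ N(0, sigma_e^2(class(t))).
``build_design`` produces the fixed design X (reference levels dropped, any
remaining collinear columns removed by pivoted QR) and the sparse random
regressor matrices; ``solve_mme`` solves Henderson's mixed-model equations at
given variance components, yielding BLUE fixed effects and BLUP coefficient
vectors for every pedigree animal — including ancestors without records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import sparse
from scipy.sparse import linalg as spla

from rrlact.basis import LegendreBasis
from rrlact.pedigree import Pedigree, a_inverse
from rrlact.simulate import CALVING_AGE_WINDOWS, residual_class

__all__ = ["ModelSpec", "Design", "ModelSolution", "build_design", "solve_mme", "ebv_curve", "ebv_total"]


@dataclass(frozen=True)
class ModelSpec:
    """Orders of fit and residual structure of one analysis."""

    ka: int = 3
    kpe: int = 3
    fixed_curve_order: int = 3  # LP degrees 0..2 for the mean curve
    age_poly_order: int = 3     # powers 0..2 of the scaled calving age
    residual_classes: int = 9   # 9 DIM classes, or 1 pooled

    def __post_init__(self) -> None:
        if not (1 <= self.ka <= 6 and 1 <= self.kpe <= 6):
            raise ValueError("orders of fit must lie in 1..6")
        if self.residual_classes not in (1, 9):
            raise ValueError("residual_classes must be 1 or 9")


@dataclass
class Design:
    """Assembled design matrices for one parity's records."""

    X: np.ndarray                # dense fixed design, full column rank
    Z_a: sparse.csr_matrix      # N x (ka * n_ped)
    Z_p: sparse.csr_matrix      # N x (kpe * n_recorded)
    y: np.ndarray
    resid_class: np.ndarray     # 0-based DIM class per record (all 0 if pooled)
    dim: np.ndarray             # integer days in milk per record
    spec: ModelSpec
    basis_a: LegendreBasis
    basis_p: LegendreBasis
    recorded: list              # animals with records, in Z_p block order
    animal_row: np.ndarray      # pedigree index per record
    fixed_names: list
    dropped: list = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return self.y.shape[0]


@dataclass
class ModelSolution:
    """BLUE fixed effects and BLUP random-regression coefficients."""

    fixed: pd.Series
    a_hat: pd.DataFrame    # one row per pedigree animal, ka columns
    pe_hat: pd.DataFrame   # one row per recorded animal, kpe columns
    diagnostics: dict

    def coefficients(self, animal) -> np.ndarray:
        try:
            return self.a_hat.loc[animal].to_numpy()
        except KeyError:
            raise KeyError(f"animal {animal!r} not in solution") from None


def _scaled_age(records: pd.DataFrame) -> np.ndarray:
    """Calving age centered at the parity-window midpoint and scaled to [-1, 1]."""
    age = records["age_months"].to_numpy(float)
    out = np.empty_like(age)
    for parity, grp in records.groupby("parity"):
        lo, hi = CALVING_AGE_WINDOWS.get(int(parity), (age.min(), age.max()))
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        out[records["parity"].to_numpy() == parity] = (grp["age_months"].to_numpy(float) - mid) / half
    return out


def build_design(
    records: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    basis: LegendreBasis | None = None,
) -> Design:
    """Assemble X, Z_a, Z_p from a filtered record table.

    Fixed factors (ecotype, year-season, herd-test-date) enter as dummies with
    the first level dropped; the age polynomial contributes the intercept; the
    fixed lactation curve contributes phi_1..phi_{order-1} (phi_0 is constant
    and therefore absorbed by the intercept).  Any remaining exact collinearity
    (e.g. ecotype nested within herd) is removed by pivoted QR and logged.
    """
    missing = [a for a in records["animal"].unique() if a not in ped._index]
    if missing:
        raise ValueError(f"records contain animals absent from the pedigree: {missing[:5]}")

    dim_range = (basis.day_min, basis.day_max) if basis is not None else (5, 270)
    basis_a = LegendreBasis(spec.ka, *dim_range)
    basis_p = LegendreBasis(spec.kpe, *dim_range)
    basis_f = LegendreBasis(spec.fixed_curve_order, *dim_range)

    n = len(records)
    dim = records["dim"].to_numpy(int)

    cols: list[np.ndarray] = []
    names: list[str] = []
    # age polynomial (power 0 is the model intercept)
    age_s = _scaled_age(records)
    for f in range(spec.age_poly_order):
        cols.append(age_s**f)
        names.append("intercept" if f == 0 else f"age^{f}")
    # fixed lactation curve, phi_0 dropped (constant)
    phi_f = basis_f.row(dim)
    for r in range(1, spec.fixed_curve_order):
        cols.append(phi_f[:, r])
        names.append(f"curve_phi{r}")
    # factors with first-level reference dropping
    for factor, key in (
        ("ecotype", records["ecotype"]),
        ("ys", list(zip(records["year"], records["season"]))),
        ("htd", list(zip(records["herd"], records["test_date"]))),
    ):
        codes, levels = pd.factorize(pd.Series(key).astype(str), sort=True)
        for lev in range(1, len(levels)):
            cols.append((codes == lev).astype(float))
            names.append(f"{factor}={levels[lev]}")
    X = np.column_stack(cols)

    # drop exactly collinear columns (pivoted QR)
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in piv[rank:]]
    X = X[:, keep]
    names = [names[j] for j in keep]

    # random regressors
    ped_idx = np.array([ped.index_of(a) for a in records["animal"]])
    recorded = sorted(records["animal"].unique(), key=ped.index_of)
    rec_pos = {a: i for i, a in enumerate(recorded)}
    rec_idx = np.array([rec_pos[a] for a in records["animal"]])

    phi_a = basis_a.row(dim)
    phi_p = basis_p.row(dim)
    rows = np.repeat(np.arange(n), spec.ka)
    cols_a = (ped_idx[:, None] * spec.ka + np.arange(spec.ka)).ravel()
    Z_a = sparse.csr_matrix((phi_a.ravel(), (rows, cols_a)), shape=(n, spec.ka * len(ped)))
    rows_p = np.repeat(np.arange(n), spec.kpe)
    cols_p = (rec_idx[:, None] * spec.kpe + np.arange(spec.kpe)).ravel()
    Z_p = sparse.csr_matrix((phi_p.ravel(), (rows_p, cols_p)), shape=(n, spec.kpe * len(recorded)))

    klass = residual_class(dim) if spec.residual_classes == 9 else np.zeros(n, dtype=int)
    return Design(
        X=X, Z_a=Z_a, Z_p=Z_p, y=records["yield_kg"].to_numpy(float),
        resid_class=np.asarray(klass, dtype=int), dim=dim, spec=spec,
        basis_a=basis_a, basis_p=basis_p, recorded=recorded,
        animal_row=ped_idx, fixed_names=names, dropped=dropped,
    )


def _residual_vector(design: Design, sigma_e2) -> np.ndarray:
    se = np.atleast_1d(np.asarray(sigma_e2, float))
    if se.size == 1:
        return np.full(design.n_records, se[0])
    return se[design.resid_class]


def solve_mme(
    design: Design,
    Ka: np.ndarray,
    Kpe: np.ndarray,
    sigma_e2,
    ped: Pedigree,
    tol: float = 1e-10,
) -> ModelSolution:
    """Solve Henderson's mixed-model equations at fixed variance components.

    Uses a sparse LU factorization with one step of iterative refinement; the
    relative residual of the solved system is reported in the diagnostics and
    must meet ``tol``.
    """
    Ka = np.asarray(Ka, float)
    Kpe = np.asarray(Kpe, float)
    if Ka.shape[0] != design.spec.ka or Kpe.shape[0] != design.spec.kpe:
        raise ValueError("variance component dimensions do not match the model spec")
    r = _residual_vector(design, sigma_e2)
    Rinv = sparse.diags(1.0 / r)
    W = sparse.hstack([sparse.csr_matrix(design.X), design.Z_a, design.Z_p], format="csr")
    C = (W.T @ Rinv @ W).tocsc()
    p = design.X.shape[1]
    Ainv = a_inverse(ped)
    Ginv = sparse.block_diag(
        [sparse.csr_matrix((p, p)),
         sparse.kron(Ainv, np.linalg.inv(Ka)),
         sparse.kron(sparse.identity(len(design.recorded)), np.linalg.inv(Kpe))],
        format="csc",
    )
    C = C + Ginv
    rhs = W.T @ (design.y / r)
    lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
    sol = lu.solve(rhs)
    sol += lu.solve(rhs - C @ sol)  # iterative refinement
    rel = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if rel > tol:
        raise RuntimeError(f"mixed-model equations solved to relative residual {rel:.2e} > {tol:g}")

    ka, kpe = design.spec.ka, design.spec.kpe
    nq = len(ped)
    b = pd.Series(sol[:p], index=design.fixed_names)
    a_hat = pd.DataFrame(sol[p:p + ka * nq].reshape(nq, ka), index=list(ped.animals))
    pe_hat = pd.DataFrame(
        sol[p + ka * nq:].reshape(len(design.recorded), kpe), index=design.recorded
    )
    return ModelSolution(
        fixed=b, a_hat=a_hat, pe_hat=pe_hat,
        diagnostics={"relative_residual": float(rel), "n_equations": C.shape[0]},
    )


def ebv_curve(solution: ModelSolution, animal, basis: LegendreBasis, days) -> np.ndarray:
    """Daily EBV(t) = sum_j a_hat_j phi_j(x(t)) at the requested integer days."""
    coeffs = solution.coefficients(animal)
    if coeffs.shape[0] != basis.order:
        raise ValueError("basis order does not match the solution's coefficient length")
    return np.atleast_2d(basis.row(np.asarray(days))) @ coeffs


def ebv_total(solution: ModelSolution, animal, basis: LegendreBasis, convention: str = "sum") -> float:
    """270-day EBV: sum (or per-day mean) of daily EBVs over the basis day range."""
    if convention not in ("sum", "mean"):
        raise ValueError(f"unknown convention {convention!r}")
    coeffs = solution.coefficients(animal)
    w = basis.grid().mean(axis=0)
    total = float(w @ coeffs)
    if convention == "sum":
        total *= basis.day_max - basis.day_min + 1
    return total
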