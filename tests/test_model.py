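"""Design assembly, mixed-model equations, and EBV curves."""

import numpy as np
import pandas as pd
import pytest

from rrlact.basis import LegendreBasis, pm3_contrast
from rrlact.model import ModelSpec, ModelSolution, build_design, ebv_curve, ebv_total, solve_mme
from rrlact.pedigree import relationship_matrix, validate_and_sort


def dense_gls(design, ped, Ka, Kpe, se2):
    """Joint-MVN conditional-mean oracle for the BLUE/BLUP solution."""
    A = relationship_matrix(ped)
    Ga = np.kron(A, Ka)
    Gp = np.kron(np.eye(len(design.recorded)), Kpe)
    Za, Zp = design.Z_a.toarray(), design.Z_p.toarray()
    R = np.diag(np.atleast_1d(se2)[design.resid_class])
    V = Za @ Ga @ Za.T + Zp @ Gp @ Zp.T + R
    Vi = np.linalg.inv(V)
    X = design.X
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ design.y)
    e = design.y - X @ b
    return b, Ga @ Za.T @ Vi @ e, Gp @ Zp.T @ Vi @ e


def one_animal_records(dim=(30, 100, 200), yld=(0.5, 0.6, 0.4)):
    return pd.DataFrame({
        "animal": 1, "parity": 1, "dim": list(dim), "yield_kg": list(yld),
        "herd": 1, "test_date": [f"2000-0{i+1}-01" for i in range(len(dim))],
        "calving_date": "2000-01-01", "age_months": 30.0,
        "ecotype": 1, "year": 2000, "season": 1,
    })


class TestBuildDesign:
    def test_z_row_is_basis_row_in_animal_block(self, tiny_dataset):
        cfg, records, ped, _ = tiny_dataset
        d = build_design(records, ped, ModelSpec())
        basis = d.basis_a
        i = 7
        row = d.Z_a[i].toarray().ravel()
        block = ped.index_of(records.iloc[i]["animal"]) * 3
        np.testing.assert_allclose(row[block:block + 3], basis.row(int(records.iloc[i]["dim"])))
        assert np.count_nonzero(row) == 3

    def test_same_animal_same_dim_identical_rows(self):
        rec = one_animal_records(dim=(80, 80, 200, 250), yld=(0.5, 0.6, 0.4, 0.45))
        ped = validate_and_sort([(1, 0, 0)])
        d = build_design(rec, ped, ModelSpec())
        np.testing.assert_array_equal(d.Z_a[0].toarray(), d.Z_a[1].toarray())

    def test_full_rank_after_dropping(self, tiny_dataset):
        cfg, records, ped, _ = tiny_dataset
        d = build_design(records, ped, ModelSpec())
        assert np.linalg.matrix_rank(d.X) == d.X.shape[1]

    def test_unknown_animal_rejected(self, tiny_dataset):
        cfg, records, ped, _ = tiny_dataset
        bad = records.copy()
        bad.loc[bad.index[0], "animal"] = 999999
        with pytest.raises(ValueError, match="absent from the pedigree"):
            build_design(bad, ped, ModelSpec())


class TestSolveMME:
    def test_matches_dense_gls_oracle(self, tiny_dataset):
        cfg, records, ped, _ = tiny_dataset
        records = records.iloc[:50]
        d = build_design(records, ped, ModelSpec())
        se2 = cfg.sigma_e2_by_class()
        sol = solve_mme(d, cfg.Ka, cfg.Kpe, se2, ped)
        b, ua, up = dense_gls(d, ped, cfg.Ka, cfg.Kpe, se2)
        np.testing.assert_allclose(sol.fixed.to_numpy(), b, atol=1e-8)
        np.testing.assert_allclose(sol.a_hat.to_numpy().ravel(), ua, atol=1e-8)
        np.testing.assert_allclose(sol.pe_hat.to_numpy().ravel(), up, atol=1e-8)

    def test_ancestor_without_records_equals_oracle(self, tiny_dataset):
        # the dense oracle covers every pedigree animal, including ancestors;
        # their BLUPs are the pedigree projection of their descendants' data
        cfg, records, ped, _ = tiny_dataset
        d = build_design(records, ped, ModelSpec())
        sol = solve_mme(d, cfg.Ka, cfg.Kpe, cfg.sigma_e2_by_class(), ped)
        _, ua, _ = dense_gls(d, ped, cfg.Ka, cfg.Kpe, cfg.sigma_e2_by_class())
        no_records = [a for a in ped.animals if a not in set(records["animal"])]
        assert no_records
        for a in no_records:
            i = ped.index_of(a)
            np.testing.assert_allclose(sol.a_hat.loc[a].to_numpy(), ua[3 * i:3 * i + 3], atol=1e-8)
            assert np.abs(sol.a_hat.loc[a].to_numpy()).max() > 0  # tied in via pedigree

    def test_shrinkage_to_zero_with_huge_residual(self):
        rec = one_animal_records()
        ped = validate_and_sort([(1, 0, 0)])
        d = build_design(rec, ped, ModelSpec())
        Ka = Kpe = 0.01 * np.eye(3)
        a_small = solve_mme(d, Ka, Kpe, 1e6, ped).a_hat.loc[1].to_numpy()
        assert np.abs(a_small).max() < 1e-6

    def test_duplicating_records_with_doubled_residual_is_invariant(self, tiny_dataset):
        cfg, records, ped, _ = tiny_dataset
        d1 = build_design(records, ped, ModelSpec())
        doubled = pd.concat([records, records], ignore_index=True)
        d2 = build_design(doubled, ped, ModelSpec())
        se2 = cfg.sigma_e2_by_class()
        s1 = solve_mme(d1, cfg.Ka, cfg.Kpe, se2, ped)
        s2 = solve_mme(d2, cfg.Ka, cfg.Kpe, 2.0 * se2, ped)
        np.testing.assert_allclose(s1.a_hat.to_numpy(), s2.a_hat.to_numpy(), atol=1e-8)

    def test_record_order_invariance(self, tiny_dataset):
        cfg, records, ped, _ = tiny_dataset
        shuffled = records.sample(frac=1.0, random_state=3).reset_index(drop=True)
        se2 = cfg.sigma_e2_by_class()
        s1 = solve_mme(build_design(records, ped, ModelSpec()), cfg.Ka, cfg.Kpe, se2, ped)
        s2 = solve_mme(build_design(shuffled, ped, ModelSpec()), cfg.Ka, cfg.Kpe, se2, ped)
        np.testing.assert_allclose(s1.a_hat.to_numpy(), s2.a_hat.to_numpy(), atol=1e-9)

    def test_kpe_to_zero_reduces_to_ridge(self):
        # one record per animal, unrelated founders: a_hat solves
        # (Z'Z/se2 + Ka^-1)^-1 Z'(y - X b)/se2
        rng = np.random.default_rng(0)
        n = 12
        rec = pd.DataFrame({
            "animal": np.arange(1, n + 1), "parity": 1,
            "dim": rng.integers(5, 271, n), "yield_kg": rng.normal(0.5, 0.1, n),
            "herd": 1, "test_date": "2000-06-01", "calving_date": "2000-01-01",
            "age_months": 30.0, "ecotype": 1, "year": 2000, "season": 1,
        })
        ped = validate_and_sort([(i, 0, 0) for i in range(1, n + 1)])
        d = build_design(rec, ped, ModelSpec())
        Ka = np.diag([0.02, 0.01, 0.005])
        se2 = 0.03
        sol = solve_mme(d, Ka, 1e-12 * np.eye(3), se2, ped)
        Za = d.Z_a.toarray()
        b = sol.fixed.to_numpy()
        ridge = np.linalg.solve(
            Za.T @ Za / se2 + np.kron(np.eye(n), np.linalg.inv(Ka)),
            Za.T @ (d.y - d.X @ b) / se2,
        )
        np.testing.assert_allclose(sol.a_hat.to_numpy().ravel(), ridge, atol=1e-6)


class TestEBV:
    def _solution(self, coeffs):
        a = pd.DataFrame([coeffs], index=[1])
        return ModelSolution(fixed=pd.Series(dtype=float), a_hat=a,
                             pe_hat=pd.DataFrame(), diagnostics={})

    def test_flat_curve(self):
        basis = LegendreBasis(3)
        sol = self._solution([1 / np.sqrt(0.5), 0.0, 0.0])
        np.testing.assert_allclose(ebv_curve(sol, 1, basis, np.arange(5, 271)), 1.0)

    def test_order1_unit_endpoints(self):
        basis = LegendreBasis(3)
        sol = self._solution([0.0, 1.0, 0.0])
        curve = ebv_curve(sol, 1, basis, [5, 270])
        np.testing.assert_allclose(curve, [-np.sqrt(1.5), np.sqrt(1.5)], atol=1e-12)

    def test_total_flat_and_odd(self):
        basis = LegendreBasis(3)
        flat = self._solution([1 / np.sqrt(0.5), 0.0, 0.0])
        assert ebv_total(flat, 1, basis, "sum") == pytest.approx(266.0)
        assert ebv_total(flat, 1, basis, "mean") == pytest.approx(1.0)
        odd = self._solution([0.0, 1.0, 0.0])
        assert ebv_total(odd, 1, basis, "sum") == pytest.approx(0.0, abs=1e-10)

    def test_total_equals_daily_loop(self):
        rng = np.random.default_rng(8)
        basis = LegendreBasis(5)
        coeffs = rng.normal(size=5)
        sol = ModelSolution(fixed=pd.Series(dtype=float),
                            a_hat=pd.DataFrame([coeffs], index=[1]),
                            pe_hat=pd.DataFrame(), diagnostics={})
        loop = sum(float(basis.row(t) @ coeffs) for t in range(5, 271))
        assert ebv_total(sol, 1, basis, "sum") == pytest.approx(loop, rel=1e-12)

    def test_contrast_of_curve_equals_contrast_of_coefficients(self):
        rng = np.random.default_rng(9)
        basis = LegendreBasis(5)
        coeffs = rng.normal(size=5)
        sol = ModelSolution(fixed=pd.Series(dtype=float),
                            a_hat=pd.DataFrame([coeffs], index=[1]),
                            pe_hat=pd.DataFrame(), diagnostics={})
        c = pm3_contrast(basis)
        via_curve = float(np.diff(ebv_curve(sol, 1, basis, [80, 257]))[0])
        assert via_curve == pytest.approx(float(c.apply(coeffs)), abs=1e-12)

    def test_unknown_animal_lookup_error(self):
        sol = self._solution([0.0, 0.0, 0.0])
        with pytest.raises(KeyError):
            ebv_curve(sol, 42, LegendreBasis(3), [100])
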