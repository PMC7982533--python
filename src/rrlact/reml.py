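"""REML estimation of random-regression covariance components.

Estimates the additive-genetic coefficient covariance Ka, the
permanent-environment coefficient covariance Kpe, and the residual
variance(s) (one per DIM class, or pooled) by restricted maximum
likelihood:

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ] + const.

The engine works on a mixed-model system in which each animal's
permanent-environment equations are absorbed analytically: records of
animal i have working covariance V_i = Phi_i Kpe Phi_i' + R_i, so the
assembled coefficient matrix contains only fixed effects and the additive
equations (with A^-1 (x) Ka^-1).  Every needed piece of the full-system
inverse — prediction-error covariances of pe vectors, per-record leverage
terms — is recovered from the absorbed inverse by block algebra.

Iteration is EM (monotone in logL, guaranteed stable) with optional
average-information (AI) acceleration once the EM steps have moved the
start into the right region; an AI proposal that lowers the likelihood or
leaves the positive-definite cone is rejected in favour of the EM step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import sparse, stats
from scipy.linalg.lapack import dpotri
from scipy.sparse import linalg as spla

from rrlact.model import Design, ModelSpec, build_design
from rrlact.pedigree import Pedigree, a_inverse

__all__ = [
    "VarianceComponents",
    "reml_fit",
    "restricted_log_likelihood",
    "count_parameters",
    "select_model",
]


@dataclass
class VarianceComponents:
    """Converged (or last-iterate) covariance components and their likelihood."""

    Ka: np.ndarray
    Kpe: np.ndarray
    sigma_e2: np.ndarray        # length 9 or length 1
    logL: float
    converged: bool
    n_iter: int
    class_counts: np.ndarray | None = None
    history: list | None = None

    def pooled_sigma_e2(self) -> float:
        """Records-weighted mean residual variance across DIM classes."""
        se = np.atleast_1d(self.sigma_e2)
        if se.size == 1:
            return float(se[0])
        if self.class_counts is None or self.class_counts.sum() == 0:
            return float(se.mean())
        w = self.class_counts / self.class_counts.sum()
        return float(w @ se)


def count_parameters(spec: ModelSpec) -> int:
    """Number of (co)variance parameters: ka(ka+1)/2 + kpe(kpe+1)/2 + residual classes."""
    return (
        spec.ka * (spec.ka + 1) // 2
        + spec.kpe * (spec.kpe + 1) // 2
        + spec.residual_classes
    )


# ---------------------------------------------------------------------------
# workspace: static structures shared by all iterations on one data set


class _Workspace:
    """Per-fit precomputation: record grouping, sparse designs, pedigree terms."""

    def __init__(self, design: Design, ped: Pedigree):
        self.spec = design.spec
        self.ka, self.kpe = design.spec.ka, design.spec.kpe
        self.ped = ped
        self.q = len(ped)
        self.qr = len(design.recorded)
        self.p = design.X.shape[1]
        self.m = self.p + self.ka * self.q

        # sort records so each animal's rows are contiguous
        order = np.lexsort((np.arange(design.n_records), design.animal_row))
        self.y = design.y[order]
        self.klass = design.resid_class[order]
        self.n = self.y.shape[0]
        X = sparse.csr_matrix(design.X)[order]
        self.X = X
        dims = design.dim[order]
        self.phi_a = design.basis_a.row(dims)
        self.phi_p = design.basis_p.row(dims)
        self.anim = design.animal_row[order]          # pedigree index per record
        rec_animals = design.recorded
        pos = {ped.index_of(a): i for i, a in enumerate(rec_animals)}
        self.rec_of_record = np.array([pos[i] for i in self.anim])
        self.rec_ped_idx = np.array([ped.index_of(a) for a in rec_animals])

        # group boundaries per recorded animal
        starts = np.flatnonzero(np.r_[True, self.anim[1:] != self.anim[:-1]])
        self.group_start = np.r_[starts, self.n]
        self.groups = [
            slice(self.group_start[g], self.group_start[g + 1])
            for g in range(len(starts))
        ]
        self.group_ped_idx = self.anim[starts]
        self.group_rec_idx = self.rec_of_record[starts]

        # sparse [X | Z_a] with additive columns after the fixed block
        rows = np.repeat(np.arange(self.n), self.ka)
        cols = (self.p + self.anim[:, None] * self.ka + np.arange(self.ka)).ravel()
        Za = sparse.csr_matrix((self.phi_a.ravel(), (rows, cols)), shape=(self.n, self.m))
        self.W = sparse.hstack([X, sparse.csr_matrix((self.n, self.ka * self.q))]).tocsr() + Za

        # local fixed-column support per animal
        self.local_fixed = []
        for sl in self.groups:
            cols_loc = np.unique(X[sl].indices)
            self.local_fixed.append(cols_loc)

        self.Ainv = a_inverse(ped).tocoo()
        self.Ainv_csc = self.Ainv.tocsc()
        self._Ainv_lu = spla.splu(self.Ainv_csc)
        self.log_det_a = ped.log_det_a()
        self.n_classes = 9 if design.spec.residual_classes == 9 else 1
        self.class_counts = np.bincount(self.klass, minlength=self.n_classes).astype(float)

    # -- per-parameter-value quantities -------------------------------------

    def _per_animal(self, Kpe, se2):
        """Per-animal V_i^-1 and log|V_i| for the current parameters."""
        out_inv, logdet = [], 0.0
        for sl in self.groups:
            phi_p = self.phi_p[sl]
            r = se2[self.klass[sl]]
            V = phi_p @ Kpe @ phi_p.T + np.diag(r)
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                raise np.linalg.LinAlgError("non-PD working covariance")
            logdet += ld
            out_inv.append(np.linalg.inv(V))
        return out_inv, logdet

    def _assemble(self, Ka, Kpe, se2):
        Vinv_blocks, logdet_v = self._per_animal(Kpe, se2)
        Vinv = sparse.block_diag(Vinv_blocks, format="csr")
        C = (self.W.T @ Vinv @ self.W).tocsc()
        Kainv = np.linalg.inv(Ka)
        G = sparse.block_diag(
            [sparse.csr_matrix((self.p, self.p)), sparse.kron(self.Ainv_csc, Kainv)],
            format="csc",
        )
        C = C + G
        rhs = self.W.T @ (Vinv @ self.y)
        return C, rhs, Vinv, logdet_v

    def _finish_loglik(self, Ka, logdet_v, log_det_c, yPy):
        sign_ka, logdet_ka = np.linalg.slogdet(Ka)
        if sign_ka <= 0:
            raise np.linalg.LinAlgError("Ka not positive definite")
        log_det_g = self.ka * self.log_det_a + self.q * logdet_ka
        return -0.5 * (logdet_v + log_det_g + log_det_c + yPy)

    def loglik_terms(self, Ka, Kpe, se2):
        """Likelihood-only evaluation via a fill-reducing sparse factorization."""
        C, rhs, Vinv, logdet_v = self._assemble(Ka, Kpe, se2)
        lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
        sol = lu.solve(rhs)
        log_det_c = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        yPy = float(self.y @ (Vinv @ self.y) - rhs @ sol)
        logL = self._finish_loglik(Ka, logdet_v, log_det_c, yPy)
        return logL, lu, sol, Vinv, C, rhs

    def dense_terms(self, Ka, Kpe, se2):
        """Dense Cholesky factorization with the full inverse of the system.

        Used by the EM/AI iteration, which needs prediction-error covariance
        blocks throughout the coefficient-matrix inverse; LAPACK potrf/potri
        on the dense matrix beats chunked sparse solves at these sizes.
        """
        C, rhs, Vinv, logdet_v = self._assemble(Ka, Kpe, se2)
        Cd = C.toarray()
        cho = sla.cho_factor(Cd, lower=True, overwrite_a=True, check_finite=False)
        sol = sla.cho_solve(cho, rhs, check_finite=False)
        log_det_c = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        yPy = float(self.y @ (Vinv @ self.y) - rhs @ sol)
        logL = self._finish_loglik(Ka, logdet_v, log_det_c, yPy)
        H, info = dpotri(cho[0], lower=1)
        if info != 0:
            raise np.linalg.LinAlgError(f"potri failed with info={info}")
        H = np.tril(H) + np.tril(H, -1).T  # potri fills the lower triangle only
        return logL, cho, H, sol, Vinv


# ---------------------------------------------------------------------------
# parameter packing


def _vech_indices(k):
    return [(r, s) for r in range(k) for s in range(r, k)]


def _pack(Ka, Kpe, se2, active):
    return np.r_[
        [Ka[r, s] for r, s in _vech_indices(Ka.shape[0])],
        [Kpe[r, s] for r, s in _vech_indices(Kpe.shape[0])],
        se2[active],
    ]


def _unpack(theta, ka, kpe, se2_template, active):
    Ka = np.zeros((ka, ka))
    Kpe = np.zeros((kpe, kpe))
    i = 0
    for r, s in _vech_indices(ka):
        Ka[r, s] = Ka[s, r] = theta[i]
        i += 1
    for r, s in _vech_indices(kpe):
        Kpe[r, s] = Kpe[s, r] = theta[i]
        i += 1
    se2 = se2_template.copy()
    se2[active] = theta[i:]
    return Ka, Kpe, se2


def _project_pd(K, floor_frac=1e-8):
    vals, vecs = np.linalg.eigh(K)
    floor = max(vals.max(), 0.0) * floor_frac
    if floor <= 0:
        floor = floor_frac
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


# ---------------------------------------------------------------------------
# one EM / AI iteration


def _em_quantities(ws: _Workspace, Ka, Kpe, se2):
    """EM-updated components plus gradient pieces at the current parameters."""
    logL, cho, H, sol, Vinv = ws.dense_terms(Ka, Kpe, se2)
    p, ka, kpe, q = ws.p, ws.ka, ws.kpe, ws.q
    b_hat = sol[:p]
    a_hat = sol[p:].reshape(q, ka)

    Kpe_inv = np.linalg.inv(Kpe)
    Ka_inv = np.linalg.inv(Ka)
    se_vec = se2[ws.klass]

    # --- additive component ------------------------------------------------
    Ai = ws.Ainv  # COO
    rows3 = p + Ai.row[:, None] * ka + np.arange(ka)
    cols3 = p + Ai.col[:, None] * ka + np.arange(ka)
    # T[r, s] = sum_e Ainv_e * H[row_e*ka+r, col_e*ka+s]  (PEV part of the EM update)
    T = np.einsum("e,ers->rs", Ai.data, H[rows3[:, :, None], cols3[:, None, :]])
    quad_a = a_hat.T @ (ws.Ainv_csc @ a_hat)
    Ka_em = (quad_a + T) / q
    Ka_em = 0.5 * (Ka_em + Ka_em.T)

    # --- per-animal pe and residual terms ----------------------------------
    Xcsr = ws.X
    fitted_fa = np.asarray(ws.W @ sol)        # X b + Za a
    resid_fa = ws.y - fitted_fa               # residual before pe
    Kpe_em = np.zeros((kpe, kpe))
    T_pe = np.zeros((kpe, kpe))
    pe_hat = np.zeros((ws.qr, kpe))
    ehat = np.empty(ws.n)
    vterm = np.empty(ws.n)
    for g, sl in enumerate(ws.groups):
        phi_p = ws.phi_p[sl]
        r_i = se_vec[sl]
        Rinv = 1.0 / r_i
        D = phi_p.T @ (phi_p * Rinv[:, None]) + Kpe_inv
        Dinv = np.linalg.inv(D)
        res_i = resid_fa[sl]
        pe_i = Dinv @ (phi_p.T @ (res_i * Rinv))
        pe_hat[ws.group_rec_idx[g]] = pe_i

        # local index set: fixed columns + the animal's additive columns
        fcols = ws.local_fixed[g]
        acols = p + ws.group_ped_idx[g] * ka + np.arange(ka)
        idx = np.r_[fcols, acols]
        Xl = np.asarray(Xcsr[sl][:, fcols].toarray())
        Wl = np.hstack([Xl, ws.phi_a[sl]])          # n_i x (f + ka)
        Bl = Wl.T @ (phi_p * Rinv[:, None])          # (f+ka) x kpe
        Hl = H[np.ix_(idx, idx)]
        M = Hl @ Bl                                   # (f+ka) x kpe
        pev = Dinv + Dinv @ (Bl.T @ M) @ Dinv
        Kpe_em += np.outer(pe_i, pe_i) + pev
        T_pe += pev

        # residual leverage per record
        e_i = res_i - phi_p @ pe_i
        ehat[sl] = e_i
        BD = M @ Dinv                                 # H B D^-1 restricted to idx
        u_H = Wl @ Hl                                 # n_i x (f+ka)
        v1 = np.einsum("ij,ij->i", u_H, Wl)           # w' H w
        v2 = np.einsum("ij,ij->i", Wl @ BD, phi_p)    # w' (H B Dinv) t
        v3 = np.einsum("ij,ij->i", phi_p @ pev, phi_p)
        vterm[sl] = v1 - 2.0 * v2 + v3
    Kpe_em /= ws.qr
    Kpe_em = 0.5 * (Kpe_em + Kpe_em.T)

    se2_em = se2.copy()
    active = ws.class_counts > 0
    for c in np.flatnonzero(active):
        mask = ws.klass == c
        se2_em[c] = (ehat[mask] @ ehat[mask] + vterm[mask].sum()) / ws.class_counts[c]

    # --- gradient ----------------------------------------------------------
    Py = ehat / se_vec
    Ta = (ws.phi_a * Py[:, None])
    Ta_anim = np.zeros((q, ka))
    np.add.at(Ta_anim, ws.anim, Ta)
    ATa = ws._Ainv_lu.solve(Ta_anim)                 # A @ Ta  (since lu factors A^-1)
    Ma = Ta_anim.T @ ATa
    KiTKi = Ka_inv @ T @ Ka_inv

    Tp = ws.phi_p * Py[:, None]
    Tp_anim = np.zeros((ws.qr, kpe))
    np.add.at(Tp_anim, ws.rec_of_record, Tp)
    Mp = Tp_anim.T @ Tp_anim
    KpiTKpi = Kpe_inv @ T_pe @ Kpe_inv

    grad = []
    for r, s in _vech_indices(ka):
        E = _sym_basis(ka, r, s)
        tr_term = q * np.sum(E * Ka_inv) - np.sum(E * KiTKi)
        grad.append(-0.5 * (tr_term - np.sum(E * Ma)))
    for r, s in _vech_indices(kpe):
        E = _sym_basis(kpe, r, s)
        tr_term = ws.qr * np.sum(E * Kpe_inv) - np.sum(E * KpiTKpi)
        grad.append(-0.5 * (tr_term - np.sum(E * Mp)))
    for c in np.flatnonzero(active):
        mask = ws.klass == c
        tr_term = float(np.sum(1.0 / se_vec[mask]) - np.sum(vterm[mask] / se_vec[mask] ** 2))
        quad = float(np.sum(Py[mask] ** 2))
        grad.append(-0.5 * (tr_term - quad))
    grad = np.asarray(grad)

    aux = {
        "logL": logL, "cho": cho, "Vinv": Vinv, "Py": Py,
        "ATa": ATa, "Tp_anim": Tp_anim, "active": active,
        "a_hat": a_hat, "pe_hat": pe_hat,
    }
    return (Ka_em, Kpe_em, se2_em), grad, aux


def _sym_basis(k, r, s):
    E = np.zeros((k, k))
    E[r, s] += 1.0
    E[s, r] += 1.0
    if r == s:
        E[r, s] = 1.0
    return E


def _apply_P(ws: _Workspace, cho, Vinv, F: np.ndarray) -> np.ndarray:
    """P F (columnwise) for the full model, via the absorbed factorization."""
    VF = Vinv @ F
    S = sla.cho_solve(cho, ws.W.T @ VF, check_finite=False)
    return VF - Vinv @ (ws.W @ S)


def _ai_matrix(ws: _Workspace, aux, Ka, Kpe, se2) -> np.ndarray:
    """Average-information matrix over the active parameter vector."""
    ka, kpe = ws.ka, ws.kpe
    Py = aux["Py"]
    fs = []
    for r, s in _vech_indices(ka):
        E = _sym_basis(ka, r, s)
        Gm = aux["ATa"] @ E
        fs.append(np.einsum("ij,ij->i", ws.phi_a, Gm[ws.anim]))
    for r, s in _vech_indices(kpe):
        E = _sym_basis(kpe, r, s)
        Gm = aux["Tp_anim"] @ E
        fs.append(np.einsum("ij,ij->i", ws.phi_p, Gm[ws.rec_of_record]))
    for c in np.flatnonzero(aux["active"]):
        f = np.where(ws.klass == c, Py, 0.0)
        fs.append(f)
    F = np.column_stack(fs)
    PF = _apply_P(ws, aux["cho"], aux["Vinv"], F)
    AI = 0.5 * (F.T @ PF)
    return 0.5 * (AI + AI.T)


# ---------------------------------------------------------------------------
# driver


def reml_fit(
    records: pd.DataFrame,
    ped: Pedigree,
    spec: ModelSpec,
    basis=None,
    init: tuple | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_em: int = 3,
    use_ai: bool = True,
    verbose: bool = False,
) -> VarianceComponents:
    """Fit (Ka, Kpe, sigma_e2) by EM-REML with AI acceleration.

    ``init`` may supply (Ka0, Kpe0, sigma_e2_0); the default start is
    Ka = Kpe = 0.1 var(y) I and sigma_e2 = 0.8 var(y).  Non-convergence
    within ``max_iter`` returns the last iterate flagged ``converged=False``
    rather than raising.
    """
    design = build_design(records, ped, spec, basis=basis)
    ws = _Workspace(design, ped)

    vy = float(np.var(ws.y))
    if init is None:
        Ka = 0.1 * vy * np.eye(spec.ka)
        Kpe = 0.1 * vy * np.eye(spec.kpe)
        se2 = np.full(ws.n_classes, 0.8 * vy)
    else:
        Ka, Kpe, se2 = (np.asarray(v, float).copy() for v in init)
        se2 = np.atleast_1d(se2)
        if se2.size == 1:
            se2 = np.full(ws.n_classes, se2[0])

    active = ws.class_counts > 0
    history = []
    logL_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        (Ka_em, Kpe_em, se2_em), grad, aux = _em_quantities(ws, Ka, Kpe, se2)
        logL = aux["logL"]
        history.append(logL)
        if verbose:
            print(f"iter {it:3d} logL {logL:.6f}")
        if abs(logL - logL_prev) < tol:
            converged = True
            break
        logL_prev = logL

        stepped = False
        if use_ai and it > n_em:
            theta = _pack(Ka, Kpe, se2, active)
            try:
                AI = _ai_matrix(ws, aux, Ka, Kpe, se2)
                delta = np.linalg.solve(AI + 1e-10 * np.eye(AI.shape[0]), grad)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(6):
                    Ka_t, Kpe_t, se2_t = _unpack(theta + step * delta, spec.ka, spec.kpe, se2, active)
                    Ka_t = _project_pd(Ka_t)
                    Kpe_t = _project_pd(Kpe_t)
                    se2_t = np.clip(se2_t, 1e-10, None)
                    try:
                        logL_t = ws.loglik_terms(Ka_t, Kpe_t, se2_t)[0]
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if logL_t >= logL - 1e-9:
                        Ka, Kpe, se2 = Ka_t, Kpe_t, se2_t
                        stepped = True
                        break
                    step *= 0.5
        if not stepped:
            Ka, Kpe, se2 = _project_pd(Ka_em), _project_pd(Kpe_em), np.clip(se2_em, 1e-12, None)

    final_logL = restricted_log_likelihood(Ka, Kpe, se2, design, ped, workspace=ws)
    return VarianceComponents(
        Ka=Ka, Kpe=Kpe, sigma_e2=se2, logL=final_logL,
        converged=converged, n_iter=it,
        class_counts=ws.class_counts, history=history,
    )


def restricted_log_likelihood(
    Ka, Kpe, sigma_e2, design: Design, ped: Pedigree, workspace: _Workspace | None = None
) -> float:
    """REML log-likelihood -1/2 [log|V| + log|X'V^-1 X| + y'Py] (no constant)."""
    ws = workspace if workspace is not None else _Workspace(design, ped)
    se2 = np.atleast_1d(np.asarray(sigma_e2, float))
    if se2.size == 1:
        se2 = np.full(ws.n_classes, se2[0])
    return float(ws.loglik_terms(np.asarray(Ka, float), np.asarray(Kpe, float), se2)[0])


# ---------------------------------------------------------------------------
# model selection (order-of-fit comparison)


def select_model(fits: list[tuple[ModelSpec, VarianceComponents]], alpha: float = 0.05,
                 criterion: str = "lrt"):
    """Compare orders of fit and choose a model.

    ``fits`` holds (spec, components) pairs estimated on the same records.
    The comparison table mirrors the order-of-fit report: ka, kpe, NP, logL.
    Default selection: likelihood-ratio tests among nested pairs at ``alpha``,
    preferring the fewest parameters when no nested larger model is
    significantly better; ``criterion="max_logl"`` picks the highest logL.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    rows = []
    for i, (spec, vc) in enumerate(fits):
        rows.append({
            "model": i + 1, "ka": spec.ka, "kpe": spec.kpe,
            "NP": count_parameters(spec), "logL": vc.logL,
        })
    table = pd.DataFrame(rows)

    def nested(small: ModelSpec, big: ModelSpec) -> bool:
        return (small.ka <= big.ka and small.kpe <= big.kpe
                and (small.ka, small.kpe) != (big.ka, big.kpe))

    if criterion == "max_logl":
        best = int(table["logL"].idxmax())
        # parsimony tie-break on effectively equal likelihoods
        near = table[np.isclose(table["logL"], table.loc[best, "logL"], atol=1e-8)]
        best = int(near["NP"].idxmin())
        return fits[best][0], table
    if criterion != "lrt":
        raise ValueError(f"unknown selection criterion {criterion!r}")

    order = table.sort_values(["NP", "logL"], ascending=[True, False]).index
    for i in order:
        spec_i, vc_i = fits[i]
        beaten = False
        for j in range(len(fits)):
            spec_j, vc_j = fits[j]
            if not nested(spec_i, spec_j):
                continue
            df = count_parameters(spec_j) - count_parameters(spec_i)
            lr = 2.0 * (vc_j.logL - vc_i.logL)
            if df > 0 and lr > stats.chi2.ppf(1 - alpha, df):
                beaten = True
                break
        if not beaten:
            return fits[i][0], table
    return fits[int(table["logL"].idxmax())][0], table
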