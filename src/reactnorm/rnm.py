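"""Reaction-norm GBLUP: Legendre basis, AI-REML fitting, AIC model ladder.

The model for a yield record of hybrid j in environment i is

    y_ij = Env_i + sum_k ( a_kj + be_kj ) * phi_k(theta_i) + e_ij

where theta_i in [-1, 1] is the environmental gradient, phi_k are normalized
Legendre polynomials, the additive coefficient vectors a_j are jointly
N(0, G (x) C_a) with G a genomic relationship matrix, the broad-environment
(repeated-record) coefficients be_j are N(0, I (x) C_be), and the residual
variance is either a single sigma^2 or the exponential link
sigma^2_i = exp(d0 + d1 * theta_i).

Variance components are estimated by average-information REML on the mixed
model equations, with step halving and an EM fallback when an AI step is not
admissible.  Records are collapsed to (environment, hybrid) cell sufficient
statistics, which is exact because the residual variance is constant within
an environment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from scipy.linalg import cho_solve, cho_factor
from scipy.linalg.lapack import dpotrf, dpotri

from .genotypes import GRM

__all__ = [
    "legendre_basis",
    "ModelSpec",
    "ResidualModel",
    "RNMFit",
    "ModelComparison",
    "ConvergenceError",
    "fit_rnm",
    "model_aic",
    "compare_models",
    "DEFAULT_LADDER",
]

_LOG2PI = math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Legendre basis
# ---------------------------------------------------------------------------

def legendre_basis(theta, order: int = 2, tol: float = 1e-6) -> np.ndarray:
    """Normalized Legendre polynomial basis evaluated at each theta.

    phi_k(t) = sqrt((2k+1)/2) * P_k(t), the convention of the random
    regression literature, which makes the columns orthonormal under the
    continuous inner product on [-1, 1].

    Parameters
    ----------
    theta : array-like in [-1, 1]
    order : highest polynomial degree; 1 or 2 in the model ladder, 0 is the
        intercept-only basis used by the plain-GBLUP arm.

    Returns
    -------
    (len(theta), order+1) matrix with row i = (phi_0, ..., phi_order)(theta_i).
    """
    if order not in (0, 1, 2):
        raise ValueError(f"order must be 0, 1 or 2, got {order}")
    t = np.atleast_1d(np.asarray(theta, dtype=float))
    if np.any(np.abs(t) > 1.0 + tol):
        raise ValueError("theta outside [-1, 1]")
    t = np.clip(t, -1.0, 1.0)
    cols = []
    for k in range(order + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        cols.append(math.sqrt((2 * k + 1) / 2.0) * npleg.legval(t, coef))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Model specification and fit containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Reaction-norm model variant.

    order : polynomial order of the random regression (0 = plain GBLUP arm)
    residual : 'homogeneous' or 'heterogeneous' (exponential link on theta)
    include_be : include the broad-environment repeated-record term
    include_bm : report the fixed average-curve regression b_m.  The b_m
        columns lie in the span of the environment fixed effects, so the fit
        itself is unchanged; when set, b_m is reported as the projection of
        the environment effects onto the polynomial basis.
    blend : identity blend fraction expected of the supplied GRM (recorded
        for provenance; the GRM itself carries the blend actually applied).
    """

    order: int = 2
    residual: str = "heterogeneous"
    include_be: bool = True
    include_bm: bool = False
    blend: float | None = None

    def __post_init__(self):
        if self.order not in (0, 1, 2):
            raise ValueError("order must be 0, 1 or 2")
        if self.residual not in ("homogeneous", "heterogeneous"):
            raise ValueError("residual must be homogeneous or heterogeneous")

    @property
    def n_coef(self) -> int:
        return self.order + 1

    @property
    def n_vc_params(self) -> int:
        na = self.n_coef
        k = na * (na + 1) // 2
        if self.include_be:
            k *= 2
        k += 2 if self.residual == "heterogeneous" else 1
        return k

    def label(self) -> str:
        return f"order{self.order}-{self.residual}" + (
            "" if self.include_be else "-nobe")


@dataclass
class ResidualModel:
    """Residual variance model: sigma^2_i = exp(d0 + d1 * theta_i)."""

    kind: str
    d0: float
    d1: float = 0.0

    def variance(self, theta) -> np.ndarray:
        return np.exp(self.d0 + self.d1 * np.asarray(theta, dtype=float))

    @property
    def sigma2(self) -> float:
        if self.kind != "homogeneous":
            raise ValueError("sigma2 is only defined for the homogeneous model")
        return float(np.exp(self.d0))


@dataclass
class RNMFit:
    """Converged reaction-norm fit."""

    spec: ModelSpec
    env_ids: list
    theta: np.ndarray
    T: np.ndarray
    beta_env: pd.Series
    a_hat: pd.DataFrame
    be_hat: pd.DataFrame | None
    C_a: np.ndarray
    C_be: np.ndarray | None
    residual: ResidualModel
    logL: float
    converged: bool
    n_iter: int
    trace: list = field(repr=False, default_factory=list)
    n_records: int = 0
    n_fixed: int = 0
    grm_blend: float = 0.0
    b_m: np.ndarray | None = None

    @property
    def n_vc_params(self) -> int:
        return self.spec.n_vc_params

    def residual_variances(self) -> np.ndarray:
        return self.residual.variance(self.theta)


@dataclass
class ModelComparison:
    """AIC table over the candidate model ladder."""

    table: pd.DataFrame
    fits: dict
    selected: ModelSpec

    @property
    def best_fit(self) -> RNMFit:
        return self.fits[self.selected.label()]


# ---------------------------------------------------------------------------
# vech helpers (lower-triangle packing, row-major)
# ---------------------------------------------------------------------------

def _vech_indices(n: int):
    return [(i, j) for i in range(n) for j in range(i + 1)]


def _vech(M: np.ndarray) -> np.ndarray:
    return np.array([M[i, j] for i, j in _vech_indices(M.shape[0])])


def _unvech(v: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    for val, (i, j) in zip(v, _vech_indices(n)):
        M[i, j] = M[j, i] = val
    return M


def _floor_psd(M: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone with an eigenvalue floor."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w[0] >= floor:
        return M
    w = np.maximum(w, floor)
    return (V * w) @ V.T


# ---------------------------------------------------------------------------
# internal fitting machinery
# ---------------------------------------------------------------------------

class _Problem:
    """Collapsed data and fixed structure for one REML problem."""

    def __init__(self, phenotypes: pd.DataFrame, theta_map: dict, grm: GRM,
                 spec: ModelSpec, y_col: str):
        self.spec = spec
        env_ids = sorted(phenotypes["env_id"].unique())
        missing = [e for e in env_ids if e not in theta_map]
        if missing:
            raise ValueError(f"gradient does not cover environments: {missing}")
        self.env_ids = env_ids
        self.theta = np.array([theta_map[e] for e in env_ids], dtype=float)
        self.T = legendre_basis(self.theta, spec.order)
        self.E = len(env_ids)
        self.na = spec.n_coef

        self.hybrids = list(grm.samples)
        hyb_index = {h: i for i, h in enumerate(self.hybrids)}
        self.q = len(self.hybrids)
        ph = phenotypes[["env_id", "hybrid_id", y_col]].copy()
        unknown = set(ph["hybrid_id"]) - set(hyb_index)
        if unknown:
            raise ValueError(
                f"{len(unknown)} phenotyped hybrids missing from the GRM, "
                f"e.g. {sorted(unknown)[:3]}")

        env_code = ph["env_id"].map({e: i for i, e in enumerate(env_ids)})
        hyb_code = ph["hybrid_id"].map(hyb_index)
        y = ph[y_col].to_numpy(dtype=float)
        cell_key = env_code.to_numpy() * self.q + hyb_code.to_numpy()
        order_ix = np.argsort(cell_key, kind="stable")
        ck, start = np.unique(cell_key[order_ix], return_index=True)
        ys = y[order_ix]
        self.cn = np.diff(np.append(start, len(ys))).astype(float)
        sums = np.add.reduceat(ys, start)
        self.cmean = sums / self.cn
        sq = np.add.reduceat(ys * ys, start)
        self.css = sq - self.cn * self.cmean ** 2
        self.ce = (ck // self.q).astype(int)
        self.cj = (ck % self.q).astype(int)
        self.n = len(ys)

        # phenotyped hybrids (be effects are only carried for these)
        ph_ids = np.unique(self.cj)
        self.ph_all = ph_ids                       # all-hybrid indices
        ph_map = {j: p for p, j in enumerate(ph_ids)}
        self.qp = len(ph_ids)
        self.cjp = np.array([ph_map[j] for j in self.cj], dtype=int)

        self.Ginv = grm.inverse()
        self.G_logdet = grm.logdet()
        self.grm_blend = grm.blend

        self.nb = self.na if spec.include_be else 0
        self.m = self.E + self.q * self.na + self.qp * self.nb
        # column offsets
        self.a_off = self.E
        self.be_off = self.E + self.q * self.na

        # per-env record counts
        self.n_env = np.bincount(self.ce, weights=self.cn,
                                 minlength=self.E)

        # gather indices for per-cell quadratic forms (env, a_j, be_j cols)
        na, nb = self.na, self.nb
        idx = [self.ce]
        for k in range(na):
            idx.append(self.a_off + self.cj * na + k)
        for k in range(nb):
            idx.append(self.be_off + self.cjp * nb + k)
        self.cell_cols = np.column_stack(idx)
        Tc = self.T[self.ce]
        self.cell_vals = np.column_stack(
            [np.ones(len(self.ce))] + [Tc] * (2 if nb else 1))

    # -- parameter packing ------------------------------------------------
    def pack(self, C_a, C_be, d) -> np.ndarray:
        parts = [_vech(C_a)]
        if self.nb:
            parts.append(_vech(C_be))
        parts.append(np.asarray(d, dtype=float))
        return np.concatenate(parts)

    def unpack(self, v: np.ndarray):
        na, nb = self.na, self.nb
        ka = na * (na + 1) // 2
        C_a = _unvech(v[:ka], na)
        pos = ka
        C_be = None
        if nb:
            kb = nb * (nb + 1) // 2
            C_be = _unvech(v[pos:pos + kb], nb)
            pos += kb
        d = v[pos:]
        return C_a, C_be, d

    def admissible(self, v: np.ndarray) -> np.ndarray:
        """Project packed parameters into the admissible region."""
        C_a, C_be, d = self.unpack(v)
        C_a = _floor_psd(C_a)
        if C_be is not None:
            C_be = _floor_psd(C_be)
        d = np.clip(d, -30.0, 30.0)
        return self.pack(C_a, C_be, d)

    # -- core evaluations --------------------------------------------------
    def _weights(self, d):
        d0 = d[0]
        d1 = d[1] if len(d) > 1 else 0.0
        logs2 = d0 + d1 * self.theta
        return np.exp(-logs2), logs2

    def solve(self, v: np.ndarray):
        """Assemble and factor the MME; return logL and solutions."""
        C_a, C_be, d = self.unpack(v)
        E, q, qp, na, nb, m = (self.E, self.q, self.qp, self.na, self.nb,
                               self.m)
        w_env, logs2 = self._weights(d)
        wc = self.cn * w_env[self.ce]                 # cell weight n_c / s2_e
        Tc = self.T[self.ce]

        C = np.zeros((m, m))
        # X'R-1X (diagonal: env one-hot fixed effects)
        np.add.at(C, (np.arange(E), np.arange(E)), 0.0)
        xtx = np.bincount(self.ce, weights=wc, minlength=E)
        C[np.arange(E), np.arange(E)] = xtx

        # couplings and data blocks
        F = np.zeros((E, qp, na))                     # X'R-1 Z_a (phenotyped)
        np.add.at(F, (self.ce, self.cjp), wc[:, None] * Tc)
        D = np.zeros((qp, na, na))                    # Z'R-1Z diag blocks
        np.add.at(D, self.cjp,
                  wc[:, None, None] * Tc[:, :, None] * Tc[:, None, :])

        a_cols = self.a_off + self.ph_all[:, None] * na + np.arange(na)
        # X - a
        C[:E, :][:, a_cols.ravel()] = F.reshape(E, qp * na)
        C[a_cols.ravel(), :E] = F.reshape(E, qp * na).T
        # a - a data part
        rows = np.repeat(a_cols, na, axis=1).reshape(qp, na, na)
        cols = np.tile(a_cols, (1, na)).reshape(qp, na, na)
        np.add.at(C, (rows, cols), D)
        # prior G^-1 (x) C_a^-1
        Ca_inv = np.linalg.inv(C_a)
        C[self.a_off:self.a_off + q * na,
          self.a_off:self.a_off + q * na] += np.kron(self.Ginv, Ca_inv)

        Cbe_inv = None
        if nb:
            be_cols = self.be_off + np.arange(qp)[:, None] * nb + np.arange(nb)
            C[:E, :][:, be_cols.ravel()] = F.reshape(E, qp * nb)
            C[be_cols.ravel(), :E] = F.reshape(E, qp * nb).T
            rb = np.repeat(a_cols, nb, axis=1).reshape(qp, na, nb)
            cb = np.tile(be_cols, (1, na)).reshape(qp, na, nb)
            np.add.at(C, (rb, cb), D)
            np.add.at(C, (np.swapaxes(cb, 1, 2), np.swapaxes(rb, 1, 2)),
                      np.swapaxes(D, 1, 2))
            Cbe_inv = np.linalg.inv(C_be)
            rows_b = np.repeat(be_cols, nb, axis=1).reshape(qp, nb, nb)
            cols_b = np.tile(be_cols, (1, nb)).reshape(qp, nb, nb)
            np.add.at(C, (rows_b, cols_b), D + Cbe_inv)

        # RHS
        rhs = np.zeros(m)
        yw = wc * self.cmean
        rhs[:E] = np.bincount(self.ce, weights=yw, minlength=E)
        ra = np.zeros((qp, na))
        np.add.at(ra, self.cjp, yw[:, None] * Tc)
        rhs[a_cols.ravel()] = ra.ravel()
        if nb:
            rhs[be_cols.ravel()] = ra.ravel()

        cf, info = dpotrf(C, lower=1, overwrite_a=0)
        if info != 0:
            raise np.linalg.LinAlgError(
                "MME coefficient matrix not positive definite"
                + ("" if self.grm_blend else
                   "; the GRM is unblended - consider blend > 0"))
        sol = cho_solve((cf, True), rhs)

        y_r1y = float(np.sum(w_env[self.ce] * self.css) + np.sum(yw * self.cmean))
        yPy = y_r1y - float(rhs @ sol)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf))))
        log_R = float(np.sum(self.n_env * logs2))
        sign_a, ld_a = np.linalg.slogdet(C_a)
        if sign_a <= 0:
            raise np.linalg.LinAlgError("C_a not positive definite")
        log_prior = na * self.G_logdet + q * ld_a
        if nb:
            sign_b, ld_b = np.linalg.slogdet(C_be)
            if sign_b <= 0:
                raise np.linalg.LinAlgError("C_be not positive definite")
            log_prior += qp * ld_b
        m2l = ((self.n - E) * _LOG2PI + log_R + log_prior + logdet_C + yPy)
        logL = -0.5 * m2l

        aux = {
            "cf": cf, "sol": sol, "C_a": C_a, "C_be": C_be, "d": d,
            "Ca_inv": Ca_inv, "Cbe_inv": Cbe_inv, "w_env": w_env,
            "wc": wc, "Tc": Tc, "F": F, "D": D,
            "a_cols": a_cols, "be_cols": be_cols if nb else None,
        }
        return logL, aux

    def grad_matrices(self, aux):
        """Gradient of logL w.r.t. C_a, C_be (full symmetric matrices) and d.

        Returns (GM_a, GM_be, grad_d, em) where dl = tr(GM_a dC_a) +
        tr(GM_be dC_be) + grad_d . dd and ``em`` carries the EM-update
        sufficient statistics.
        """
        E, q, qp, na, nb = self.E, self.q, self.qp, self.na, self.nb
        sol = aux["sol"]
        Ca_inv, Cbe_inv = aux["Ca_inv"], aux["Cbe_inv"]
        w_env, Tc = aux["w_env"], aux["Tc"]
        d = aux["d"]

        inv, info = dpotri(aux["cf"], lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        Cinv = np.tril(inv) + np.tril(inv, -1).T
        aux["Cinv"] = Cinv

        U = sol[self.a_off:self.a_off + q * na].reshape(q, na)
        Ube = (sol[self.be_off:].reshape(qp, nb) if nb else None)
        aux["U"], aux["Ube"] = U, Ube

        Cuu_aa = Cinv[self.a_off:self.a_off + q * na,
                      self.a_off:self.a_off + q * na].reshape(q, na, q, na)
        Phi_a = np.einsum("ab,akbl->kl", self.Ginv, Cuu_aa, optimize=True)
        UGU = U.T @ self.Ginv @ U
        N_a = q * Ca_inv - Ca_inv @ Phi_a @ Ca_inv
        Q_a = Ca_inv @ UGU @ Ca_inv
        GM_a = -0.5 * (N_a - Q_a)

        GM_be = None
        em = {"Phi_a": Phi_a, "UGU": UGU}
        if nb:
            be_cols = aux["be_cols"]
            bb = Cinv[be_cols[:, :, None].repeat(nb, 2),
                      be_cols[:, None, :].repeat(nb, 1)]
            Phi_be = bb.sum(axis=0)
            UbUb = Ube.T @ Ube
            N_be = qp * Cbe_inv - Cbe_inv @ Phi_be @ Cbe_inv
            Q_be = Cbe_inv @ UbUb @ Cbe_inv
            GM_be = -0.5 * (N_be - Q_be)
            em.update(Phi_be=Phi_be, UbUb=UbUb)

        # residual link parameters
        cols = self.cell_cols
        sub = Cinv[cols[:, :, None], cols[:, None, :]]
        v = self.cell_vals
        qf = np.einsum("ci,cj,cij->c", v, v, sub, optimize=True)
        beta = sol[:E]
        fit_c = beta[self.ce] + np.sum(Tc * U[self.cj], axis=1)
        if nb:
            fit_c = fit_c + np.sum(Tc * Ube[self.cjp], axis=1)
        rc = self.cmean - fit_c
        w_c = w_env[self.ce]
        sse_c = self.css + self.cn * rc ** 2
        aux.update(qf=qf, rc=rc, w_c=w_c, sse_c=sse_c)

        n_d = 2 if len(d) > 1 else 1
        taus = [np.ones(len(self.ce))]
        if n_d > 1:
            taus.append(self.theta[self.ce])
        aux["taus"] = taus
        grad_d = np.empty(n_d)
        for k in range(n_d):
            tr = float(np.sum(self.cn * taus[k] * (1.0 - w_c * qf)))
            yterm = float(np.sum(w_c * taus[k] * sse_c))
            grad_d[k] = -0.5 * (tr - yterm)
        return GM_a, GM_be, grad_d, em

    def derivs(self, aux):
        """REML gradient (packed) and AI matrix at the current parameters."""
        E, q, qp, na, nb = self.E, self.q, self.qp, self.na, self.nb
        GM_a, GM_be, grad_d, em = self.grad_matrices(aux)
        Ca_inv, Cbe_inv = aux["Ca_inv"], aux["Cbe_inv"]
        w_env, Tc = aux["w_env"], aux["Tc"]
        U, Ube = aux["U"], aux["Ube"]
        rc, w_c, sse_c = aux["rc"], aux["w_c"], aux["sse_c"]
        taus = aux["taus"]
        n_d = len(taus)

        grad_blocks = [np.array(
            [(2.0 if i != j else 1.0) * GM_a[i, j]
             for i, j in _vech_indices(na)])]
        if nb:
            grad_blocks.append(np.array(
                [(2.0 if i != j else 1.0) * GM_be[i, j]
                 for i, j in _vech_indices(nb)]))
        grad_blocks.append(grad_d)
        grad = np.concatenate(grad_blocks)

        # --- AI matrix -----------------------------------------------------
        # f-vector cell representations
        phis = []          # covariance-type params: phi constant per cell
        for i, j in _vech_indices(na):
            Eij = np.zeros((na, na))
            Eij[i, j] = Eij[j, i] = 1.0
            At = U @ Ca_inv @ Eij
            phis.append(np.sum(Tc * At[self.cj], axis=1))
        if nb:
            for i, j in _vech_indices(nb):
                Eij = np.zeros((nb, nb))
                Eij[i, j] = Eij[j, i] = 1.0
                Bt = Ube @ Cbe_inv @ Eij
                phis.append(np.sum(Tc * Bt[self.cjp], axis=1))
        n_cov = len(phis)
        P = n_cov + n_d

        # W'R-1 f for every parameter
        Gmat = np.zeros((self.m, P))
        wc = aux["wc"]
        a_cols = aux["a_cols"]
        for k, phi in enumerate(phis):
            u = wc * phi
            Gmat[:E, k] = np.bincount(self.ce, weights=u, minlength=E)
            gk = np.zeros((qp, na))
            np.add.at(gk, self.cjp, u[:, None] * Tc)
            Gmat[a_cols.ravel(), k] = gk.ravel()
            if nb:
                Gmat[aux["be_cols"].ravel(), k] = gk.ravel()
        for k in range(n_d):
            u = w_c * taus[k] * self.cn * rc
            col = n_cov + k
            Gmat[:E, col] = np.bincount(self.ce, weights=u, minlength=E)
            gk = np.zeros((qp, na))
            np.add.at(gk, self.cjp, u[:, None] * Tc)
            Gmat[a_cols.ravel(), col] = gk.ravel()
            if nb:
                Gmat[aux["be_cols"].ravel(), col] = gk.ravel()

        Z = cho_solve((aux["cf"], True), Gmat)

        S = np.zeros((P, P))
        for k in range(n_cov):
            for l in range(k, n_cov):
                S[k, l] = S[l, k] = float(np.sum(wc * phis[k] * phis[l]))
        for k in range(n_cov):
            for l in range(n_d):
                val = float(np.sum(w_c * taus[l] * phis[k] * self.cn * rc))
                S[k, n_cov + l] = S[n_cov + l, k] = val
        for k in range(n_d):
            for l in range(k, n_d):
                val = float(np.sum(w_c * taus[k] * taus[l] * sse_c))
                S[n_cov + k, n_cov + l] = S[n_cov + l, n_cov + k] = val
        AI = 0.5 * (S - Gmat.T @ Z)
        AI = 0.5 * (AI + AI.T)
        return grad, AI, em

    def em_step(self, v: np.ndarray, em: dict) -> np.ndarray:
        C_a, C_be, d = self.unpack(v)
        C_a = (em["UGU"] + em["Phi_a"]) / self.q
        if self.nb:
            C_be = (em["UbUb"] + em["Phi_be"]) / self.qp
        return self.pack(_floor_psd(C_a),
                         _floor_psd(C_be) if self.nb else None, d)


def _tri_indices(n: int):
    return [(i, j) for i in range(n) for j in range(i + 1)]


def _chol_pack(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor packed row-major, log-transformed diagonal."""
    L = np.linalg.cholesky(_floor_psd(C))
    out = []
    for i, j in _tri_indices(C.shape[0]):
        out.append(math.log(max(L[i, j], 1e-12)) if i == j else L[i, j])
    return np.array(out)


def _chol_unpack(x: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    L = np.zeros((n, n))
    for val, (i, j) in zip(x, _tri_indices(n)):
        L[i, j] = math.exp(min(val, 30.0)) if i == j else val
    return L @ L.T, L


def _polish_lbfgs(prob: _Problem, v: np.ndarray, fix_d1: bool,
                  max_iter: int = 300):
    """Quasi-Newton refinement in an unconstrained log-Cholesky space.

    Used when the AI loop cannot finish on its own (typically a solution on
    or near the PSD boundary, where projected AI steps degenerate).  The
    gradient in Cholesky coordinates is dl/dL = 2 (dl/dC) L by the chain
    rule, with the diagonal additionally scaled by L_ii for the log
    transform.
    """
    from scipy.optimize import minimize

    na, nb = prob.na, prob.nb
    ka = na * (na + 1) // 2
    C_a, C_be, d = prob.unpack(v)
    x0 = [_chol_pack(C_a)]
    if nb:
        x0.append(_chol_pack(C_be))
    n_d_all = len(d)
    d_free = 1 if (fix_d1 and n_d_all == 2) else n_d_all
    x0.append(d[:d_free])
    x0 = np.concatenate(x0)

    def split(x):
        Ca, La = _chol_unpack(x[:ka], na)
        pos = ka
        Cb = Lb = None
        if nb:
            Cb, Lb = _chol_unpack(x[pos:pos + ka], nb)
            pos += ka
        dd = np.zeros(n_d_all)
        dd[:d_free] = x[pos:]
        return Ca, La, Cb, Lb, dd

    def fun(x):
        Ca, La, Cb, Lb, dd = split(x)
        try:
            logL, aux = prob.solve(prob.pack(Ca, Cb, dd))
            GM_a, GM_be, grad_d, _ = prob.grad_matrices(aux)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(x)
        g = []
        GL = 2.0 * GM_a @ La
        for i, j in _tri_indices(na):
            g.append(GL[i, j] * (La[i, i] if i == j else 1.0))
        if nb:
            GLb = 2.0 * GM_be @ Lb
            for i, j in _tri_indices(nb):
                g.append(GLb[i, j] * (Lb[i, i] if i == j else 1.0))
        g.extend(grad_d[:d_free])
        return -logL, -np.array(g)

    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-13,
                            "gtol": 1e-7})
    Ca, _, Cb, _, dd = split(res.x)
    v_out = prob.admissible(prob.pack(Ca, Cb, dd))
    if fix_d1 and n_d_all == 2:
        v_out[-1] = 0.0
    return v_out, res


def _start_values(prob: _Problem, spec: ModelSpec) -> np.ndarray:
    """Data-driven starting values for the variance parameters."""
    resid = prob.cmean - np.bincount(
        prob.ce, weights=prob.cn * prob.cmean, minlength=prob.E)[prob.ce] / \
        np.maximum(prob.n_env[prob.ce], 1.0)
    vp = float(np.average(resid ** 2, weights=prob.cn)
               + np.sum(prob.css) / prob.n)
    vp = max(vp, 1e-4)
    na = spec.n_coef
    C_a = vp * np.diag([1.0, 0.3, 0.1][:na])
    C_be = vp * np.diag([0.3, 0.1, 0.05][:na]) if spec.include_be else None
    d = [math.log(0.5 * vp)] + ([0.0] if spec.residual == "heterogeneous"
                                else [])
    return prob.pack(C_a, C_be, np.array(d))


def fit_rnm(phenotypes: pd.DataFrame, gradient, grm: GRM,
            spec: ModelSpec | None = None, y_col: str = "yield_Mg_ha",
            max_iter: int = 200, tol_param: float = 1e-8,
            tol_logl: float = 1e-9, start: np.ndarray | None = None,
            fix_d1: bool = False, verbose: bool = False) -> RNMFit:
    """Fit the reaction-norm GBLUP by AI-REML.

    Parameters
    ----------
    phenotypes : records with columns env_id, hybrid_id and ``y_col``.
    gradient : mapping env_id -> theta (an ``EnvironmentGradient``, dict or
        pandas Series).
    grm : genomic relationship matrix over at least all phenotyped hybrids;
        coefficient predictions are returned for every GRM hybrid, so
        unphenotyped relatives obtain predictions through G.
    spec : model variant (defaults to the order-2 heterogeneous model).
    start : optional packed parameter start (warm starting the ladder).
    fix_d1 : constrain the residual-link slope d1 to zero while keeping the
        heterogeneous parameterization (nested-model checks).
    """
    spec = spec or ModelSpec()
    theta_map = _as_theta_map(gradient)
    prob = _Problem(phenotypes, theta_map, grm, spec, y_col)

    v = prob.admissible(start if start is not None
                        else _start_values(prob, spec))
    n_d = 2 if spec.residual == "heterogeneous" else 1
    d1_idx = len(v) - 1 if (n_d == 2) else None
    if fix_d1 and d1_idx is not None:
        v[d1_idx] = 0.0

    trace: list[dict] = []
    logL, aux = prob.solve(v)
    converged = False
    n_iter = 0
    lam = 0.0          # Levenberg-Marquardt damping on the AI step
    for it in range(1, max_iter + 1):
        n_iter = it
        grad, AI, em = prob.derivs(aux)
        if fix_d1 and d1_idx is not None:
            grad = grad.copy()
            grad[-1] = 0.0
            AI = AI.copy()
            AI[-1, :] = AI[:, -1] = 0.0
            AI[-1, -1] = 1.0
        ai_scale = float(np.mean(np.abs(np.diag(AI)))) + 1e-12

        new_v, new_logL, new_aux, how = None, None, None, "ai"
        lam_try = lam
        for _ in range(8):
            damp = (lam_try * ai_scale + 1e-10) * np.eye(len(AI))
            try:
                step = np.linalg.solve(AI + damp, grad)
            except np.linalg.LinAlgError:
                lam_try = max(4.0 * lam_try, 1e-4)
                continue
            if not np.all(np.isfinite(step)):
                lam_try = max(4.0 * lam_try, 1e-4)
                continue
            cand = prob.admissible(v + step)
            if fix_d1 and d1_idx is not None:
                cand[d1_idx] = 0.0
            try:
                cl, ca = prob.solve(cand)
            except np.linalg.LinAlgError:
                lam_try = max(4.0 * lam_try, 1e-4)
                continue
            if cl >= logL - 1e-9:
                new_v, new_logL, new_aux = cand, cl, ca
                lam = lam_try / 4.0 if lam_try > 1e-4 else 0.0
                break
            lam_try = max(4.0 * lam_try, 1e-4)
        if new_v is None:
            how = "em"
            lam = max(lam, 1e-4)
            cand = prob.em_step(v, em)
            if fix_d1 and d1_idx is not None:
                cand[d1_idx] = 0.0
            try:
                cl, ca = prob.solve(cand)
            except np.linalg.LinAlgError:
                cl = -np.inf
            if cl >= logL - 1e-9:
                new_v, new_logL, new_aux = cand, cl, ca
            else:
                # neither a damped AI step nor EM can improve the REML
                # log-likelihood: numerical optimum (often a PSD boundary)
                trace.append({"iter": it, "logL": logL, "step": "stall",
                              "max_rel_change": 0.0, "delta_logL": 0.0})
                converged = True
                break

        dpar = float(np.max(np.abs(new_v - v) / (np.abs(v) + 1.0)))
        dlog = new_logL - logL
        trace.append({"iter": it, "logL": new_logL, "step": how,
                      "max_rel_change": dpar, "delta_logL": dlog})
        if verbose:
            print(f"  it {it:3d} logL {new_logL:.6f} ({how}) "
                  f"dpar {dpar:.2e} dlogL {dlog:.2e}")
        v, logL, aux = new_v, new_logL, new_aux
        if dpar < tol_param or abs(dlog) < tol_logl:
            converged = True
            break
        # diminishing returns: when 20 iterations gain < 1e-6 logL in total
        # the component estimates are at their numerical optimum (typically a
        # PSD-boundary solution where derivative precision is the limit)
        if it >= 20 and logL - trace[-20]["logL"] < 1e-6:
            converged = True
            break
    if not converged:
        # AI/EM loop exhausted its budget; refine with quasi-Newton in the
        # unconstrained log-Cholesky parameterization
        v_pol, res = _polish_lbfgs(prob, v, fix_d1)
        pol_logL, pol_aux = prob.solve(v_pol)
        trace.append({"iter": n_iter + 1, "logL": pol_logL, "step": "lbfgs",
                      "max_rel_change": float(
                          np.max(np.abs(v_pol - v) / (np.abs(v) + 1.0))),
                      "delta_logL": pol_logL - logL,
                      "nfev": int(res.nfev)})
        if pol_logL >= logL - 1e-9 and np.isfinite(pol_logL):
            # the refinement ran to its own termination (convergence or the
            # line-search precision limit of a PSD-boundary solution)
            v, logL, aux = v_pol, pol_logL, pol_aux
            converged = True
        else:
            raise ConvergenceError(
                f"AI-REML did not converge in {max_iter} iterations and the "
                f"quasi-Newton refinement failed ({res.message})", trace)

    C_a, C_be, d = prob.unpack(v)
    sol = aux["sol"]
    na = spec.n_coef
    beta_env = pd.Series(sol[:prob.E], index=prob.env_ids, name="beta")
    a_hat = pd.DataFrame(
        sol[prob.a_off:prob.a_off + prob.q * na].reshape(prob.q, na),
        index=prob.hybrids, columns=[f"a{k}" for k in range(na)])
    be_hat = None
    if prob.nb:
        be_full = np.zeros((prob.q, na))
        be_full[prob.ph_all] = sol[prob.be_off:].reshape(prob.qp, na)
        be_hat = pd.DataFrame(be_full, index=prob.hybrids,
                              columns=[f"be{k}" for k in range(na)])
    resid = ResidualModel(spec.residual, float(d[0]),
                          float(d[1]) if len(d) > 1 else 0.0)
    b_m = None
    if spec.include_bm:
        # projection of env effects onto the polynomial basis (the b_m
        # columns span a subspace of the env fixed effects)
        b_m, *_ = np.linalg.lstsq(prob.T, beta_env.to_numpy(), rcond=None)
    return RNMFit(spec=spec, env_ids=prob.env_ids, theta=prob.theta,
                  T=prob.T, beta_env=beta_env, a_hat=a_hat, be_hat=be_hat,
                  C_a=C_a, C_be=C_be, residual=resid, logL=float(logL),
                  converged=converged, n_iter=n_iter, trace=trace,
                  n_records=prob.n, n_fixed=prob.E,
                  grm_blend=prob.grm_blend, b_m=b_m)


def _as_theta_map(gradient) -> dict:
    if hasattr(gradient, "theta_map"):
        return dict(gradient.theta_map())
    if isinstance(gradient, pd.Series):
        return gradient.to_dict()
    if isinstance(gradient, pd.DataFrame):
        return dict(zip(gradient["env_id"], gradient["theta"]))
    return dict(gradient)


# ---------------------------------------------------------------------------
# AIC ladder
# ---------------------------------------------------------------------------

DEFAULT_LADDER = (
    ModelSpec(order=1, residual="homogeneous"),
    ModelSpec(order=1, residual="heterogeneous"),
    ModelSpec(order=2, residual="homogeneous"),
    ModelSpec(order=2, residual="heterogeneous"),
)


def model_aic(fit: RNMFit) -> float:
    """AIC = -2 logL_REML + 2k with k the free (co)variance parameters.

    Comparisons are only meaningful between fits sharing the same fixed
    effects (the ladder keeps the environment fixed effect throughout).
    """
    return -2.0 * fit.logL + 2.0 * fit.n_vc_params


def compare_models(phenotypes: pd.DataFrame, gradient, grm: GRM,
                   ladder=DEFAULT_LADDER, y_col: str = "yield_Mg_ha",
                   **fit_kwargs) -> ModelComparison:
    """Fit the candidate ladder and select the minimum-AIC model.

    Fits are warm-started left to right where the coefficient dimension
    allows.  A member failure is flagged in the table rather than raised,
    unless every member fails.
    """
    rows, fits = [], {}
    env_sets = set()
    prev: RNMFit | None = None
    for spec in ladder:
        start = None
        if prev is not None:
            start = _warm_start(prev, spec)
        try:
            fit = fit_rnm(phenotypes, gradient, grm, spec, y_col=y_col,
                          start=start, **fit_kwargs)
            fits[spec.label()] = fit
            env_sets.add(tuple(fit.env_ids))
            rows.append({"order": spec.order, "residual": spec.residual,
                         "logL": fit.logL, "k": spec.n_vc_params,
                         "AIC": model_aic(fit), "converged": True})
            prev = fit
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as err:
            rows.append({"order": spec.order, "residual": spec.residual,
                         "logL": np.nan, "k": spec.n_vc_params,
                         "AIC": np.nan, "converged": False,
                         "error": str(err)})
    if len(env_sets) > 1:
        raise ValueError("ladder fits do not share fixed-effect structure")
    table = pd.DataFrame(rows)
    if table["AIC"].isna().all():
        raise RuntimeError("every ladder member failed to converge")
    best = int(table["AIC"].idxmin())
    selected = ladder[best]
    return ModelComparison(table=table, fits=fits, selected=selected)


def _warm_start(prev: RNMFit, spec: ModelSpec) -> np.ndarray | None:
    """Map a previous fit's parameters onto a new spec's parameter vector."""
    na = spec.n_coef
    C_a = np.eye(na) * max(np.diag(prev.C_a).min(), 1e-3)
    k = min(na, prev.C_a.shape[0])
    C_a[:k, :k] = prev.C_a[:k, :k]
    C_a = _floor_psd(C_a)
    C_be = None
    if spec.include_be:
        if prev.C_be is not None:
            C_be = np.eye(na) * max(np.diag(prev.C_be).min(), 1e-4)
            C_be[:k, :k] = prev.C_be[:k, :k]
            C_be = _floor_psd(C_be)
        else:
            C_be = 0.05 * C_a
    d = [prev.residual.d0]
    if spec.residual == "heterogeneous":
        d.append(prev.residual.d1)
    parts = [_vech(C_a)]
    if spec.include_be:
        parts.append(_vech(C_be))
    parts.append(np.array(d))
    return np.concatenate(parts)
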