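"""Legendre basis and the AI-REML reaction-norm machinery."""

from conftest import dense_reml_logl

import math

import numpy as np
import pandas as pd
import pytest

from reactnorm import (GRM, ModelSpec, fit_rnm, legendre_basis, model_aic,
                       simulate_parents, make_hybrids, simulate_trial,
                       SimulationConfig, grm_vanraden1)
from reactnorm.rnm import _Problem


class TestLegendreBasis:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, (0.70711, 0.0, -0.79057)),
        (1.0, (0.70711, 1.22474, 1.58114)),
        (-1.0, (0.70711, -1.22474, 1.58114)),
    ])
    def test_closed_forms(self, theta, expected):
        row = legendre_basis([theta], 2)[0]
        np.testing.assert_allclose(row, expected, atol=5e-6)

    def test_orthonormal_under_quadrature(self):
        x, w = np.polynomial.legendre.leggauss(20)
        T = legendre_basis(x, 2)
        gram = (T * w[:, None]).T @ T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-10)

    def test_rejects_out_of_domain(self):
        with pytest.raises(ValueError, match="theta"):
            legendre_basis([1.2], 2)

    def test_rejects_unsupported_order(self):
        with pytest.raises(ValueError, match="order"):
            legendre_basis([0.0], 3)


def _toy_problem(seed=7, q=10, E=5, order=2, include_be=True, hetero=True,
                 density=0.9):
    """Small simulated data plus matching problem/GRM objects."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(q, q))
    G = A @ A.T / q + 0.5 * np.eye(q)
    d = np.sqrt(np.diag(G))
    G = G / np.outer(d, d) + 0.01 * np.eye(q)
    grm = GRM([f"H{i}" for i in range(q)], G, 1.0, 0.01)
    theta = np.linspace(-1, 1, E)
    T = legendre_basis(theta, order)
    na = order + 1
    Ca = np.diag([0.5, 0.2, 0.05][:na])
    Cbe = np.diag([0.1, 0.03, 0.01][:na])
    a = (np.linalg.cholesky(np.kron(G, Ca))
         @ rng.normal(size=q * na)).reshape(q, na)
    be = (rng.normal(size=(q, na)) @ np.sqrt(Cbe))
    rows = []
    for e in range(E):
        for j in range(q):
            if rng.random() < density:
                for rep in range(2):
                    sd = math.sqrt(math.exp(-0.7 + (0.5 if hetero else 0)
                                            * theta[e]))
                    rows.append((f"E{e}", f"H{j}",
                                 8 + theta[e] + T[e] @ (a[j] + be[j])
                                 + rng.normal() * sd))
    ph = pd.DataFrame(rows, columns=["env_id", "hybrid_id", "yield_Mg_ha"])
    tmap = {f"E{e}": theta[e] for e in range(E)}
    return ph, tmap, grm, dict(Ca=Ca, Cbe=Cbe, a=a)


class TestREMLInternals:
    def test_mme_logl_matches_dense_evaluation(self):
        ph, tmap, grm, truth = _toy_problem()
        spec = ModelSpec()
        prob = _Problem(ph, tmap, grm, spec, "yield_Mg_ha")
        v = prob.pack(truth["Ca"], truth["Cbe"], np.array([-0.7, 0.5]))
        logL, _ = prob.solve(v)
        dense = dense_reml_logl(ph, tmap, grm, 2, True, truth["Ca"],
                                 truth["Cbe"], -0.7, 0.5)
        assert logL == pytest.approx(dense, abs=1e-8)

    def test_gradient_matches_finite_differences(self):
        ph, tmap, grm, truth = _toy_problem(seed=9, q=8, E=4)
        spec = ModelSpec()
        prob = _Problem(ph, tmap, grm, spec, "yield_Mg_ha")
        v = prob.pack(truth["Ca"], truth["Cbe"], np.array([-0.7, 0.5]))
        _, aux = prob.solve(v)
        grad, _, _ = prob.derivs(aux)
        num = np.empty_like(v)
        for k in range(len(v)):
            vp, vm = v.copy(), v.copy()
            vp[k] += 1e-6
            vm[k] -= 1e-6
            num[k] = (prob.solve(vp)[0] - prob.solve(vm)[0]) / 2e-6
        np.testing.assert_allclose(grad, num, atol=1e-4, rtol=1e-4)


class TestFitRNM:
    def test_nested_heterogeneous_with_d1_zero_matches_homogeneous(self):
        ph, tmap, grm, _ = _toy_problem(seed=15, q=20, E=6, hetero=False)
        homo = fit_rnm(ph, tmap, grm, ModelSpec(residual="homogeneous"))
        het0 = fit_rnm(ph, tmap, grm, ModelSpec(residual="heterogeneous"),
                       fix_d1=True)
        assert abs(homo.logL - het0.logL) < 1e-6
        assert het0.residual.d1 == 0.0

    def test_unphenotyped_hybrid_coefficients_follow_conditional_mean(self):
        ph, tmap, grm, _ = _toy_problem(seed=17, q=12, E=5)
        drop = "H3"
        ph = ph[ph["hybrid_id"] != drop]
        fit = fit_rnm(ph, tmap, grm, ModelSpec())
        hybs = list(fit.a_hat.index)
        u = hybs.index(drop)
        others = [i for i, h in enumerate(hybs) if h != drop]
        G = grm.matrix
        w = np.linalg.solve(G[np.ix_(others, others)], G[u, others])
        expect = w @ fit.a_hat.to_numpy()[others]
        np.testing.assert_allclose(fit.a_hat.loc[drop].to_numpy(), expect,
                                   atol=1e-6)
        assert fit.be_hat.loc[drop].abs().max() == 0.0

    def test_null_broad_environment_component_shrinks(self):
        par, _ = simulate_parents(40, 300, seed=25)
        _, hyb = make_hybrids(par, 100, seed=26)
        cfg = SimulationConfig(n_parents=40, n_snps=300, n_hybrids=100,
                               n_envs=12, n_years=2, incidence_density=0.7,
                               C_be=np.zeros((3, 3)), seed=27)
        pheno, truth = simulate_trial(hyb, cfg)
        grm = grm_vanraden1(hyb, blend=0.01)
        fit = fit_rnm(pheno, truth.true_theta, grm, ModelSpec())
        assert np.abs(fit.C_be).max() < 0.1
        assert np.abs(np.diag(fit.C_a) - np.diag(cfg.C_a)).max() < 0.3

    def test_order0_fit_equals_closed_form_gblup(self):
        """The intercept-only arm must reproduce a directly solved GBLUP at
        the same variance components."""
        ph, tmap, grm, _ = _toy_problem(seed=19, q=15, E=5, hetero=False)
        fit = fit_rnm(ph, tmap, grm,
                      ModelSpec(order=0, residual="homogeneous",
                                include_be=False))
        # closed-form mixed-model solve at the fitted components
        va = fit.C_a[0, 0] * 0.5          # phi_0^2 = 1/2
        ve = fit.residual.sigma2
        envs = sorted(ph["env_id"].unique())
        ei = ph["env_id"].map({e: i for i, e in enumerate(envs)}).to_numpy()
        hi = ph["hybrid_id"].map(
            {h: i for i, h in enumerate(grm.samples)}).to_numpy()
        y = ph["yield_Mg_ha"].to_numpy()
        n, E, q = len(y), len(envs), grm.n
        X = np.zeros((n, E))
        X[np.arange(n), ei] = 1.0
        Z = np.zeros((n, q))
        Z[np.arange(n), hi] = 1.0
        C = np.block([
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + ve / va * np.linalg.inv(grm.matrix)]])
        sol = np.linalg.solve(C, np.concatenate([X.T @ y, Z.T @ y]))
        g_direct = sol[E:]
        g_fit = fit.a_hat.to_numpy()[:, 0] * math.sqrt(0.5)
        np.testing.assert_allclose(g_fit, g_direct, atol=1e-5)

    def test_constant_theta_order1_reproduces_gblup_ranking(self):
        """With a constant gradient the order-1 model collapses onto plain
        GBLUP: intercept predictions correlate > 0.9999."""
        ph, tmap, grm, _ = _toy_problem(seed=21, q=30, E=4, hetero=False)
        const_map = {e: 0.3 for e in tmap}
        rn = fit_rnm(ph, const_map, grm,
                     ModelSpec(order=1, residual="homogeneous",
                               include_be=False))
        gb = fit_rnm(ph, const_map, grm,
                     ModelSpec(order=0, residual="homogeneous",
                               include_be=False))
        t = legendre_basis([0.3], 1)[0]
        pred_rn = rn.a_hat.to_numpy() @ t
        pred_gb = gb.a_hat.to_numpy()[:, 0] * legendre_basis([0.3], 0)[0, 0]
        r = np.corrcoef(pred_rn, pred_gb)[0, 1]
        assert r > 0.9999

    def test_missing_gradient_environment_errors(self):
        ph, tmap, grm, _ = _toy_problem()
        bad = {k: v for k, v in tmap.items() if k != "E0"}
        with pytest.raises(ValueError, match="gradient does not cover"):
            fit_rnm(ph, bad, grm, ModelSpec())

    def test_phenotyped_hybrid_missing_from_grm_errors(self):
        ph, tmap, grm, _ = _toy_problem()
        small = GRM(grm.samples[:-1], grm.matrix[:-1, :-1], 1.0, 0.01)
        with pytest.raises(ValueError, match="missing from the GRM"):
            fit_rnm(ph, tmap, small, ModelSpec())


class TestAIC:
    @pytest.mark.parametrize("spec,k", [
        (ModelSpec(order=2, residual="heterogeneous"), 14),
        (ModelSpec(order=1, residual="homogeneous"), 7),
        (ModelSpec(order=1, residual="heterogeneous"), 8),
        (ModelSpec(order=2, residual="homogeneous"), 13),
        (ModelSpec(order=2, residual="heterogeneous", include_be=False), 8),
    ])
    def test_free_parameter_count(self, spec, k):
        assert spec.n_vc_params == k

    def test_aic_formula(self):
        ph, tmap, grm, _ = _toy_problem(seed=23, q=12, E=5)
        fit = fit_rnm(ph, tmap, grm, ModelSpec(order=1,
                                               residual="homogeneous"))
        assert model_aic(fit) == pytest.approx(-2 * fit.logL + 2 * 7)
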