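"""SNP-effect backsolving, selection with LD pruning, allele-state tests."""

import numpy as np
import pandas as pd
import pytest

from reactnorm import (GenotypeMatrix, ModelSpec, SimulationConfig,
                       allele_state_test, annotation_window_query,
                       backsolve_snp_effects, fit_rnm, grm_vanraden1,
                       legendre_basis, make_hybrids, select_top_snps,
                       simulate_parents, simulate_trial, snp_env_effects)
from reactnorm.params import gebv_trajectories


class TestBacksolve:
    def test_reconstruction_identity_with_unblended_grm(self, exact_fit):
        geno = exact_fit["hybrids"]
        Z = geno.values - 2.0 * exact_fit["freq"]
        u = backsolve_snp_effects(Z, exact_fit["fit"].a_hat,
                                  snp_ids=geno.snps["snp_id"])
        recon = Z @ u.to_numpy()
        err = np.abs(recon - exact_fit["fit"].a_hat.to_numpy()).max()
        assert err < 1e-6

    def test_monomorphic_snp_zero_effect(self):
        rng = np.random.default_rng(1)
        M = rng.integers(0, 3, size=(20, 10)).astype(float)
        M[:, 4] = 2.0                               # monomorphic
        Z = M - M.mean(axis=0)
        a = pd.DataFrame(rng.normal(size=(20, 3)),
                         columns=["a0", "a1", "a2"])
        u = backsolve_snp_effects(Z, a)
        assert np.all(u.to_numpy()[4] == 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(15, 30))
        a = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a0", "a1"])
        u1 = backsolve_snp_effects(Z, a)
        u2 = backsolve_snp_effects(Z, 2.0 * a)
        np.testing.assert_allclose(u2.to_numpy(), 2.0 * u1.to_numpy(),
                                   atol=1e-10)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            backsolve_snp_effects(np.zeros((5, 3)),
                                  pd.DataFrame(np.zeros((4, 2))))

    def test_composition_equals_environmentwise_backsolve(self, exact_fit):
        """Basis-expanding coefficient effects equals backsolving directly
        against per-environment GEBVs (checked to 1e-8)."""
        fit = exact_fit["fit"]
        geno = exact_fit["hybrids"]
        Z = geno.values - 2.0 * exact_fit["freq"]
        u = backsolve_snp_effects(Z, fit.a_hat)
        via_coeff = snp_env_effects(u, T=fit.T, env_ids=fit.env_ids)
        gebv = gebv_trajectories(fit.a_hat, T=fit.T, env_ids=fit.env_ids)
        direct = backsolve_snp_effects(Z, gebv)
        np.testing.assert_allclose(via_coeff.to_numpy(),
                                   direct.to_numpy(), atol=1e-8)


class TestSnpEnvEffects:
    def test_intercept_effect_constant_across_environments(self):
        u = pd.DataFrame([[0.3, 0.0, 0.0]], index=["s"],
                         columns=["a0", "a1", "a2"])
        eff = snp_env_effects(u, theta=np.linspace(-1, 1, 5))
        np.testing.assert_allclose(eff.to_numpy()[0],
                                   0.3 * np.sqrt(0.5), atol=1e-12)

    def test_slope_effect_antisymmetric(self):
        u = pd.DataFrame([[0.0, 0.4, 0.0]], index=["s"],
                         columns=["a0", "a1", "a2"])
        eff = snp_env_effects(u, theta=[-0.7, 0.0, 0.7]).to_numpy()[0]
        assert eff[1] == pytest.approx(0.0, abs=1e-12)
        assert eff[0] == pytest.approx(-eff[2], abs=1e-12)

    def test_order_mismatch_errors(self):
        u = pd.DataFrame([[0.1, 0.2]], columns=["a0", "a1"])
        with pytest.raises(ValueError, match="order mismatch"):
            snp_env_effects(u, T=legendre_basis([0.0], 2))


class TestSelection:
    def _ld(self, pairs):
        return pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"])

    def test_total_ld_collapses_to_one_pick(self):
        snps = [f"s{i}" for i in range(6)]
        eff = pd.DataFrame(np.linspace(1, 0.5, 6)[:, None],
                           index=snps, columns=["E1"])
        pairs = [(a, b, 0.9) for i, a in enumerate(snps)
                 for b in snps[i + 1:]]
        sel = select_top_snps(eff, k=5, ld_table=self._ld(pairs))
        assert sel["per_env"]["E1"] == ["s0"]
        assert sel["union"] == ["s0"]

    def test_identical_environments_identical_selections(self):
        rng = np.random.default_rng(3)
        snps = [f"s{i}" for i in range(20)]
        col = rng.normal(size=20)
        eff = pd.DataFrame({"E1": col, "E2": col}, index=snps)
        sel = select_top_snps(eff, k=5, ld_table=self._ld([]))
        assert sel["per_env"]["E1"] == sel["per_env"]["E2"]

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        snps = [f"s{i}" for i in range(15)]
        eff = pd.DataFrame(rng.normal(size=(15, 3)), index=snps,
                           columns=["E1", "E2", "E3"])
        ld = self._ld([("s0", "s1", 0.5)])
        s1 = select_top_snps(eff, k=4, ld_table=ld)
        s2 = select_top_snps(3.0 * eff, k=4, ld_table=ld)
        assert s1 == s2

    def test_k_below_one_errors(self):
        with pytest.raises(ValueError, match="k"):
            select_top_snps(pd.DataFrame({"E": [1.0]}, index=["s"]),
                            k=0, ld_table=self._ld([]))

    def test_planted_qtl_recovered(self):
        """Three independent large-effect loci drive the trait; all three
        appear in the union selection and their per-environment effect
        profiles rank-correlate with the truth."""
        from scipy.stats import spearmanr

        from conftest import disjoint_cross_hybrids

        parents, cross, hybrids, pfreq = disjoint_cross_hybrids(40, 400,
                                                                seed=41)
        cfg = SimulationConfig(n_parents=100, n_snps=400, n_hybrids=40,
                               n_envs=8, n_years=2, incidence_density=1.0,
                               C_a=np.diag([1e-4, 1e-4, 1e-4]),
                               C_be=np.zeros((3, 3)), d0=-2.5, d1=0.0,
                               seed=43)
        pheno, truth = simulate_trial(hybrids, cfg)
        # choose 3 well-separated polymorphic SNPs and add their effects
        freq = hybrids.compute_freq()
        poly = np.nonzero((freq > 0.6) & (freq < 0.9))[0]
        qtl = [int(poly[5]), int(poly[len(poly) // 2]), int(poly[-5])]
        theta = truth.true_theta
        T = legendre_basis(theta.to_numpy(), 2)
        coef = np.array([[0.8, 0.4, 0.0],      # variable-magnitude QTL
                         [0.0, 0.6, 0.0],      # slope QTL
                         [0.5, -0.4, 0.0]])    # crossover QTL
        Z = hybrids.values - 2.0 * pfreq
        emap = {e: i for i, e in enumerate(theta.index)}
        hmap = {h: i for i, h in enumerate(hybrids.samples)}
        add = np.zeros(len(pheno))
        for t, s in enumerate(qtl):
            prof = T @ coef[t]
            add += (Z[pheno["hybrid_id"].map(hmap), s]
                    * prof[pheno["env_id"].map(emap)])
        pheno = pheno.assign(yield_Mg_ha=pheno["yield_Mg_ha"] + add)

        grm = grm_vanraden1(hybrids, blend=0.0, freq=pfreq)
        fit = fit_rnm(pheno, theta, grm, ModelSpec(order=2,
                                                   residual="homogeneous"))
        u = backsolve_snp_effects(Z, fit.a_hat,
                                  snp_ids=hybrids.snps["snp_id"])
        eff = snp_env_effects(u, T=fit.T, env_ids=fit.env_ids)
        from reactnorm import ld_r2_window
        ld_table, _ = ld_r2_window(hybrids, window_snps=50)
        sel = select_top_snps(eff, k=5, ld_table=ld_table,
                              snp_meta=hybrids.snps)
        names = [hybrids.snps["snp_id"].iloc[s] for s in qtl]
        assert set(names) <= set(sel["union"])
        for t, name in enumerate(names):
            true_prof = pd.Series(T @ coef[t], index=theta.index)
            est_prof = eff.loc[name].reindex(theta.index)
            rho = spearmanr(true_prof, est_prof).statistic
            assert rho > 0.7


class TestAlleleState:
    def _setup(self, counts=(12, 12, 12), seed=5, shift=(0.0, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        n = sum(counts)
        hybrids = [f"H{i}" for i in range(n)]
        calls = np.concatenate([np.full(c, v) for c, v in
                                zip(counts, (0.0, 1.0, 2.0))])
        snps = pd.DataFrame({"snp_id": ["s0"], "chrom": ["1"], "pos": [100]})
        geno = GenotypeMatrix(hybrids, snps, calls[:, None])
        y = rng.normal(8.0, 0.5, size=n)
        y += np.concatenate([np.full(c, s) for c, s in zip(counts, shift)])
        pheno = pd.DataFrame({"env_id": "E1", "hybrid_id": hybrids,
                              "yield_Mg_ha": y})
        return geno, pheno

    def test_identical_values_f_zero_one_group(self):
        geno, pheno = self._setup()
        pheno["yield_Mg_ha"] = 8.0
        res = allele_state_test(pheno, geno, ["s0"], {"E1": 0.5})
        r = res[0]
        assert r.included and r.F == 0.0 and r.p == 1.0
        assert set(r.groups.values()) == {"a"}

    def test_textbook_anova_matches_hand_computation(self):
        # 3 groups x 5 values with hand-computable sums of squares
        geno, pheno = self._setup(counts=(5, 5, 5))
        vals = np.array([1, 2, 3, 4, 5,
                         2, 3, 4, 5, 6,
                         4, 5, 6, 7, 8], dtype=float)
        pheno["yield_Mg_ha"] = vals
        res = allele_state_test(pheno, geno, ["s0"], {"E1": 0.5},
                                min_class=5)
        grand = vals.mean()
        means = [vals[:5].mean(), vals[5:10].mean(), vals[10:].mean()]
        ssb = 5 * sum((m - grand) ** 2 for m in means)
        ssw = sum(((vals[i * 5:(i + 1) * 5] - means[i]) ** 2).sum()
                  for i in range(3))
        F_hand = (ssb / 2) / (ssw / 12)
        assert res[0].F == pytest.approx(F_hand, abs=1e-10)

    def test_small_class_excluded(self):
        geno, pheno = self._setup(counts=(9, 40, 40))
        res = allele_state_test(pheno, geno, ["s0"], {"E1": 0.5})
        assert not res[0].included
        assert res[0].reason == "class below minimum"

    def test_nonpositive_gradient_environment_excluded(self):
        geno, pheno = self._setup()
        res = allele_state_test(pheno, geno, ["s0"], {"E1": -0.2})
        assert not res[0].included
        assert "gradient" in res[0].reason

    def test_favorable_minor_allele_detected(self):
        geno, pheno = self._setup(counts=(15, 15, 15),
                                  shift=(1.5, 0.7, 0.0), seed=6)
        res = allele_state_test(pheno, geno, ["s0"], {"E1": 0.5})
        r = res[0]
        assert r.included and r.p < 0.05
        assert r.minor_beats_major
        assert r.groups[0] != r.groups[2]


class TestAnnotationQuery:
    def test_closed_window(self):
        snps = pd.DataFrame({"snp_id": ["s"], "chrom": ["2"],
                             "pos": [5000]})
        ann = pd.DataFrame({
            "chrom": ["2", "2", "1"],
            "start": [3000, 6000, 4500], "end": [4000, 7000, 5500],
            "name": ["geneA", "geneB", "wrongChrom"]})
        hits = annotation_window_query(snps, ann, window_bp=1000)
        assert set(hits["gene"]) == {"geneA", "geneB"}
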