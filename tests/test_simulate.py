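"""Generative model: parents, hybrids, trials, covariates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reactnorm import (GenotypeMatrix, SimulationConfig, hybrids_from_crosses,
                       legendre_basis, make_hybrids, simulate_env_covariates,
                       simulate_parents, simulate_trial)


class TestParents:
    def test_domain_and_shape(self):
        par, freq = simulate_parents(50, 1000, seed=1)
        assert par.values.shape == (50, 1000)
        assert np.isin(par.values, (0.0, 1.0, 2.0)).all()
        assert np.isin(par.values, (0.0, 2.0)).all()   # clean panel: no hets

    def test_deterministic_under_seed(self):
        a, _ = simulate_parents(20, 100, seed=1)
        b, _ = simulate_parents(20, 100, seed=1)
        np.testing.assert_array_equal(a.values, b.values)
        assert list(a.snps["pos"]) == list(b.snps["pos"])

    def test_injected_heterozygote_fraction(self):
        par, _ = simulate_parents(100, 2000, seed=2, het_error_rate=0.01)
        frac = float(np.mean(par.values == 1.0))
        n = par.values.size
        tol = 4 * np.sqrt(0.01 * 0.99 / n)
        assert abs(frac - 0.01) < tol

    def test_maf_spectrum_mass_near_bound(self):
        par, freq = simulate_parents(300, 2000, seed=3)
        maf = np.minimum(freq, 1 - freq)
        assert (maf < 0.05).mean() > 0.10      # spike near the 1% bound
        assert maf.max() <= 0.5 + 1e-9

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            simulate_parents(2, 100, seed=1)
        with pytest.raises(ValueError):
            simulate_parents(10, 5, seed=1)

    def test_positions_nondecreasing_within_chrom(self):
        par, _ = simulate_parents(10, 200, seed=4)
        for _, sub in par.snps.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing


class TestHybrids:
    def test_mendelian_sum(self):
        snps = pd.DataFrame({"snp_id": ["a", "b", "c"], "chrom": "1",
                             "pos": [1, 2, 3]})
        parents = GenotypeMatrix(["P1", "P2"], snps,
                                 np.array([[0.0, 2.0, 0.0],
                                           [0.0, 2.0, 2.0]]))
        cross = pd.DataFrame({"hybrid_id": ["H"], "parent1": ["P1"],
                              "parent2": ["P2"]})
        hyb = hybrids_from_crosses(parents, cross)
        np.testing.assert_array_equal(hyb.values, [[0.0, 2.0, 1.0]])

    def test_cross_space_exhausted(self):
        par, _ = simulate_parents(5, 20, seed=5)
        with pytest.raises(ValueError, match="cross space"):
            make_hybrids(par, 5 * 5 - 5, seed=1)

    def test_unique_parent_pairs(self):
        par, _ = simulate_parents(50, 50, seed=6)
        cross, hyb = make_hybrids(par, 200, seed=1)
        pairs = {tuple(sorted(p)) for p in
                 zip(cross["parent1"], cross["parent2"])}
        assert len(pairs) == 200
        assert (cross["parent1"] != cross["parent2"]).all()

    def test_rejects_heterozygous_parents(self):
        snps = pd.DataFrame({"snp_id": ["a"], "chrom": "1", "pos": [1]})
        parents = GenotypeMatrix(["P1", "P2"], snps,
                                 np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="homozygous"):
            make_hybrids(parents, 1, seed=1)


class TestTrial:
    def test_conservation_of_plot_count(self, small_trial):
        pheno = small_trial["pheno"]
        cfg = small_trial["cfg"]
        cells = pheno.groupby(["env_id", "hybrid_id"]).size()
        assert (cells == cfg.reps_per_plot).all()
        assert len(pheno) == len(cells) * cfg.reps_per_plot

    def test_truth_gebv_is_basis_expansion(self, small_trial):
        truth = small_trial["truth"]
        T = legendre_basis(truth.true_theta.to_numpy(), 2)
        expect = truth.true_coeffs_a.to_numpy() @ T.T
        np.testing.assert_array_equal(truth.true_gebv.to_numpy(), expect)

    def test_every_env_and_hybrid_covered(self, small_trial):
        pheno = small_trial["pheno"]
        cfg = small_trial["cfg"]
        assert pheno.groupby("env_id")["hybrid_id"].nunique().min() >= 2
        assert pheno["hybrid_id"].nunique() == cfg.n_hybrids

    def test_homogeneous_limit_levene(self):
        """With d1 = 0 the per-environment residual variances are
        statistically indistinguishable."""
        par, _ = simulate_parents(30, 200, seed=31)
        _, hyb = make_hybrids(par, 80, seed=32)
        cfg = SimulationConfig(n_parents=30, n_snps=200, n_hybrids=80,
                               n_envs=8, n_years=2, incidence_density=0.8,
                               d1=0.0, seed=33)
        pheno, truth = simulate_trial(hyb, cfg)
        T = legendre_basis(truth.true_theta.to_numpy(), 2)
        tmap = {e: i for i, e in enumerate(truth.true_theta.index)}
        hmap = {h: i for i, h in enumerate(truth.true_coeffs_a.index)}
        coefs = (truth.true_coeffs_a.to_numpy()
                 + truth.true_coeffs_be.to_numpy())
        ei = pheno["env_id"].map(tmap).to_numpy()
        hi = pheno["hybrid_id"].map(hmap).to_numpy()
        resid = (pheno["yield_Mg_ha"].to_numpy()
                 - truth.true_merit.to_numpy()[ei]
                 - np.sum(T[ei] * coefs[hi], axis=1))
        groups = [resid[ei == e] for e in range(cfg.n_envs)]
        _, p = stats.levene(*groups)
        assert p > 0.01

    def test_rank_one_coefficient_covariance_means_no_gei(self):
        par, _ = simulate_parents(20, 100, seed=41)
        _, hyb = make_hybrids(par, 40, seed=42)
        cfg = SimulationConfig(n_parents=20, n_snps=100, n_hybrids=40,
                               n_envs=8, n_years=2,
                               C_a=0.3 * np.ones((3, 3)),
                               C_be=np.zeros((3, 3)),
                               incidence_density=1.0, seed=43)
        _, truth = simulate_trial(hyb, cfg)
        G = truth.true_gebv.to_numpy()
        # trajectories are pairwise proportional: rank order is identical
        # (up to global sign) in every environment
        rho = pd.DataFrame(G).corr(method="spearman").to_numpy()
        assert np.all(np.abs(rho) > 1 - 1e-12)

    def test_mean_yield_monotone_in_theta(self):
        par, _ = simulate_parents(60, 400, seed=51)
        _, hyb = make_hybrids(par, 300, seed=52)
        cfg = SimulationConfig(n_parents=60, n_snps=400, n_hybrids=300,
                               n_envs=24, n_years=4, incidence_density=0.5,
                               seed=53)
        pheno, truth = simulate_trial(hyb, cfg)
        env_means = pheno.groupby("env_id")["yield_Mg_ha"].mean()
        df = pd.DataFrame({"theta": truth.true_theta,
                           "mean": env_means}).sort_values("theta")
        bins = np.array_split(df["mean"].to_numpy(), 6)
        bin_means = [b.mean() for b in bins]
        assert all(np.diff(bin_means) > 0)

    def test_outlier_injection_flagged(self):
        par, _ = simulate_parents(20, 100, seed=61)
        _, hyb = make_hybrids(par, 50, seed=62)
        cfg = SimulationConfig(n_parents=20, n_snps=100, n_hybrids=50,
                               n_envs=6, n_years=2, incidence_density=0.8,
                               outlier_frac=0.02, seed=63)
        pheno, truth = simulate_trial(hyb, cfg)
        n_out = int(truth.outlier_flags.sum())
        assert n_out == round(0.02 * len(pheno))

    def test_variance_decomposition_homogeneous_no_be(self):
        """With d1=0, C_be=0 and identity coefficient draws the phenotypic
        variance per environment is T_i C_a T_i' + exp(d0)."""
        par, _ = simulate_parents(40, 200, seed=71)
        _, hyb = make_hybrids(par, 400, seed=72)
        cfg = SimulationConfig(n_parents=40, n_snps=200, n_hybrids=400,
                               n_envs=6, n_years=1, incidence_density=1.0,
                               reps_per_plot=1, d1=0.0,
                               C_be=np.zeros((3, 3)),
                               identity_coeff_draws=True, seed=73)
        pheno, truth = simulate_trial(hyb, cfg)
        T = legendre_basis(truth.true_theta.to_numpy(), 2)
        expect = np.sum((T @ cfg.C_a) * T, axis=1) + np.exp(cfg.d0)
        obs = (pheno.groupby("env_id")["yield_Mg_ha"].var()
               .reindex(truth.true_theta.index).to_numpy())
        assert np.all(np.abs(obs - expect) / expect < 0.25)

    def test_sparse_incidence_rejected(self):
        par, _ = simulate_parents(10, 50, seed=81)
        _, hyb = make_hybrids(par, 4, seed=82)
        cfg = SimulationConfig(n_parents=10, n_snps=50, n_hybrids=4,
                               n_envs=12, n_years=4,
                               incidence_density=0.01, seed=83)
        with pytest.raises(ValueError, match="sparse"):
            simulate_trial(hyb, cfg)


class TestCovariates:
    def test_deterministic(self):
        merit = pd.Series([5.0, 8.0, 11.0], index=["a", "b", "c"])
        w1, s1 = simulate_env_covariates(merit, 1.0, seed=9)
        w2, s2 = simulate_env_covariates(merit, 1.0, seed=9)
        pd.testing.assert_frame_equal(w1, w2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_noiseless_summaries_rank_correlate_with_merit(self):
        from reactnorm.merit import build_features

        merit = pd.Series(np.linspace(4, 13, 12),
                          index=[f"E{i}" for i in range(12)])
        weather, soil = simulate_env_covariates(merit, 0.0, seed=10)
        feats = build_features(weather, soil).table.loc[merit.index]
        for col in ("T2M_07", "ALLSKY_SFC_PAR_TOT_07", "SOC_0-5"):
            rho = stats.spearmanr(feats[col], merit).statistic
            assert rho == pytest.approx(1.0)

    def test_daily_coverage(self):
        merit = pd.Series([5.0, 9.0], index=["a", "b"])
        weather, soil = simulate_env_covariates(merit, 1.0, seed=11)
        assert len(weather) == 2 * 214          # April-October daily rows
        assert set(soil["depth_cm"]) == {"0-5", "5-15", "15-30"}
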