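"""Shared fixtures: small simulated trials reused across test modules."""

import math

import numpy as np
import pandas as pd
import pytest

from reactnorm import (ModelSpec, SimulationConfig, fit_baseline_blup,
                       legendre_basis,
                       fit_rnm, grm_vanraden1, make_hybrids, qc_phenotypes,
                       scale_gradient, simulate_parents, simulate_trial)


@pytest.fixture(scope="session")
def small_trial():
    """A compact trial: 60 hybrids x 10 environments, known truth."""
    parents, _ = simulate_parents(30, 300, seed=11)
    cross, hybrids = make_hybrids(parents, 60, seed=12)
    cfg = SimulationConfig(n_parents=30, n_snps=300, n_hybrids=60,
                           n_envs=10, n_years=2, incidence_density=0.6,
                           seed=13)
    pheno, truth = simulate_trial(hybrids, cfg)
    return {"parents": parents, "cross": cross, "hybrids": hybrids,
            "pheno": pheno, "truth": truth, "cfg": cfg}


@pytest.fixture(scope="session")
def small_gradient(small_trial):
    pheno_qc, _ = qc_phenotypes(small_trial["pheno"])
    fit1 = fit_baseline_blup(pheno_qc)
    return pheno_qc, scale_gradient(fit1.beta)


@pytest.fixture(scope="session")
def small_fit(small_trial, small_gradient):
    """Order-2 heterogeneous fit of the small trial."""
    pheno_qc, grad = small_gradient
    grm = grm_vanraden1(small_trial["hybrids"], blend=0.01)
    fit = fit_rnm(pheno_qc, grad, grm, ModelSpec())
    return {"fit": fit, "grm": grm, "pheno_qc": pheno_qc, "grad": grad}


def disjoint_cross_hybrids(n_hybrids, n_snps, seed):
    """Hybrids from disjoint parent pairs with base-panel frequencies.

    A full-rank unblended GRM needs (a) disjoint pairs - crosses sharing
    parents are exactly linearly dependent ((p_i+p_j)+(p_k+p_l) =
    (p_i+p_l)+(p_k+p_j)) - and (b) centring frequencies from a panel larger
    than the crossed parents, because centring by the used parents alone
    zeroes the sum of all hybrid rows.  Returns (parents, cross, hybrids,
    base_freq).
    """
    import pandas as pd

    from reactnorm import hybrids_from_crosses

    parents, _ = simulate_parents(2 * n_hybrids + 20, n_snps, seed=seed)
    base_freq = parents.compute_freq()
    cross = pd.DataFrame({
        "hybrid_id": [f"H{k:04d}" for k in range(n_hybrids)],
        "parent1": [parents.samples[2 * k] for k in range(n_hybrids)],
        "parent2": [parents.samples[2 * k + 1] for k in range(n_hybrids)],
    })
    return parents, cross, hybrids_from_crosses(parents, cross), base_freq


@pytest.fixture(scope="session")
def exact_fit():
    """Fit with an unblended, full-rank GRM, so the SNP-effect backsolve
    identity Z u = a holds exactly.

    Centring must use base-population (parent) frequencies: centring by the
    hybrid panel's own frequencies zeroes every column sum, which puts the
    all-ones vector in the GRM null space.
    """
    parents, cross, hybrids, pfreq = disjoint_cross_hybrids(40, 400, seed=31)
    cfg = SimulationConfig(n_parents=100, n_snps=400, n_hybrids=40,
                           n_envs=8, n_years=2, incidence_density=0.8,
                           seed=33)
    pheno, truth = simulate_trial(hybrids, cfg)
    grm = grm_vanraden1(hybrids, blend=0.0, freq=pfreq)
    fit = fit_rnm(pheno, truth.true_theta, grm, ModelSpec())
    return {"fit": fit, "grm": grm, "hybrids": hybrids, "pheno": pheno,
            "truth": truth, "freq": pfreq}


@pytest.fixture(scope="session")
def medium_trial():
    """150 hybrids x 16 environments over 4 years, with covariates."""
    from reactnorm import simulate_env_covariates

    parents, _ = simulate_parents(50, 600, seed=21)
    cross, hybrids = make_hybrids(parents, 150, seed=22)
    cfg = SimulationConfig(n_parents=50, n_snps=600, n_hybrids=150,
                           n_envs=16, n_years=4, incidence_density=0.35,
                           seed=23)
    pheno, truth = simulate_trial(hybrids, cfg)
    weather, soil = simulate_env_covariates(truth.true_merit,
                                            cfg.covariate_noise, seed=24)
    return {"hybrids": hybrids, "pheno": pheno, "truth": truth,
            "weather": weather, "soil": soil, "cfg": cfg}


def dense_reml_logl(ph, tmap, grm, order, include_be, Ca, Cbe, d0, d1):
    """Independent dense-V REML evaluation (never touches the MME path)."""
    envs = sorted(ph["env_id"].unique())
    theta = np.array([tmap[e] for e in envs])
    T = legendre_basis(theta, order)
    hybs = list(grm.samples)
    ei = ph["env_id"].map({e: i for i, e in enumerate(envs)}).to_numpy()
    hi = ph["hybrid_id"].map({h: i for i, h in enumerate(hybs)}).to_numpy()
    y = ph["yield_Mg_ha"].to_numpy()
    n, E, q, na = len(y), len(envs), len(hybs), order + 1
    X = np.zeros((n, E))
    X[np.arange(n), ei] = 1.0
    Z = np.zeros((n, q * na))
    for i in range(n):
        Z[i, hi[i] * na:hi[i] * na + na] = T[ei[i]]
    V = Z @ np.kron(grm.matrix, Ca) @ Z.T
    if include_be:
        V = V + Z @ np.kron(np.eye(q), Cbe) @ Z.T
    V = V + np.diag(np.exp(d0 + d1 * theta[ei]))
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    b = np.linalg.solve(XVX, X.T @ Vi @ y)
    r = y - X @ b
    _, l1 = np.linalg.slogdet(V)
    _, l2 = np.linalg.slogdet(XVX)
    return -0.5 * ((n - E) * math.log(2 * math.pi) + l1 + l2 + r @ Vi @ y)
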