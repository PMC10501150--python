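"""Per-environment genetic parameters derived from a reaction-norm fit.

From the fitted coefficient covariance C_a and the basis matrix T the
environment-level additive covariance is Sigma = T C_a T'; its diagonal
gives per-environment additive variances, which combine with the residual
model into narrow-sense heritabilities, and its standardization gives the
genetic correlation of yield between environments.  GEBV trajectories are
the basis expansion of the predicted additive coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rnm import RNMFit, ResidualModel, legendre_basis

__all__ = [
    "GeneticParams",
    "genetic_covariance",
    "heritability",
    "genetic_correlation",
    "gebv_trajectories",
    "genetic_params",
    "plot_trajectories",
]


@dataclass
class GeneticParams:
    env_ids: list
    theta: np.ndarray
    Sigma: np.ndarray          # envs x envs additive covariance
    h2: np.ndarray             # per-environment narrow-sense heritability
    R: np.ndarray              # envs x envs genetic correlation
    residual_var: np.ndarray   # per-environment residual variance used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "env_id": self.env_ids, "theta": self.theta,
            "additive_var": np.diag(self.Sigma), "h2": self.h2,
            "residual_var": self.residual_var,
        })


def genetic_covariance(T: np.ndarray, C_a: np.ndarray,
                       tol: float = 1e-8) -> np.ndarray:
    """Environment-level additive covariance Sigma = T C_a T'."""
    T = np.asarray(T, float)
    C_a = np.asarray(C_a, float)
    if T.shape[1] != C_a.shape[0] or C_a.shape[0] != C_a.shape[1]:
        raise ValueError(
            f"shapes not conformable: T {T.shape}, C_a {C_a.shape}")
    if np.linalg.eigvalsh(0.5 * (C_a + C_a.T))[0] < -tol:
        raise ValueError("C_a is not positive semi-definite")
    S = T @ C_a @ T.T
    return 0.5 * (S + S.T)


def heritability(Sigma: np.ndarray, residual: ResidualModel | np.ndarray,
                 theta=None) -> np.ndarray:
    """Narrow-sense h2 per environment: sigma_a^2 / (sigma_a^2 + sigma_e^2).

    ``residual`` is either a fitted residual model (evaluated at ``theta``)
    or an explicit vector of per-environment residual variances.
    """
    va = np.diag(np.asarray(Sigma, float))
    if isinstance(residual, ResidualModel):
        if theta is None:
            raise ValueError("theta required with a residual model")
        ve = residual.variance(theta)
    else:
        ve = np.asarray(residual, float)
    tot = va + ve
    if np.any(tot <= 0):
        raise ValueError("zero total variance in some environment")
    return va / tot


def genetic_correlation(Sigma: np.ndarray) -> np.ndarray:
    """Correlation matrix from the environment-level additive covariance."""
    va = np.diag(Sigma)
    if np.any(va <= 0):
        raise ValueError("non-positive additive variance on the diagonal")
    d = 1.0 / np.sqrt(va)
    R = Sigma * np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def gebv_trajectories(a_hat: pd.DataFrame, T: np.ndarray | None = None,
                      theta=None, env_ids=None) -> pd.DataFrame:
    """GEBV per hybrid and environment: the basis expansion T a_j.

    Either a basis matrix ``T`` or a theta grid (from which the basis is
    built at the order implied by ``a_hat``) must be supplied.  Works for
    unphenotyped hybrids too, whose coefficients come from the relationship
    matrix during fitting.
    """
    A = a_hat.to_numpy(dtype=float)
    order = A.shape[1] - 1
    if T is None:
        if theta is None:
            raise ValueError("supply T or theta")
        T = legendre_basis(theta, order)
    T = np.asarray(T, float)
    if T.shape[1] != A.shape[1]:
        raise ValueError(
            f"basis order mismatch: T has {T.shape[1]} columns, "
            f"a_hat has {A.shape[1]} coefficients")
    cols = (list(env_ids) if env_ids is not None
            else [f"theta={t:.3f}" for t in
                  (theta if theta is not None else range(T.shape[0]))])
    return pd.DataFrame(A @ T.T, index=a_hat.index, columns=cols)


def genetic_params(fit: RNMFit) -> GeneticParams:
    """All per-environment genetic parameters of a converged fit."""
    Sigma = genetic_covariance(fit.T, fit.C_a)
    ve = fit.residual_variances()
    h2 = heritability(Sigma, ve)
    R = genetic_correlation(Sigma)
    return GeneticParams(env_ids=list(fit.env_ids), theta=fit.theta,
                         Sigma=Sigma, h2=h2, R=R, residual_var=ve)


def plot_trajectories(fit: RNMFit, hybrids=None, n_grid: int = 101, ax=None):
    """Plot GEBV trajectories over a theta grid (requires matplotlib)."""
    import matplotlib.pyplot as plt

    grid = np.linspace(-1.0, 1.0, n_grid)
    A = fit.a_hat if hybrids is None else fit.a_hat.loc[hybrids]
    traj = gebv_trajectories(A, theta=grid)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for _, row in traj.iterrows():
        ax.plot(grid, row.to_numpy(), lw=0.7, alpha=0.6)
    ax.set_xlabel("environmental gradient (theta)")
    ax.set_ylabel("GEBV (Mg/ha)")
    return ax
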