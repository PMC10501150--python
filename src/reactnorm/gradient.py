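"""Environmental gradient: phenotype screening, baseline BLUP, scaling.

The merit of an environment is its fixed effect in the baseline model

    y = X beta + Z g + e,   g ~ N(0, I sg2),  e ~ N(0, I se2)

fitted on replicate-level records with an identity covariance for the hybrid
effect (the goal is an unbiased beta, not breeding values).  The fitted
environment effects are min-max scaled to theta in [-1, 1], which is the
covariate of the reaction-norm stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = [
    "PhenotypeQCReport",
    "Eq1Fit",
    "EnvironmentGradient",
    "qc_phenotypes",
    "fit_baseline_blup",
    "baseline_loglik",
    "scale_gradient",
    "identity_blup",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# phenotype QC
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeQCReport:
    n_records_in: int
    n_outliers_removed: int = 0
    repeatability: dict = field(default_factory=dict)
    envs_dropped_repeatability: list = field(default_factory=list)
    envs_dropped_too_small: list = field(default_factory=list)
    envs_without_replication: list = field(default_factory=list)
    n_records_out: int = 0


def qc_phenotypes(table: pd.DataFrame, y_col: str = "yield_Mg_ha",
                  sd_limit: float = 3.0, repeatability_min: float = 0.1
                  ) -> tuple[pd.DataFrame, PhenotypeQCReport]:
    """Screen replicate-level yield records.

    Per environment, records farther than ``sd_limit`` standard deviations
    from the environment mean are removed in a single pass (mean and SD from
    the unfiltered environment).  Environments with plot-basis repeatability
    below ``repeatability_min`` are then dropped, as are environments left
    with fewer than two hybrids.  Repeatability is sigma_h^2 / (sigma_h^2 +
    sigma_res^2) from a one-way method-of-moments decomposition over hybrids;
    environments without any replication are retained (the screen needs
    within-hybrid replicates) and listed in the report.
    """
    rep = PhenotypeQCReport(n_records_in=len(table))
    df = table.copy()

    grp = df.groupby("env_id")[y_col]
    mu = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    keep = (df[y_col] - mu).abs() <= sd_limit * sd
    keep |= sd == 0.0
    rep.n_outliers_removed = int((~keep).sum())
    df = df.loc[keep]

    keep_envs = []
    for env, sub in df.groupby("env_id"):
        counts = sub.groupby("hybrid_id")[y_col].count()
        if len(counts) < 2:
            rep.envs_dropped_too_small.append(env)
            warnings.warn(f"environment {env!r} has <2 hybrids after "
                          "filtering; dropped")
            continue
        if (counts <= 1).all():
            rep.envs_without_replication.append(env)
            keep_envs.append(env)
            continue
        r = _repeatability_oneway(sub, y_col)
        rep.repeatability[env] = r
        if r < repeatability_min:
            rep.envs_dropped_repeatability.append(env)
        else:
            keep_envs.append(env)

    out = df[df["env_id"].isin(keep_envs)].reset_index(drop=True)
    rep.n_records_out = len(out)
    return out, rep


def _repeatability_oneway(sub: pd.DataFrame, y_col: str) -> float:
    """Plot-basis repeatability from a one-way hybrid decomposition."""
    y = sub[y_col].to_numpy(dtype=float)
    codes, _ = pd.factorize(sub["hybrid_id"])
    a = codes.max() + 1
    N = len(y)
    n_i = np.bincount(codes).astype(float)
    means = np.bincount(codes, weights=y) / n_i
    ss_within = float(np.sum((y - means[codes]) ** 2))
    ss_between = float(np.sum(n_i * (means - y.mean()) ** 2))
    df_w = N - a
    if df_w <= 0:
        return math.nan
    msw = ss_within / df_w
    msb = ss_between / (a - 1)
    k = (N - float(np.sum(n_i ** 2)) / N) / (a - 1)
    sigma_h2 = max((msb - msw) / k, 0.0)
    tot = sigma_h2 + msw
    return sigma_h2 / tot if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# baseline BLUP model (environment fixed effect + identity hybrid effect)
# ---------------------------------------------------------------------------

@dataclass
class Eq1Fit:
    """REML fit of the baseline environment-merit model."""

    beta: pd.Series           # per-environment fixed effect, Mg/ha
    g: pd.Series              # per-hybrid BLUP (identity covariance)
    sigma_g2: float
    sigma_e2: float
    logL: float
    converged: bool
    n_evals: int
    trace: list = field(repr=False, default_factory=list)


def _design_codes(table: pd.DataFrame, y_col: str):
    envs = sorted(table["env_id"].unique())
    hybs = sorted(table["hybrid_id"].unique())
    e = table["env_id"].map({v: i for i, v in enumerate(envs)}).to_numpy()
    h = table["hybrid_id"].map({v: i for i, v in enumerate(hybs)}).to_numpy()
    y = table[y_col].to_numpy(dtype=float)
    return envs, hybs, e, h, y


def _m2logl_parts(e, h, y, E, q, sg2, se2):
    """-2 REML logL and MME solutions for the baseline model."""
    n = len(y)
    w = 1.0 / se2
    m = E + q
    C = np.zeros((m, m))
    C[np.arange(E), np.arange(E)] = np.bincount(e, minlength=E) * w
    XtZ = np.zeros((E, q))
    np.add.at(XtZ, (e, h), w)
    C[:E, E:] = XtZ
    C[E:, :E] = XtZ.T
    C[E + np.arange(q), E + np.arange(q)] = (
        np.bincount(h, minlength=q) * w + 1.0 / sg2)
    rhs = np.concatenate([
        np.bincount(e, weights=y, minlength=E) * w,
        np.bincount(h, weights=y, minlength=q) * w,
    ])
    cf = cho_factor(C, lower=True)
    sol = cho_solve(cf, rhs)
    yPy = float(y @ y) * w - float(rhs @ sol)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    m2l = ((n - E) * _LOG2PI + n * math.log(se2) + q * math.log(sg2)
           + logdet_C + yPy)
    return m2l, sol


def baseline_loglik(table: pd.DataFrame, sigma_g2: float, sigma_e2: float,
                    y_col: str = "yield_Mg_ha") -> float:
    """REML log-likelihood of the baseline model at given components."""
    envs, hybs, e, h, y = _design_codes(table, y_col)
    m2l, _ = _m2logl_parts(e, h, y, len(envs), len(hybs), sigma_g2, sigma_e2)
    return -0.5 * m2l


def fit_baseline_blup(table: pd.DataFrame, y_col: str = "yield_Mg_ha",
                      max_evals: int = 500) -> Eq1Fit:
    """REML fit of the environment-merit model.

    The environment fixed effect uses a one-effect-per-environment coding
    with no global intercept, so beta is directly the environment merit.
    Components are found by Nelder-Mead on the log-variance scale; beta and
    the hybrid BLUPs are the generalized-least-squares / BLUP solutions at
    the optimum.
    """
    envs, hybs, e, h, y = _design_codes(table, y_col)
    E, q = len(envs), len(hybs)
    if E < 2:
        raise ValueError("need at least two environments")
    vtot = max(float(np.var(y - np.bincount(e, weights=y, minlength=E)[e]
                     / np.bincount(e, minlength=E)[e])), 1e-6)
    trace = []

    def obj(x):
        sg2, se2 = math.exp(x[0]), math.exp(x[1])
        try:
            m2l, _ = _m2logl_parts(e, h, y, E, q, sg2, se2)
        except np.linalg.LinAlgError:
            return 1e12
        trace.append({"sigma_g2": sg2, "sigma_e2": se2, "m2logl": m2l})
        return m2l

    x0 = np.log([0.5 * vtot, 0.5 * vtot])
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10,
                            "maxfev": max_evals})
    if not res.success:
        err = RuntimeError(
            f"baseline REML did not converge: {res.message}")
        err.trace = trace
        raise err
    sg2, se2 = float(math.exp(res.x[0])), float(math.exp(res.x[1]))
    m2l, sol = _m2logl_parts(e, h, y, E, q, sg2, se2)
    return Eq1Fit(
        beta=pd.Series(sol[:E], index=envs, name="beta"),
        g=pd.Series(sol[E:], index=hybs, name="g"),
        sigma_g2=sg2, sigma_e2=se2, logL=-0.5 * m2l,
        converged=True, n_evals=int(res.nfev), trace=trace,
    )


# ---------------------------------------------------------------------------
# min-max scaling to the environmental gradient
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentGradient:
    """Per-environment merit beta and its min-max scaled value theta."""

    table: pd.DataFrame            # env_id, beta, theta
    beta_min: float
    beta_max: float

    def theta_map(self) -> dict:
        return dict(zip(self.table["env_id"], self.table["theta"]))

    def beta_map(self) -> dict:
        return dict(zip(self.table["env_id"], self.table["beta"]))

    def scale(self, beta, clip: bool = False) -> np.ndarray:
        """Scale out-of-sample merits with the stored (beta_min, beta_max)."""
        theta = -1.0 + 2.0 * (np.asarray(beta, float) - self.beta_min) / (
            self.beta_max - self.beta_min)
        return np.clip(theta, -1.0, 1.0) if clip else theta

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EnvironmentGradient":
        t = pd.read_csv(path)
        return cls(t, float(t["beta"].min()), float(t["beta"].max()))


def scale_gradient(beta) -> EnvironmentGradient:
    """Min-max scale environment effects to theta in [-1, 1].

    theta_i = -1 + 2 (beta_i - beta_min) / (beta_max - beta_min); the
    extreme environments land exactly on -1 and +1.
    """
    if isinstance(beta, dict):
        beta = pd.Series(beta)
    elif not isinstance(beta, pd.Series):
        beta = pd.Series(np.asarray(beta, dtype=float),
                         index=[f"env{i}" for i in range(len(beta))])
    if len(beta) < 2:
        raise ValueError("need at least two environments to scale")
    bmin, bmax = float(beta.min()), float(beta.max())
    if bmax == bmin:
        raise ValueError("all environment effects equal: zero range")
    theta = -1.0 + 2.0 * (beta - bmin) / (bmax - bmin)
    table = pd.DataFrame({"env_id": beta.index, "beta": beta.to_numpy(),
                          "theta": theta.to_numpy()})
    return EnvironmentGradient(table, bmin, bmax)


# ---------------------------------------------------------------------------
# within-environment identity BLUP (reference values for cross-validation)
# ---------------------------------------------------------------------------

def identity_blup(table: pd.DataFrame, y_col: str = "yield_Mg_ha",
                  max_evals: int = 400) -> tuple[pd.Series, dict]:
    """Single-environment hybrid BLUPs: y = mu + g + e, identity covariance.

    Returns per-hybrid BLUPs and an info dict.  When no hybrid has
    replication the genetic and residual variances are confounded; the
    function falls back to centred hybrid means and flags it.
    """
    hybs = sorted(table["hybrid_id"].unique())
    if len(hybs) < 2:
        raise ValueError("need at least two hybrids")
    h = table["hybrid_id"].map({v: i for i, v in enumerate(hybs)}).to_numpy()
    y = table[y_col].to_numpy(dtype=float)
    q = len(hybs)
    counts = np.bincount(h, minlength=q).astype(float)
    means = np.bincount(h, weights=y, minlength=q) / counts

    if counts.max() <= 1.0:
        blup = pd.Series(means - means.mean(), index=hybs, name="blup")
        return blup, {"fallback_centered_means": True}

    n = len(y)
    vtot = max(float(y.var()), 1e-8)

    def obj(x):
        sg2, se2 = math.exp(x[0]), math.exp(x[1])
        w = 1.0 / se2
        # absorb mu analytically via the 1-fixed-effect MME
        m = 1 + q
        C = np.zeros((m, m))
        C[0, 0] = n * w
        C[0, 1:] = counts * w
        C[1:, 0] = counts * w
        C[np.arange(1, m), np.arange(1, m)] = counts * w + 1.0 / sg2
        rhs = np.concatenate([[y.sum() * w],
                              np.bincount(h, weights=y, minlength=q) * w])
        try:
            cf = cho_factor(C, lower=True)
        except np.linalg.LinAlgError:
            return 1e12
        sol = cho_solve(cf, rhs)
        yPy = float(y @ y) * w - float(rhs @ sol)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return ((n - 1) * _LOG2PI + n * math.log(se2) + q * math.log(sg2)
                + logdet + yPy)

    res = minimize(obj, np.log([0.5 * vtot, 0.5 * vtot]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-9,
                            "maxfev": max_evals})
    sg2, se2 = math.exp(res.x[0]), math.exp(res.x[1])
    w = 1.0 / se2
    m = 1 + q
    C = np.zeros((m, m))
    C[0, 0] = n * w
    C[0, 1:] = counts * w
    C[1:, 0] = counts * w
    C[np.arange(1, m), np.arange(1, m)] = counts * w + 1.0 / sg2
    rhs = np.concatenate([[y.sum() * w],
                          np.bincount(h, weights=y, minlength=q) * w])
    sol = cho_solve(cho_factor(C, lower=True), rhs)
    blup = pd.Series(sol[1:], index=hybs, name="blup")
    return blup, {"fallback_centered_means": False,
                  "sigma_g2": float(sg2), "sigma_e2": float(se2),
                  "mu": float(sol[0])}
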