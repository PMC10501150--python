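"""Synthetic multi-environment hybrid trials with known truth.

The generator mirrors the structure the reaction-norm analysis assumes: fully
homozygous inbred parents with a low-MAF-heavy allele-frequency spectrum and
distance-decaying LD, hybrids formed as crosses of two parents, additive
reaction-norm coefficients drawn from N(0, K (x) C_a) with K the realized
genomic relationship of the hybrids, a broad-environment repeated-record term
N(0, I (x) C_be), an environment merit spanning a stated yield range, and a
residual standard deviation exponentially linked to the scaled gradient.
Environment covariates (daily weather and layered soil) are generated with a
subset of variables linearly loaded on the environment merit so that the
merit-prediction stage has recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, grm_vanraden1
from .rnm import legendre_basis

__all__ = [
    "SimulationConfig",
    "TruthBundle",
    "simulate_parents",
    "make_hybrids",
    "simulate_trial",
    "simulate_env_covariates",
    "WEATHER_VARIABLES",
    "SOIL_VARIABLES",
    "SOIL_DEPTHS",
]

# Monthly-aggregated weather variables (NASA-POWER style identifiers) and the
# layered soil variables consumed by the merit-prediction stage.
WEATHER_VARIABLES = [
    "ALLSKY_SFC_PAR_TOT", "T2MWET", "QV2M", "RH2M", "T2M_MAX", "PS",
    "T2MDEW", "WS2M", "T2M_MIN", "T2M", "PRECTOTCORR",
]
SOIL_VARIABLES = ["Sand", "Silt", "Clay", "SOC", "Nitrogen"]
SOIL_DEPTHS = ["0-5", "5-15", "15-30"]


@dataclass
class SimulationConfig:
    """Generative settings for a synthetic hybrid trial.

    Scale defaults are roughly one tenth of a large public maize
    multi-environment trial (thousands of hybrids across ~90 location-years);
    the genetic architecture defaults are a 3-coefficient additive covariance
    diag(0.5, 0.2, 0.05), a small broad-environment covariance, and a
    residual link exp(-0.7 + 0.5 theta), with environment mean yields
    spanning 4.2-13.5 Mg/ha.
    """

    n_parents: int = 60
    n_snps: int = 1000
    n_hybrids: int = 150
    n_envs: int = 16
    n_years: int = 4
    reps_per_plot: int = 2
    incidence_density: float = 0.25
    C_a: np.ndarray = field(
        default_factory=lambda: np.diag([0.5, 0.2, 0.05]))
    C_be: np.ndarray = field(
        default_factory=lambda: np.diag([0.1, 0.03, 0.01]))
    d0: float = -0.7
    d1: float = 0.5
    merit_range: tuple = (4.2, 13.5)
    covariate_noise: float = 1.0
    outlier_frac: float = 0.0
    identity_coeff_draws: bool = False   # misspecification experiments
    seed: int = 0

    def __post_init__(self):
        self.C_a = np.asarray(self.C_a, dtype=float)
        self.C_be = np.asarray(self.C_be, dtype=float)
        for name, M in (("C_a", self.C_a), ("C_be", self.C_be)):
            if M.shape != (3, 3) or not np.allclose(M, M.T):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            if np.linalg.eigvalsh(M)[0] < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
        if not (0.0 < self.incidence_density <= 1.0):
            raise ValueError("incidence_density must be in (0, 1]")
        if self.reps_per_plot < 1:
            raise ValueError("reps_per_plot must be >= 1")
        for name in ("n_parents", "n_snps", "n_hybrids", "n_envs", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["C_a"] = self.C_a.tolist()
        d["C_be"] = self.C_be.tolist()
        return d


@dataclass
class TruthBundle:
    """Ground truth of a simulated trial, for parameter-recovery tests."""

    true_merit: pd.Series              # per-environment mean yield, Mg/ha
    true_theta: pd.Series              # min-max scaled merit, [-1, 1]
    true_coeffs_a: pd.DataFrame        # hybrids x 3 additive coefficients
    true_coeffs_be: pd.DataFrame       # hybrids x 3 broad-environment
    true_gebv: pd.DataFrame            # hybrids x environments, = a T'
    outlier_flags: pd.Series           # aligned to the phenotype table index
    config: SimulationConfig


# ---------------------------------------------------------------------------
# parents and hybrids
# ---------------------------------------------------------------------------

def simulate_parents(n_parents: int, n_snps: int, seed: int,
                     n_chrom: int = 2, mean_spacing_bp: float = 2000.0,
                     ld_length_bp: float = 2000.0,
                     missing_rate: float = 0.0,
                     het_error_rate: float = 0.0) -> tuple[GenotypeMatrix,
                                                           np.ndarray]:
    """Simulate a homozygous biallelic inbred panel.

    Major-allele frequencies are drawn from 1 - (0.01 + 0.49 Beta(0.6, 1.4)),
    a spectrum with substantial mass just above the 1% MAF bound.  Calls are
    thresholded from a latent Gaussian AR process whose step correlation
    decays as exp(-spacing / ld_length_bp), producing LD that decays with bp
    distance.  ``het_error_rate`` plants stray heterozygous calls and
    ``missing_rate`` masks calls, both for QC testing; clean panels use the
    defaults of zero.
    """
    if n_parents < 4 or n_snps < 10:
        raise ValueError("need n_parents >= 4 and n_snps >= 10")
    rng = np.random.default_rng(seed)

    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps - per.sum()] += 1
    chroms, pos = [], []
    for c, k in enumerate(per, start=1):
        spacing = rng.exponential(mean_spacing_bp, size=k).astype(int) + 1
        p = np.cumsum(spacing)
        chroms.extend([str(c)] * k)
        pos.extend(p.tolist())
    pos = np.array(pos)

    maf = 0.01 + 0.49 * rng.beta(0.6, 1.4, size=n_snps)
    p_major = 1.0 - maf

    # latent AR process per parent, restarting at chromosome boundaries
    step = np.ones(n_snps)
    start = 0
    for k in per:
        d = np.diff(pos[start:start + k], prepend=pos[start])
        rho = np.exp(-d / ld_length_bp)
        rho[0] = 0.0
        step[start:start + k] = rho
        start += k
    z = np.empty((n_parents, n_snps))
    eps = rng.standard_normal((n_parents, n_snps))
    z[:, 0] = eps[:, 0]
    for s in range(1, n_snps):
        r = step[s]
        z[:, s] = r * z[:, s - 1] + np.sqrt(1.0 - r * r) * eps[:, s]

    from scipy.stats import norm
    thresh = norm.ppf(p_major)
    values = np.where(z <= thresh, 2.0, 0.0)

    if het_error_rate > 0:
        mask = rng.random(values.shape) < het_error_rate
        values[mask] = 1.0
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan

    snps = pd.DataFrame({
        "snp_id": [f"S{c}_{p}" for c, p in zip(chroms, pos)],
        "chrom": chroms, "pos": pos, "biallelic": True,
    })
    samples = [f"P{i:03d}" for i in range(n_parents)]
    g = GenotypeMatrix(samples, snps, values)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(values, axis=0) / 2.0
    g.allele_freq = freq
    return g, freq


def hybrids_from_crosses(parents: GenotypeMatrix, cross: pd.DataFrame
                         ) -> GenotypeMatrix:
    """Assemble hybrid genotypes from a hybrid -> (parent1, parent2) table.

    With homozygous parents the hybrid call at a locus is the Mendelian sum
    of one gamete from each parent, (p1 + p2) / 2 on the 0/2 coding.
    """
    vals = parents.values
    if np.isnan(vals).any():
        raise ValueError("parents must be complete (impute first)")
    if not np.isin(vals, (0.0, 2.0)).all():
        raise ValueError("parents must be homozygous (0/2 coding); "
                         "odd parental sums are not Mendelian for inbreds")
    idx = {s: i for i, s in enumerate(parents.samples)}
    missing = ({*cross["parent1"], *cross["parent2"]} - set(idx))
    if missing:
        raise ValueError(f"cross table parents absent from the panel: "
                         f"{sorted(missing)[:5]}")
    hv = np.stack([(vals[idx[p1]] + vals[idx[p2]]) / 2.0
                   for p1, p2 in zip(cross["parent1"], cross["parent2"])])
    hyb = GenotypeMatrix(list(cross["hybrid_id"]), parents.snps.copy(), hv)
    hyb.compute_freq()
    return hyb


def make_hybrids(parents: GenotypeMatrix, n_hybrids: int, seed: int
                 ) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Cross homozygous parents into random single-cross hybrids.

    Each hybrid is an unordered pair of two distinct parents; values follow
    the Mendelian sum, so hybrid calls lie in {0, 1, 2}.
    """
    vals = parents.values
    if np.isnan(vals).any():
        raise ValueError("parents must be complete (impute first)")
    if not np.isin(vals, (0.0, 2.0)).all():
        raise ValueError("parents must be homozygous (0/2 coding); "
                         "odd parental sums are not Mendelian for inbreds")
    n = parents.n_samples
    max_crosses = n * (n - 1) // 2
    if n_hybrids > max_crosses:
        raise ValueError(
            f"cross space exhausted: {n_hybrids} hybrids requested but only "
            f"{max_crosses} distinct parent pairs exist")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_hybrids:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        chosen.add((min(i, j), max(i, j)))
    pairs = sorted(chosen)
    rng.shuffle(pairs)
    pairs = pairs[:n_hybrids]

    hybrid_ids = [f"H{k:04d}" for k in range(n_hybrids)]
    cross = pd.DataFrame({
        "hybrid_id": hybrid_ids,
        "parent1": [parents.samples[i] for i, _ in pairs],
        "parent2": [parents.samples[j] for _, j in pairs],
    })
    return cross, hybrids_from_crosses(parents, cross)


# ---------------------------------------------------------------------------
# trial phenotypes
# ---------------------------------------------------------------------------

def _env_layout(n_envs: int, n_years: int) -> pd.DataFrame:
    per = np.full(n_years, n_envs // n_years)
    per[: n_envs - per.sum()] += 1
    rows = []
    for y, k in enumerate(per, start=1):
        for loc in range(1, k + 1):
            rows.append({"env_id": f"L{loc:02d}_Y{y}", "year": y,
                         "location": f"L{loc:02d}"})
    return pd.DataFrame(rows)


def simulate_trial(genotypes: GenotypeMatrix, config: SimulationConfig
                   ) -> tuple[pd.DataFrame, TruthBundle]:
    """Generate plot-level yields for a hybrid x environment trial.

    Environment merits are uniform on ``merit_range`` and min-max scaled to
    the true gradient.  Hybrid coefficient vectors are drawn from the matrix
    normal with row covariance K (the realized VanRaden relationship of the
    supplied hybrids, identity when ``identity_coeff_draws``) and column
    covariance C_a; the broad-environment term uses identity rows and C_be.
    The hybrid x environment incidence is year-structured (each hybrid is
    active in a 1-3 year window) and thinned to ``incidence_density``; every
    environment keeps at least two hybrids and every hybrid at least one
    environment.  Records are replicated ``reps_per_plot`` times with
    residual SD sqrt(exp(d0 + d1 theta)).  ``outlier_frac`` of records are
    displaced beyond 3 environment SDs and flagged in the truth bundle.
    """
    cfg = config
    if np.isnan(genotypes.values).any():
        raise ValueError("genotypes must be complete")
    rng = np.random.default_rng(cfg.seed)
    hybrids = list(genotypes.samples)
    q = len(hybrids)

    envs = _env_layout(cfg.n_envs, cfg.n_years)
    merit = rng.uniform(*cfg.merit_range, size=cfg.n_envs)
    bmin, bmax = merit.min(), merit.max()
    theta = -1.0 + 2.0 * (merit - bmin) / (bmax - bmin) if bmax > bmin \
        else np.zeros(cfg.n_envs)
    T = legendre_basis(theta, 2)

    if cfg.identity_coeff_draws:
        Lk = np.eye(q)
    else:
        K = grm_vanraden1(genotypes, blend=1e-6).matrix
        Lk = np.linalg.cholesky(K + 1e-8 * np.eye(q))
    La = _chol_psd(cfg.C_a)
    Lbe = _chol_psd(cfg.C_be)
    A = Lk @ rng.standard_normal((q, 3)) @ La.T
    BE = rng.standard_normal((q, 3)) @ Lbe.T

    # year-structured incidence
    years = envs["year"].to_numpy()
    env_by_year = {y: np.nonzero(years == y)[0] for y in np.unique(years)}
    span_probs = np.array([0.5, 0.3, 0.2])
    for attempt in range(20):
        cells = np.zeros((q, cfg.n_envs), dtype=bool)
        for j in range(q):
            start = rng.integers(1, cfg.n_years + 1)
            span = min(rng.choice([1, 2, 3], p=span_probs), cfg.n_years)
            active = [y for y in range(start, start + span)
                      if y <= cfg.n_years]
            allowed = np.concatenate([env_by_year[y] for y in active])
            take = allowed[rng.random(len(allowed)) < cfg.incidence_density]
            if take.size == 0:
                take = np.array([rng.choice(allowed)])
            cells[j, take] = True
        if (cells.sum(axis=0) >= 2).all():
            break
    else:
        raise ValueError(
            "incidence too sparse: some environment kept fewer than two "
            "hybrids; increase incidence_density or n_hybrids")

    jj, ee = np.nonzero(cells)
    reps = cfg.reps_per_plot
    n_rec = len(jj) * reps
    j_rec = np.repeat(jj, reps)
    e_rec = np.repeat(ee, reps)
    rep_rec = np.tile(np.arange(1, reps + 1), len(jj))
    sd_env = np.sqrt(np.exp(cfg.d0 + cfg.d1 * theta))
    genetic = np.sum(T[e_rec] * (A[j_rec] + BE[j_rec]), axis=1)
    y = merit[e_rec] + genetic + rng.standard_normal(n_rec) * sd_env[e_rec]

    out_flags = np.zeros(n_rec, dtype=bool)
    n_out = int(round(cfg.outlier_frac * n_rec))
    if n_out > 0:
        pick = rng.choice(n_rec, size=n_out, replace=False)
        sign = rng.choice([-1.0, 1.0], size=n_out)
        y[pick] += sign * rng.uniform(4.0, 6.0, size=n_out) * sd_env[e_rec[pick]]
        out_flags[pick] = True

    table = pd.DataFrame({
        "env_id": envs["env_id"].to_numpy()[e_rec],
        "year": envs["year"].to_numpy()[e_rec],
        "location": envs["location"].to_numpy()[e_rec],
        "hybrid_id": np.array(hybrids)[j_rec],
        "rep": rep_rec,
        "yield_Mg_ha": y,
    })

    env_index = envs["env_id"]
    truth = TruthBundle(
        true_merit=pd.Series(merit, index=env_index, name="merit"),
        true_theta=pd.Series(theta, index=env_index, name="theta"),
        true_coeffs_a=pd.DataFrame(A, index=hybrids,
                                   columns=["a0", "a1", "a2"]),
        true_coeffs_be=pd.DataFrame(BE, index=hybrids,
                                    columns=["be0", "be1", "be2"]),
        true_gebv=pd.DataFrame(A @ T.T, index=hybrids, columns=env_index),
        outlier_flags=pd.Series(out_flags, index=table.index,
                                name="is_outlier"),
        config=cfg,
    )
    return table, truth


def _chol_psd(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(np.asarray(M, float))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


# ---------------------------------------------------------------------------
# environment covariates
# ---------------------------------------------------------------------------

_MONTHS = [4, 5, 6, 7, 8, 9, 10]
_DAYS_IN_MONTH = {4: 30, 5: 31, 6: 30, 7: 31, 8: 31, 9: 30, 10: 31}

# daily base level and seasonal amplitude for each weather variable, plus the
# linear loading of the environment merit (z-scored); two weather variables
# and one soil variable carry signal, the rest are pure noise
_WEATHER_BASE = {
    "ALLSKY_SFC_PAR_TOT": (110.0, 15.0, 2.0),
    "T2MWET": (16.0, 4.0, 0.0),
    "QV2M": (10.0, 3.0, 0.0),
    "RH2M": (70.0, 8.0, 0.0),
    "T2M_MAX": (27.0, 6.0, 0.0),
    "PS": (98.0, 1.0, 0.0),
    "T2MDEW": (12.0, 5.0, 0.0),
    "WS2M": (4.0, 1.0, 0.0),
    "T2M_MIN": (12.0, 5.0, 0.0),
    "T2M": (20.0, 6.0, 2.0),
    "PRECTOTCORR": (3.0, 1.0, 0.0),
}
_SOIL_BASE = {
    "Sand": 400.0, "Silt": 350.0, "Clay": 250.0,
    "SOC": 15.0, "Nitrogen": 1.5,
}
_SOIL_LOADING = {"SOC": 1.5}


def simulate_env_covariates(merit: pd.Series, covariate_noise: float,
                            seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily April-October weather and layered soil tables per environment.

    T2M and ALLSKY_SFC_PAR_TOT (weather) and SOC (soil) are linear in the
    z-scored environment merit plus noise; all other variables are pure
    noise around realistic levels, so a merit predictor has both signal and
    distractor features.  With ``covariate_noise`` = 0 the monthly summaries
    of the loaded variables are exact linear functions of merit.
    """
    rng = np.random.default_rng(seed)
    merit = pd.Series(merit)
    mz = (merit - merit.mean())
    sd = mz.std()
    mz = mz / sd if sd > 0 else mz * 0.0

    days = []
    for m in _MONTHS:
        days.extend((m, d) for d in range(1, _DAYS_IN_MONTH[m] + 1))
    n_days = len(days)

    wrows = []
    for env, z in mz.items():
        block = {
            "env_id": env,
            "date": [f"2016-{m:02d}-{d:02d}" for m, d in days],
        }
        doy = np.arange(n_days)
        season = np.sin(np.pi * doy / n_days)
        for var, (base, amp, load) in _WEATHER_BASE.items():
            vals = (base + amp * season + load * z
                    + covariate_noise * rng.standard_normal(n_days))
            if var == "PRECTOTCORR":
                vals = np.clip(vals, 0.0, None)
            block[var] = vals
        wrows.append(pd.DataFrame(block))
    weather = pd.concat(wrows, ignore_index=True)

    srows = []
    for env, z in mz.items():
        for depth in SOIL_DEPTHS:
            row = {"env_id": env, "depth_cm": depth}
            for var in SOIL_VARIABLES:
                load = _SOIL_LOADING.get(var, 0.0)
                row[var] = (_SOIL_BASE[var] + load * z
                            + covariate_noise * rng.standard_normal())
            srows.append(row)
    soil = pd.DataFrame(srows)
    return weather, soil
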