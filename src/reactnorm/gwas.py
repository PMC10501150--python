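"""SNP effects backsolved from reaction-norm coefficient predictions.

Per-coefficient SNP effects are recovered from the hybrid coefficient
predictions by the projection u_j = Z'(ZZ')^-1 a_j, with Z the centred
allele-count matrix used to build the relationship matrix (minimum-norm
pseudo-inverse solution when ZZ' is singular).  Per-environment SNP effects
follow by basis expansion, SNP_s = T u_s.  Effects are reported for the
major allele: a negative value means the minor allele is favourable.

Top-SNP selection mimics the field practice of taking the k largest-effect
markers per environment while pruning anything in LD with an already
selected marker; allele-state yield contrasts use one-way ANOVA over the
three genotype classes followed by Fisher LSD grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .rnm import legendre_basis

__all__ = [
    "backsolve_snp_effects",
    "snp_env_effects",
    "select_top_snps",
    "allele_state_test",
    "AlleleStateResult",
    "annotation_window_query",
]


def backsolve_snp_effects(Z: np.ndarray, a_hat: pd.DataFrame,
                          snp_ids=None) -> pd.DataFrame:
    """Backsolve per-coefficient SNP effects from coefficient predictions.

    Parameters
    ----------
    Z : hybrids x SNPs centred genotype matrix (M - 2p, the same centring as
        the relationship matrix; build it with an unblended G for the exact
        reconstruction identity Z u = a).
    a_hat : hybrids x coefficients predictions from the reaction-norm fit.

    Returns SNPs x coefficients effects (minimum-norm solution when ZZ' is
    rank deficient).  A monomorphic SNP has a zero centred column and hence
    an exactly zero effect.
    """
    Z = np.asarray(Z, float)
    A = a_hat.to_numpy(dtype=float)
    if Z.shape[0] != A.shape[0]:
        raise ValueError(
            f"dimension mismatch: Z has {Z.shape[0]} hybrids, "
            f"a_hat has {A.shape[0]}")
    ZZt = Z @ Z.T
    # pinv handles singular ZZ' (minimum-norm solution)
    U = Z.T @ np.linalg.pinv(ZZt, hermitian=True) @ A
    cols = list(a_hat.columns)
    idx = (list(snp_ids) if snp_ids is not None
           else [f"snp{i}" for i in range(Z.shape[1])])
    return pd.DataFrame(U, index=idx, columns=cols)


def snp_env_effects(u_hat: pd.DataFrame, T: np.ndarray | None = None,
                    theta=None, env_ids=None) -> pd.DataFrame:
    """Per-environment SNP effects: SNP_s = T u_s (basis expansion)."""
    U = u_hat.to_numpy(dtype=float)
    order = U.shape[1] - 1
    if T is None:
        if theta is None:
            raise ValueError("supply T or theta")
        T = legendre_basis(theta, order)
    T = np.asarray(T, float)
    if T.shape[1] != U.shape[1]:
        raise ValueError("basis order mismatch between T and u_hat")
    cols = (list(env_ids) if env_ids is not None
            else [f"env{i}" for i in range(T.shape[0])])
    return pd.DataFrame(U @ T.T, index=u_hat.index, columns=cols)


def select_top_snps(effects: pd.DataFrame, k: int, ld_table: pd.DataFrame,
                    ld_threshold: float = 0.2, snp_meta: pd.DataFrame = None,
                    global_pruning: bool = True) -> dict:
    """Greedy top-k selection per environment with LD pruning.

    Per environment, SNPs are visited in decreasing |effect| (ties broken by
    chromosome then position when ``snp_meta`` is given, else by SNP id); a
    SNP is taken unless its LD with any already selected SNP exceeds
    ``ld_threshold``.  With ``global_pruning`` the running selection spans
    all environments processed so far (a SNP already selected elsewhere can
    be re-selected for another environment - it is never in LD with itself);
    otherwise pruning is only against the current environment's picks.
    Pairs absent from ``ld_table`` (beyond the LD window) are treated as not
    in LD.

    Returns {"per_env": {env: [snp, ...]}, "union": [...]}.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ld = {}
    for a, b, r2 in zip(ld_table["snp_a"], ld_table["snp_b"],
                        ld_table["r2"]):
        ld[(a, b)] = r2
        ld[(b, a)] = r2

    if snp_meta is not None:
        meta = snp_meta.set_index("snp_id")
        def sort_key(s):
            return (str(meta.at[s, "chrom"]), int(meta.at[s, "pos"]))
    else:
        def sort_key(s):
            return (s,)

    per_env: dict = {}
    global_sel: list = []
    for env in effects.columns:
        col = effects[env]
        ranked = sorted(col.index,
                        key=lambda s: (-abs(col[s]),) + sort_key(s))
        base = global_sel if global_pruning else []
        picks = []
        for s in ranked:
            if len(picks) >= k:
                break
            against = [t for t in set(base) | set(picks) if t != s]
            if any(ld.get((s, t), 0.0) > ld_threshold for t in against):
                continue
            picks.append(s)
            if global_pruning and s not in global_sel:
                global_sel.append(s)
        per_env[env] = picks
    union = sorted({s for picks in per_env.values() for s in picks})
    return {"per_env": per_env, "union": union}


@dataclass
class AlleleStateResult:
    """Allele-state yield contrast for one (SNP, environment) pair."""

    snp_id: str
    env_id: str
    theta: float
    included: bool
    reason: str = ""
    class_counts: dict = field(default_factory=dict)
    class_means: dict = field(default_factory=dict)
    F: float = np.nan
    p: float = np.nan
    groups: dict = field(default_factory=dict)   # genotype state -> letters
    minor_beats_major: bool = False


def allele_state_test(phenotypes: pd.DataFrame, genotypes: GenotypeMatrix,
                      snp_ids, gradient, min_class: int = 10,
                      alpha: float = 0.05, y_col: str = "yield_Mg_ha"
                      ) -> list[AlleleStateResult]:
    """Compare hybrid yields across the three genotype states per SNP.

    Hybrids are averaged to one value per environment; classes are the
    major-allele counts {0 (minor homozygote), 1, 2 (major homozygote)}.
    A pair is excluded when the environment's gradient value is <= 0, when
    any genotype class holds fewer than ``min_class`` hybrids, or when fewer
    than two classes are non-empty.  Where the one-way ANOVA is significant
    at ``alpha``, Fisher LSD letters are assigned; ``minor_beats_major``
    flags pairs where the minor-homozygote class significantly out-yields
    the major-homozygote class.
    """
    theta_map = (gradient.theta_map() if hasattr(gradient, "theta_map")
                 else dict(gradient))
    snp_pos = {s: i for i, s in enumerate(genotypes.snps["snp_id"])}
    hyb_pos = {h: i for i, h in enumerate(genotypes.samples)}

    hyb_means = (phenotypes.groupby(["env_id", "hybrid_id"])[y_col]
                 .mean().reset_index())
    results: list[AlleleStateResult] = []
    for snp in snp_ids:
        if snp not in snp_pos:
            raise KeyError(f"unknown SNP {snp!r}")
        calls = genotypes.values[:, snp_pos[snp]]
        for env, sub in hyb_means.groupby("env_id"):
            theta = float(theta_map.get(env, np.nan))
            res = AlleleStateResult(snp_id=snp, env_id=env, theta=theta,
                                    included=False)
            if not theta > 0.0:
                res.reason = "environment not above 0 on the gradient"
                results.append(res)
                continue
            states = np.array([calls[hyb_pos[h]] for h in sub["hybrid_id"]])
            yv = sub[y_col].to_numpy(dtype=float)
            groups = {s: yv[states == s] for s in (0.0, 1.0, 2.0)}
            res.class_counts = {int(s): int(len(g))
                                for s, g in groups.items()}
            res.class_means = {int(s): (float(g.mean()) if len(g) else np.nan)
                               for s, g in groups.items()}
            nonempty = [g for g in groups.values() if len(g) > 0]
            if len(nonempty) < 2:
                res.reason = "fewer than two genotype classes present"
                results.append(res)
                continue
            if any(len(g) < min_class for g in groups.values()):
                res.reason = "class below minimum"
                results.append(res)
                continue
            res.included = True
            res.F, res.p = _anova_f(groups)
            if res.p < alpha:
                res.groups = _lsd_letters(groups, alpha)
                res.minor_beats_major = _sig_greater(groups, 0.0, 2.0, alpha)
            else:
                res.groups = {0: "a", 1: "a", 2: "a"}
            results.append(res)
    return results


def _anova_f(groups: dict) -> tuple[float, float]:
    arrays = [g for g in groups.values() if len(g) > 0]
    all_equal = all(np.ptp(g) == 0 for g in arrays) and \
        np.ptp([g[0] for g in arrays]) == 0
    if all_equal:
        return 0.0, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*arrays)
    if np.isnan(F):
        return 0.0, 1.0
    return float(F), float(p)


def _pooled_mse(groups: dict) -> tuple[float, int]:
    sse, df = 0.0, 0
    for g in groups.values():
        if len(g) > 1:
            sse += float(np.sum((g - g.mean()) ** 2))
            df += len(g) - 1
    return (sse / df if df > 0 else np.nan), df


def _lsd_pvalue(ga, gb, mse, df) -> float:
    se = np.sqrt(mse * (1.0 / len(ga) + 1.0 / len(gb)))
    if se == 0 or df <= 0:
        return 1.0
    t = (ga.mean() - gb.mean()) / se
    return float(2.0 * stats.t.sf(abs(t), df))


def _sig_greater(groups, a, b, alpha) -> bool:
    ga, gb = groups[a], groups[b]
    if len(ga) == 0 or len(gb) == 0:
        return False
    mse, df = _pooled_mse(groups)
    p = _lsd_pvalue(ga, gb, mse, df)
    return p < alpha and ga.mean() > gb.mean()


def _lsd_letters(groups: dict, alpha: float) -> dict:
    """Compact letter display from pairwise Fisher LSD tests."""
    keys = [s for s, g in groups.items() if len(g) > 0]
    keys.sort(key=lambda s: -groups[s].mean())
    mse, df = _pooled_mse(groups)
    differ = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            differ[(a, b)] = differ[(b, a)] = \
                _lsd_pvalue(groups[a], groups[b], mse, df) < alpha
    letters: dict = {s: "" for s in keys}
    letter_ord = 0
    covered: set = set()
    for i, a in enumerate(keys):
        if a in covered:
            continue
        block = [a]
        for b in keys[i + 1:]:
            if all(not differ[(b, c)] for c in block):
                block.append(b)
        lab = chr(ord("a") + letter_ord)
        letter_ord += 1
        for s in block:
            letters[s] += lab
        covered.update(block)
    return {int(s): letters[s] for s in keys}


def annotation_window_query(snp_meta: pd.DataFrame,
                            annotations: pd.DataFrame,
                            window_bp: int = 1000) -> pd.DataFrame:
    """Genes within +-window_bp of each SNP (closed interval, 1-based).

    ``annotations`` needs columns chrom, start, end, name (e.g. parsed from
    BED or GFF).  Returns one row per (snp, gene) hit.
    """
    hits = []
    for _, snp in snp_meta.iterrows():
        lo, hi = snp["pos"] - window_bp, snp["pos"] + window_bp
        sel = annotations[(annotations["chrom"].astype(str) ==
                           str(snp["chrom"]))
                          & (annotations["end"] >= lo)
                          & (annotations["start"] <= hi)]
        for _, gene in sel.iterrows():
            hits.append({"snp_id": snp["snp_id"], "gene": gene["name"],
                         "gene_start": gene["start"],
                         "gene_end": gene["end"]})
    return pd.DataFrame(hits,
                        columns=["snp_id", "gene", "gene_start", "gene_end"])
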