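"""Genotype handling: QC, naive imputation, hybrid assembly support, GRM, LD.

SNP calls are held as counts of the *major* allele (0/1/2) per sample x SNP,
the coding used throughout the downstream genomic models.  Missing calls are
``NaN`` and are only legal before imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "QCReport",
    "qc_inbreds",
    "impute_naive",
    "grm_vanraden1",
    "ld_r2_window",
]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-count matrix with marker metadata.

    Attributes
    ----------
    samples : list of str
        Sample identifiers (inbred parents or hybrids), one per row.
    snps : pandas.DataFrame
        Marker table with columns ``snp_id``, ``chrom``, ``pos`` (1-based bp,
        non-decreasing within chromosome) and, when known, ``biallelic``.
    values : numpy.ndarray, float
        Counts of the reference/major allele in {0, 1, 2}; NaN = missing.
    allele_freq : numpy.ndarray or None
        Per-SNP frequency of the counted allele.  After major-allele
        orientation this lies in [0.5, 1].
    oriented : bool
        True once columns have been flipped so the counted allele is major.
    """

    samples: list
    snps: pd.DataFrame
    values: np.ndarray
    allele_freq: np.ndarray | None = None
    oriented: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~(np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("genotype values must be 0/1/2 or missing (NaN)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.snps.reset_index(drop=True).copy(),
            self.values.copy(),
            None if self.allele_freq is None else self.allele_freq.copy(),
            self.oriented,
        )

    def compute_freq(self) -> np.ndarray:
        """Frequency of the counted allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.values, axis=0) / 2.0
        self.allele_freq = freq
        return freq

    def orient_major(self) -> "GenotypeMatrix":
        """Flip columns so the counted allele is the major one (freq >= 0.5)."""
        freq = self.compute_freq()
        flip = freq < 0.5
        out = self.copy()
        out.values[:, flip] = 2.0 - out.values[:, flip]
        out.allele_freq = np.where(flip, 1.0 - freq, freq)
        out.oriented = True
        return out

    # ---- plain-text I/O (0/1/2 TSV) -------------------------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.samples,
                          columns=self.snps["snp_id"])
        df.index.name = "sample"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, snp_meta: pd.DataFrame | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        vals = df.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid genotype value {vals[r, c]!r} at sample "
                f"{df.index[r]!r}, SNP {df.columns[c]!r} (line {r + 2})"
            )
        if snp_meta is None:
            snp_meta = pd.DataFrame(
                {"snp_id": df.columns,
                 "chrom": "1",
                 "pos": np.arange(1, len(df.columns) + 1)}
            )
        return cls(list(df.index), snp_meta.reset_index(drop=True), vals)


@dataclass
class GRM:
    """VanRaden method-1 genomic relationship matrix with provenance."""

    samples: list
    matrix: np.ndarray
    denominator: float
    blend: float = 0.0

    @property
    def n(self) -> int:
        return len(self.samples)

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def logdet(self) -> float:
        sign, ld = np.linalg.slogdet(self.matrix)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "GRM is not positive definite; increase the blend fraction"
            )
        return ld


@dataclass
class QCReport:
    """Counts of SNPs/calls affected by each genotype-QC rule."""

    n_snps_in: int = 0
    n_het_calls_masked: int = 0
    n_non_biallelic_dropped: int = 0
    n_maf_dropped: int = 0
    n_missing_dropped: int = 0
    n_snps_out: int = 0
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def qc_inbreds(calls: GenotypeMatrix, maf_min: float = 0.01,
               miss_max: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """Quality-control raw inbred-line calls.

    Filter order is fixed: heterozygous calls are set missing (implausible in
    inbreds), SNPs flagged non-biallelic are dropped, then a minor-allele-
    frequency filter (strictly below ``maf_min``, computed on non-missing
    calls) and a missingness filter (fraction missing strictly above
    ``miss_max``).  The surviving matrix is oriented to major-allele counts.
    """
    rep = QCReport(n_snps_in=calls.n_snps,
                   params={"maf_min": maf_min, "miss_max": miss_max})
    g = calls.copy()

    het = g.values == 1.0
    rep.n_het_calls_masked = int(het.sum())
    g.values[het] = np.nan

    if "biallelic" in g.snps.columns:
        keep = g.snps["biallelic"].astype(bool).to_numpy()
    else:
        keep = np.ones(g.n_snps, dtype=bool)
    rep.n_non_biallelic_dropped = int((~keep).sum())
    g = _subset_snps(g, keep)

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g.values, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    all_missing = np.isnan(freq)
    keep = ~all_missing & (maf >= maf_min)          # "less than 1%" is strict
    rep.n_maf_dropped = int((~keep).sum())
    g = _subset_snps(g, keep)

    miss = np.isnan(g.values).mean(axis=0)
    keep = miss <= miss_max
    rep.n_missing_dropped = int((~keep).sum())
    g = _subset_snps(g, keep)

    rep.n_snps_out = g.n_snps
    if g.n_snps == 0:
        worst = max(
            [("non-biallelic", rep.n_non_biallelic_dropped),
             ("MAF", rep.n_maf_dropped),
             ("missingness", rep.n_missing_dropped)],
            key=lambda kv: kv[1],
        )[0]
        raise ValueError(
            f"all SNPs removed by QC; dominating rule: {worst}"
        )
    return g.orient_major(), rep


def _subset_snps(g: GenotypeMatrix, keep: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(
        list(g.samples),
        g.snps.loc[keep].reset_index(drop=True),
        g.values[:, keep],
        None,
        g.oriented,
    )


def impute_naive(matrix: GenotypeMatrix, inbred: bool = True) -> GenotypeMatrix:
    """Replace missing calls with the rounded per-SNP expectation 2p.

    For inbred panels the replacement is constrained to the homozygous states,
    i.e. the nearest of {0, 2} (ties go to the major homozygote).  This is a
    deterministic frequency-based imputer, not a haplotype model.
    """
    g = matrix.copy()
    obs = ~np.isnan(g.values)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0,
                        np.nansum(g.values, axis=0) / (2.0 * n_obs), np.nan)
    if np.isnan(freq).any():
        bad = g.snps["snp_id"].iloc[int(np.argmax(np.isnan(freq)))]
        raise ValueError(f"SNP {bad!r} has no observed calls; cannot impute")
    if inbred:
        fill = np.where(2.0 * freq >= 1.0, 2.0, 0.0)
    else:
        fill = np.clip(np.round(2.0 * freq), 0, 2)
    miss = np.isnan(g.values)
    g.values[miss] = np.broadcast_to(fill, g.values.shape)[miss]
    g.compute_freq()
    return g


def grm_vanraden1(matrix: GenotypeMatrix, blend: float = 0.01,
                  freq: np.ndarray | None = None) -> GRM:
    """VanRaden method-1 GRM: G = WW' / (2 * sum p(1-p)), W = M - 2p.

    ``freq`` overrides the allele frequencies used for centring (defaults to
    the frequencies observed in ``matrix``).  ``blend`` mixes in an identity
    fraction, G* = (1-eps) G + eps I, to guarantee invertibility.
    """
    M = matrix.values
    if np.isnan(M).any():
        raise ValueError("GRM requires a complete (imputed) genotype matrix")
    p = matrix.compute_freq() if freq is None else np.asarray(freq, float)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: zero GRM denominator")
    W = M - 2.0 * p
    G = (W @ W.T) / denom
    if blend:
        G = (1.0 - blend) * G + blend * np.eye(len(G))
    return GRM(list(matrix.samples), G, denom, blend)


def ld_r2_window(matrix: GenotypeMatrix, window_snps: int = 100,
                 decay_threshold: float = 0.2,
                 n_bins: int = 20) -> tuple[pd.DataFrame, dict]:
    """Pairwise r^2 of allele counts within a sliding index window.

    Returns the pair table (within-chromosome pairs up to ``window_snps``
    apart) and a decay summary: mean r^2 binned by bp distance plus the first
    bin midpoint at which mean r^2 falls below ``decay_threshold``.
    Zero-variance SNPs yield undefined correlations; such pairs are skipped
    and counted.
    """
    M = matrix.values
    if np.isnan(M).any():
        raise ValueError("LD requires a complete genotype matrix")
    chroms = matrix.snps["chrom"].to_numpy()
    pos = matrix.snps["pos"].to_numpy()
    ids = matrix.snps["snp_id"].to_numpy()
    sd = M.std(axis=0)
    Mc = M - M.mean(axis=0)

    rows = []
    n_skipped = 0
    for off in range(1, window_snps + 1):
        if off >= M.shape[1]:
            break
        a = slice(0, M.shape[1] - off)
        b = slice(off, M.shape[1])
        same = chroms[a] == chroms[b]
        ok = same & (sd[a] > 0) & (sd[b] > 0)
        n_skipped += int((same & ~ok).sum())
        if not ok.any():
            continue
        ia = np.nonzero(ok)[0]
        ib = ia + off
        num = (Mc[:, ia] * Mc[:, ib]).sum(axis=0)
        r2 = (num / (M.shape[0] * sd[ia] * sd[ib])) ** 2
        rows.append(pd.DataFrame({
            "snp_a": ids[ia], "snp_b": ids[ib],
            "dist_bp": np.abs(pos[ib] - pos[ia]), "r2": r2,
        }))
    table = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["snp_a", "snp_b", "dist_bp", "r2"]))

    summary: dict = {"n_pairs": len(table), "n_skipped": n_skipped,
                     "threshold": decay_threshold, "decay_distance_bp": None}
    if len(table):
        edges = np.linspace(0, table["dist_bp"].max() + 1, n_bins + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        idx = np.digitize(table["dist_bp"], edges) - 1
        means = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                means[b] = table["r2"][sel].mean()
        summary["bin_mid_bp"] = mids.tolist()
        summary["bin_mean_r2"] = means.tolist()
        below = np.nonzero(~np.isnan(means) & (means < decay_threshold))[0]
        if below.size:
            summary["decay_distance_bp"] = float(mids[below[0]])
    return table, summary
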