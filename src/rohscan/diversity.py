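"""Heterozygosity and pairwise linkage disequilibrium.

LD is the composite (genotype-correlation) r-squared: the squared Pearson
correlation of counted-allele dosages over the samples non-missing at both
sites.  This is the haplotype-free measure genotype-based toolkits report by
default, and is what the sample-size adjustment (subtract 1/(beta*n), beta=2
for unphased diploid data) and the LD-decay Ne estimator expect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset

__all__ = [
    "LDBin",
    "heterozygosity",
    "ld_r2",
    "bin_ld",
    "r2_adjust",
]


@dataclass
class LDBin:
    """Distance-binned LD summary feeding the Ne estimator."""

    dist_lo_bp: float
    dist_hi_bp: float
    mean_r2: float
    mean_r2adj: float
    n_pairs: int
    c_t: float  # recombination fraction assigned to the bin midpoint

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("empty LD bin")
        if not 0 <= self.mean_r2 <= 1:
            raise ValueError("mean r2 outside [0, 1]")
        if not 0 < self.c_t <= 0.5:
            raise ValueError("c_t must lie in (0, 0.5]")

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.dist_lo_bp + self.dist_hi_bp)


def heterozygosity(ds: GenotypeDataset) -> dict:
    """Observed and expected heterozygosity, per SNP and genome-wide.

    Ho per SNP is the fraction of non-missing calls that are heterozygous;
    He = 2p(1-p) with p from non-missing calls.  Genome-wide values are the
    unweighted mean +/- sd across SNPs.  All-missing SNPs are excluded with a
    warning.
    """
    if ds.n_variants == 0:
        raise ValueError("dataset has no variants")
    calls = ds.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    usable = n_obs > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} all-missing SNP(s) excluded from heterozygosity",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(usable, (calls == 1).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
        p = np.where(usable, np.where(obs, calls, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    he = 2.0 * p * (1.0 - p)
    return {
        "ho_per_snp": ho,
        "he_per_snp": he,
        "ho_mean": float(np.nanmean(ho)),
        "ho_sd": float(np.nanstd(ho, ddof=1)),
        "he_mean": float(np.nanmean(he)),
        "he_sd": float(np.nanstd(he, ddof=1)),
    }


def ld_r2(
    ds: GenotypeDataset,
    max_dist_bp: float = 10_000_000,
    max_pairs_per_snp: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """All within-chromosome SNP pairs up to ``max_dist_bp`` with composite r2.

    Returns a DataFrame with columns chrom, i, j, dist_bp, r2.  Pairs where
    either site has zero variance over the jointly observed samples are
    skipped.  ``max_pairs_per_snp`` subsamples the partners of each left SNP
    (seeded) to bound runtime on dense maps.
    """
    rng = np.random.default_rng(seed)
    rows_chrom: list[str] = []
    rows = []
    for start, stop, chrom in ds.variants.chrom_blocks():
        pos = ds.variants.pos_bp[start:stop]
        block = ds.calls[:, start:stop].astype(np.float64)
        block[block == MISSING] = np.nan
        m = stop - start
        for a in range(m):
            b_hi = int(np.searchsorted(pos, pos[a] + max_dist_bp, side="right"))
            partners = np.arange(a + 1, b_hi)
            if partners.size == 0:
                continue
            if max_pairs_per_snp is not None and partners.size > max_pairs_per_snp:
                partners = np.sort(
                    rng.choice(partners, size=max_pairs_per_snp, replace=False)
                )
            x = block[:, a]
            Y = block[:, partners]
            ok = ~np.isnan(x)[:, None] & ~np.isnan(Y)
            nobs = ok.sum(axis=0)
            xm = np.where(ok, x[:, None], 0.0)
            ym = np.where(ok, Y, 0.0)
            sx = xm.sum(axis=0)
            sy = ym.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = (xm * ym).sum(axis=0) - sx * sy / nobs
                varx = (xm * xm).sum(axis=0) - sx * sx / nobs
                vary = (ym * ym).sum(axis=0) - sy * sy / nobs
                r2v = cov * cov / (varx * vary)
            good = (nobs >= 2) & (varx > 0) & (vary > 0)
            for b, r2 in zip(partners[good], r2v[good]):
                rows.append((a + start, b + start, int(pos[b] - pos[a]), float(r2)))
                rows_chrom.append(str(chrom))
    out = pd.DataFrame(rows, columns=["i", "j", "dist_bp", "r2"])
    out.insert(0, "chrom", rows_chrom)
    return out


def r2_adjust(r2, n_samples: int, beta: float = 2.0):
    """Sample-size-corrected LD: r2 - 1/(beta*n), floored at 0.

    beta = 2 for unphased genotype data (the chance correlation of two
    independent dosage vectors has expectation ~ 1/(2n)); beta = 1 for
    haplotype data.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    return np.maximum(np.asarray(r2, dtype=float) - 1.0 / (beta * n_samples), 0.0)


def bin_ld(
    pairs: pd.DataFrame,
    n_samples: int,
    edges_bp: np.ndarray | None = None,
    beta: float = 2.0,
    cm_per_mb: float = 1.0,
    mapping: str = "haldane",
    min_pairs: int = 1,
) -> list[LDBin]:
    """Bin an ld_r2 pair table by physical distance.

    Default edges: 50 log-spaced bins over [50 kb, 10 Mb].  Each bin carries
    the mean raw r2, the sample-size-adjusted mean, the pair count, and the
    recombination fraction of its midpoint under the chosen map function.
    """
    from .ne import physical_to_c

    if edges_bp is None:
        edges_bp = np.geomspace(50_000, 10_000_000, 51)
    edges_bp = np.asarray(edges_bp, dtype=float)
    out: list[LDBin] = []
    d = pairs["dist_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    for lo, hi in zip(edges_bp[:-1], edges_bp[1:]):
        sel = (d >= lo) & (d < hi)
        n = int(sel.sum())
        if n < min_pairs:
            continue
        mean_r2 = float(r2[sel].mean())
        out.append(
            LDBin(
                dist_lo_bp=float(lo),
                dist_hi_bp=float(hi),
                mean_r2=mean_r2,
                mean_r2adj=float(r2_adjust(mean_r2, n_samples, beta)),
                n_pairs=n,
                c_t=physical_to_c(0.5 * (lo + hi), cm_per_mb, mapping),
            )
        )
    return out
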