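"""ROH islands and cold-spots from per-SNP ROH incidence.

The incidence track counts, for every QC-passing SNP, how many individuals
carry at least one ROH spanning its position.  Islands are maximal runs of
consecutive SNPs whose incidence reaches the top-0.5% empirical threshold
(candidate footprints of selection); cold-spots are maximal runs of SNPs
never inside any individual's ROH (candidate high-recombination or balanced
regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomicInterval, VariantMap
from .roh import ROHSet

__all__ = [
    "IncidenceTrack",
    "IslandRegion",
    "snp_roh_incidence",
    "detect_islands",
    "detect_coldspots",
]


@dataclass
class IncidenceTrack:
    counts: np.ndarray  # per-SNP count of individuals with a covering ROH
    n_samples: int
    variants: VariantMap

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n_samples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.variants.chrom,
                "pos_bp": self.variants.pos_bp,
                "count": self.counts,
                "proportion": self.proportions,
            }
        )


@dataclass
class IslandRegion:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    mean_abs_ihs: float | None = None

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start_bp, self.end_bp)


def snp_roh_incidence(rohset: ROHSet, variants: VariantMap, n_samples: int | None = None) -> IncidenceTrack:
    """Count, per SNP, the individuals with >= 1 segment spanning its position.

    Within a sample+chromosome segments are non-overlapping, so summing
    segment coverage never double-counts an individual.
    """
    n_samples = n_samples if n_samples is not None else rohset.n_samples
    counts = np.zeros(len(variants), dtype=np.int64)
    bounds = {str(c): (s, e) for s, e, c in variants.chrom_blocks()}
    for row in rohset.segments.itertuples():
        c = str(row.chrom)
        if c not in bounds:
            continue
        s, e = bounds[c]
        pos = variants.pos_bp[s:e]
        lo = s + int(np.searchsorted(pos, row.start_bp, side="left"))
        hi = s + int(np.searchsorted(pos, row.end_bp, side="right"))
        counts[lo:hi] += 1
    return IncidenceTrack(counts=counts, n_samples=n_samples, variants=variants)


def detect_islands(
    track: IncidenceTrack, top_fraction: float = 0.005
) -> tuple[list[IslandRegion], float]:
    """Merge the top-``top_fraction`` most ROH-covered SNPs into islands.

    The threshold is the empirical order statistic at rank
    ceil((1 - top_fraction) * m) of the per-SNP proportions; every SNP at or
    above it is an island SNP (ties kept, so at least ceil(top_fraction * m)
    SNPs qualify).  Maximal runs of consecutive island SNPs — strict map
    adjacency, no bridging across sub-threshold SNPs — become islands.
    Returns (islands, realized threshold).
    """
    prop = track.proportions
    m = prop.size
    if m == 0:
        raise ValueError("empty incidence track")
    if prop.max() == prop.min():
        raise ValueError("degenerate incidence: all SNPs have equal ROH incidence")
    rank = int(np.ceil((1.0 - top_fraction) * m))
    threshold = float(np.sort(prop)[rank - 1])
    is_island = prop >= threshold
    islands: list[IslandRegion] = []
    for s, e, c in track.variants.chrom_blocks():
        pos = track.variants.pos_bp[s:e]
        mask = is_island[s:e]
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        brk = np.nonzero(np.diff(idx) != 1)[0]
        starts = np.concatenate([[0], brk + 1])
        ends = np.concatenate([brk, [idx.size - 1]])
        for a, b in zip(starts, ends):
            islands.append(
                IslandRegion(
                    chrom=str(c),
                    start_bp=int(pos[idx[a]]),
                    end_bp=int(pos[idx[b]]),
                    n_snps=int(idx[b] - idx[a] + 1),
                )
            )
    return islands, threshold


def detect_coldspots(track: IncidenceTrack) -> pd.DataFrame:
    """Maximal runs of SNPs with zero ROH incidence, sorted by span descending.

    Columns: chrom, start_bp, end_bp, n_snps, span_bp.
    """
    rows = []
    for s, e, c in track.variants.chrom_blocks():
        pos = track.variants.pos_bp[s:e]
        zero = track.counts[s:e] == 0
        idx = np.nonzero(zero)[0]
        if idx.size == 0:
            continue
        brk = np.nonzero(np.diff(idx) != 1)[0]
        starts = np.concatenate([[0], brk + 1])
        ends = np.concatenate([brk, [idx.size - 1]])
        for a, b in zip(starts, ends):
            rows.append(
                {
                    "chrom": str(c),
                    "start_bp": int(pos[idx[a]]),
                    "end_bp": int(pos[idx[b]]),
                    "n_snps": int(idx[b] - idx[a] + 1),
                    "span_bp": int(pos[idx[b]] - pos[idx[a]] + 1),
                }
            )
    out = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "span_bp"])
    return out.sort_values("span_bp", ascending=False).reset_index(drop=True)


def islands_to_frame(islands: list[IslandRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_bp": r.length_bp,
                "mean_abs_ihs": r.mean_abs_ihs,
                "n_snps": r.n_snps,
            }
            for r in islands
        ],
        columns=["chrom", "start_bp", "end_bp", "length_bp", "mean_abs_ihs", "n_snps"],
    )
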