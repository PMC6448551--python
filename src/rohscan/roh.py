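"""Runs-of-homozygosity detection by sliding-window scan.

The caller follows the classic PLINK ``--homozyg`` recipe: slide a 50-SNP
window one SNP at a time; a window is "homozygous" if it contains at most one
heterozygous and five missing calls; a SNP is ROH-eligible if at least 5% of
the windows covering it are homozygous (SNPs near chromosome ends are judged
on the windows that actually exist); maximal runs of eligible SNPs, split at
inter-SNP gaps above 1 Mb, become candidate segments; candidates must contain
at least 100 SNPs, span at least 1 Mb, and average at most 50 kb per SNP.
Segment endpoints are the positions of the first and last eligible SNP.

``call_roh_exact`` re-derives the same definition by direct per-window
enumeration (no vectorized shortcuts) and exists as an independent check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenomicInterval, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ROHParams",
    "ROHSet",
    "call_roh",
    "call_roh_exact",
    "summarize_roh",
    "expected_roh_length",
]

#: length-class edges in Mb: [1, 5), [5, 10), [10, inf)
DEFAULT_CLASS_EDGES_MB: tuple[float, ...] = (1.0, 5.0, 10.0, float("inf"))


@dataclass(frozen=True)
class ROHParams:
    """Scan parameters; the defaults are the PLINK v1.07 ``--homozyg`` defaults."""

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    window_hit_fraction: float = 0.05
    min_snps: int = 100
    min_length_kb: float = 1000.0
    max_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.window_hit_fraction <= 1:
            raise ValueError("window_hit_fraction must lie in (0, 1]")
        for name in (
            "window_snps",
            "min_snps",
            "min_length_kb",
            "max_kb_per_snp",
            "max_gap_kb",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_max_het < 0 or self.window_max_missing < 0:
            raise ValueError("window allowances must be non-negative")


SEGMENT_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp", "length_class"]


@dataclass
class ROHSet:
    """Called segments, one row per segment, with per-sample totals."""

    segments: pd.DataFrame
    n_samples: int
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.segments.columns) != SEGMENT_COLUMNS:
            raise ValueError(f"segment table must have columns {SEGMENT_COLUMNS}")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def per_sample_totals(self) -> pd.DataFrame:
        """count and summed length per sample (zero rows for ROH-free samples)."""
        base = pd.DataFrame(
            {"n_roh": 0, "total_length_bp": 0},
            index=pd.Index(self.samples or sorted(self.segments["sample"].unique()), name="sample"),
        )
        if len(self.segments):
            agg = self.segments.groupby("sample").agg(
                n_roh=("length_bp", "size"), total_length_bp=("length_bp", "sum")
            )
            base.loc[agg.index, :] = agg
        return base

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(str(r.chrom), int(r.start_bp), int(r.end_bp))
            for r in self.segments.itertuples()
        ]

    def to_tsv(self, path: str) -> None:
        self.segments.to_csv(path, sep="\t", index=False)


def length_class_of(length_bp: float, edges_mb=DEFAULT_CLASS_EDGES_MB) -> str:
    mb = length_bp / 1e6
    for lo, hi in zip(edges_mb[:-1], edges_mb[1:]):
        if lo <= mb < hi:
            return f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
    return "<%g" % edges_mb[0]


def _eligible_snps(het: np.ndarray, miss: np.ndarray, p: ROHParams) -> np.ndarray:
    """Vectorized per-SNP eligibility via prefix sums over window verdicts."""
    L = het.size
    W = p.window_snps
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(miss)])
    wh = ch[W:] - ch[:-W]  # het count per window start
    wm = cm[W:] - cm[:-W]
    ok = (wh <= p.window_max_het) & (wm <= p.window_max_missing)
    cok = np.concatenate([[0], np.cumsum(ok)])
    idx = np.arange(L)
    lo = np.maximum(0, idx - W + 1)
    hi = np.minimum(idx, L - W)
    hits = cok[hi + 1] - cok[lo]
    return hits / (hi - lo + 1) >= p.window_hit_fraction


def _runs_to_segments(
    eligible: np.ndarray, pos: np.ndarray, p: ROHParams
) -> list[tuple[int, int, int]]:
    """(start_idx, end_idx, n_snps) for runs passing the gap/count/length/density filters."""
    out = []
    idx = np.nonzero(eligible)[0]
    if idx.size == 0:
        return out
    # break runs at non-consecutive indices or at gaps > max_gap
    gaps = np.diff(idx)
    pos_gaps = np.diff(pos[idx])
    brk = (gaps != 1) | (pos_gaps > p.max_gap_kb * 1000)
    run_starts = np.concatenate([[0], np.nonzero(brk)[0] + 1])
    run_ends = np.concatenate([np.nonzero(brk)[0], [idx.size - 1]])
    for a, b in zip(run_starts, run_ends):
        i, j = int(idx[a]), int(idx[b])
        n = j - i + 1
        length = int(pos[j] - pos[i] + 1)
        if (
            n >= p.min_snps
            and length >= p.min_length_kb * 1000
            and length / n <= p.max_kb_per_snp * 1000
        ):
            out.append((i, j, n))
    return out


def call_roh(ds: GenotypeDataset, params: ROHParams | None = None) -> ROHSet:
    """Detect ROH per individual and chromosome (see module docstring)."""
    p = params or ROHParams()
    rows = []
    for start, stop, chrom in ds.variants.chrom_blocks():
        if stop - start < p.window_snps:
            warnings.warn(
                f"chromosome {chrom}: fewer SNPs ({stop - start}) than the "
                f"window size; skipped",
                stacklevel=2,
            )
            continue
        pos = ds.variants.pos_bp[start:stop]
        block = ds.calls[:, start:stop]
        het_all = block == 1
        miss_all = block == MISSING
        for i, sid in enumerate(ds.samples):
            eligible = _eligible_snps(
                het_all[i].astype(np.int64), miss_all[i].astype(np.int64), p
            )
            for a, b, n in _runs_to_segments(eligible, pos, p):
                length = int(pos[b] - pos[a] + 1)
                rows.append(
                    (sid, str(chrom), int(pos[a]), int(pos[b]), n, length,
                     length_class_of(length))
                )
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return ROHSet(segments=seg, n_samples=ds.n_samples, samples=list(ds.samples))


def call_roh_exact(ds: GenotypeDataset, params: ROHParams | None = None) -> ROHSet:
    """Brute-force re-derivation of :func:`call_roh` (independent check).

    Every window verdict and per-SNP eligibility fraction is computed by
    explicit enumeration; the run/gap/count/length/density filters are applied
    in plain Python.  Output must equal :func:`call_roh` on any input.
    """
    p = params or ROHParams()
    W = p.window_snps
    rows = []
    for start, stop, chrom in ds.variants.chrom_blocks():
        L = stop - start
        if L < W:
            continue
        pos = ds.variants.pos_bp[start:stop]
        for i, sid in enumerate(ds.samples):
            g = ds.calls[i, start:stop]
            window_ok = []
            for s in range(L - W + 1):
                w = g[s : s + W]
                n_het = int(np.count_nonzero(w == 1))
                n_miss = int(np.count_nonzero(w == MISSING))
                window_ok.append(
                    n_het <= p.window_max_het and n_miss <= p.window_max_missing
                )
            eligible = []
            for j in range(L):
                lo = max(0, j - W + 1)
                hi = min(j, L - W)
                wins = window_ok[lo : hi + 1]
                eligible.append(sum(wins) / len(wins) >= p.window_hit_fraction)
            # maximal runs of eligible SNPs, split at large gaps
            runs = []
            run = None
            for j in range(L):
                if eligible[j]:
                    if run is None:
                        run = [j, j]
                    elif pos[j] - pos[run[1]] > p.max_gap_kb * 1000:
                        runs.append(run)
                        run = [j, j]
                    else:
                        run[1] = j
                else:
                    if run is not None:
                        runs.append(run)
                        run = None
            if run is not None:
                runs.append(run)
            for a, b in runs:
                n = b - a + 1
                length = int(pos[b] - pos[a] + 1)
                if n < p.min_snps:
                    continue
                if length < p.min_length_kb * 1000:
                    continue
                if length / n > p.max_kb_per_snp * 1000:
                    continue
                rows.append(
                    (sid, str(chrom), int(pos[a]), int(pos[b]), n, length,
                     length_class_of(length))
                )
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return ROHSet(segments=seg, n_samples=ds.n_samples, samples=list(ds.samples))


def summarize_roh(
    rohset: ROHSet,
    l_auto_bp: float,
    n_samples: int | None = None,
    class_edges_mb=DEFAULT_CLASS_EDGES_MB,
) -> pd.DataFrame:
    """Per-length-class descriptive table.

    Columns: count, pct_of_count (share of all segments), mean_mb, sd_mb, and
    coverage_pct = summed class length / (n_samples * l_auto_bp) * 100 — the
    average fraction of the genome an individual carries in ROH of that class.
    A "Total" row aggregates all classes.
    """
    n_samples = n_samples if n_samples is not None else rohset.n_samples
    seg = rohset.segments
    labels = [
        f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
        for lo, hi in zip(class_edges_mb[:-1], class_edges_mb[1:])
    ]
    total = len(seg)
    rows = []
    for label, lo, hi in zip(labels, class_edges_mb[:-1], class_edges_mb[1:]):
        mb = seg["length_bp"] / 1e6
        sel = seg[(mb >= lo) & (mb < hi)]
        count = len(sel)
        rows.append(
            {
                "length_class": label,
                "count": count,
                "pct_of_count": 100.0 * count / total if total else 0.0,
                "mean_mb": sel["length_bp"].mean() / 1e6 if count else 0.0,
                "sd_mb": sel["length_bp"].std(ddof=1) / 1e6 if count > 1 else 0.0,
                "coverage_pct": 100.0 * sel["length_bp"].sum() / (n_samples * l_auto_bp),
            }
        )
    rows.append(
        {
            "length_class": f"Total (>{class_edges_mb[0]:g})",
            "count": total,
            "pct_of_count": 100.0 if total else 0.0,
            "mean_mb": seg["length_bp"].mean() / 1e6 if total else 0.0,
            "sd_mb": seg["length_bp"].std(ddof=1) / 1e6 if total > 1 else 0.0,
            "coverage_pct": 100.0 * seg["length_bp"].sum() / (n_samples * l_auto_bp),
        }
    )
    return pd.DataFrame(rows).set_index("length_class")


def expected_roh_length(g: float, cm_per_mb: float = 1.0) -> float:
    """Expected ROH length (Mb) for a common ancestor ``g`` generations back.

    An IBD segment inherited from an ancestor g generations ago has expected
    genetic length 1/(2g) Morgan; conversion to Mb uses the constant map
    density ``cm_per_mb``.
    """
    if g <= 0:
        raise ValueError("generations must be positive")
    return 100.0 / (2.0 * g) / cm_per_mb


def segments_from_table(segments: pd.DataFrame, n_samples: int, samples=None) -> ROHSet:
    """Build an :class:`ROHSet` from a bare segment table (adds derived columns)."""
    seg = segments.copy()
    if "length_bp" not in seg:
        seg["length_bp"] = seg["end_bp"] - seg["start_bp"] + 1
    if "n_snps" not in seg:
        seg["n_snps"] = 0
    if "length_class" not in seg:
        seg["length_class"] = [length_class_of(x) for x in seg["length_bp"]]
    return ROHSet(segments=seg[SEGMENT_COLUMNS], n_samples=n_samples,
                  samples=list(samples) if samples is not None else [])
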