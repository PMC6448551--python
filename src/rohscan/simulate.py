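"""Synthetic genotypes with known autozygosity.

The generator emulates a livestock population genotyped at roughly one SNP
per 13.6 kb with MAF >= 0.05: a founder pool with tunable, distance-decaying
linkage disequilibrium; gene-dropping through an arbitrary sire/dam pedigree
with Haldane (no-interference) recombination at a constant cM/Mb rate,
tracking founder-haplotype origin so that true autozygous (IBD) tracts are
known exactly; direct planting of autozygous tracts for calibration; a
planted selective sweep for haplotype-based selection scans; and genotype
noise (missingness, heterozygote-miscall) injection.

It is a transmission simulator, not a coalescent: founder LD comes from a
first-order copying process and there is no mutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, Pedigree, VariantMap

__all__ = [
    "FounderPool",
    "IBDTruth",
    "SweepTruth",
    "make_map",
    "sample_founders",
    "gene_drop",
    "plant_roh",
    "plant_sweep",
    "inject_noise",
    "hwe_genotypes",
    "diploids_from_pool",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class FounderPool:
    """2F x M binary matrix of founder chromosomes plus its frequency model."""

    haplotypes: np.ndarray  # uint8, 2F x M
    freqs: np.ndarray  # target allele-1 frequency per SNP
    rho: float
    variants: VariantMap
    chrom_lengths: dict = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def to_haplotype_set(self):
        from .ihs import HaplotypeSet

        return HaplotypeSet(haps=self.haplotypes.copy(), variants=self.variants)


@dataclass
class IBDTruth:
    """True autozygous tracts per individual.

    ``tracts`` has columns sample, chrom, start_bp, end_bp, origin (founder
    haplotype id, or -1 for planted tracts).  ``f_true`` is the autozygous
    fraction sum(tract length)/l_auto per sample.
    """

    tracts: pd.DataFrame
    f_true: pd.Series
    l_auto_bp: int

    def tracts_of(self, sample: str) -> pd.DataFrame:
        return self.tracts[self.tracts["sample"] == sample]


@dataclass(frozen=True)
class SweepTruth:
    focal_index: int
    carrier_freq: float
    core_half_len_bp: int


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------


def make_map(
    chrom_lengths: dict | list,
    spacing_bp: int = 13_600,
    seed: int | None = None,
    jitter: float = 0.3,
) -> tuple[VariantMap, dict]:
    """Evenly spaced SNP map over the given chromosomes.

    ``chrom_lengths``: dict name -> bp, or list of bp (named "1", "2", ...).
    Positions are laid down every ``spacing_bp`` with optional uniform jitter
    (fraction of the spacing), mirroring a roughly even genome-wide density.
    """
    if isinstance(chrom_lengths, (list, tuple)):
        chrom_lengths = {str(i + 1): int(L) for i, L in enumerate(chrom_lengths)}
    rng = np.random.default_rng(seed)
    chroms, pos, ids, ref, alt = [], [], [], [], []
    for name, L in chrom_lengths.items():
        base = np.arange(spacing_bp // 2, L, spacing_bp, dtype=np.int64)
        if jitter > 0 and seed is not None:
            base = base + rng.integers(
                -int(spacing_bp * jitter / 2), int(spacing_bp * jitter / 2) + 1, base.size
            )
            base = np.sort(base)
            base = base[(base >= 1) & (base <= L)]
            base = base[np.concatenate([[True], np.diff(base) > 0])]
        chroms.extend([str(name)] * base.size)
        pos.extend(base.tolist())
        ids.extend(f"snp_{name}_{k}" for k in range(base.size))
        ref.extend(["A"] * base.size)
        alt.extend(["G"] * base.size)
    vmap = VariantMap(
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        ids=np.array(ids, dtype=object),
        ref_allele=np.array(ref, dtype=object),
        alt_allele=np.array(alt, dtype=object),
        anc_allele=np.array(["A"] * len(pos), dtype=object),
    )
    return vmap, {str(k): int(v) for k, v in chrom_lengths.items()}


# ---------------------------------------------------------------------------
# founder pool
# ---------------------------------------------------------------------------


def sample_founders(
    n_founders: int,
    vmap: VariantMap,
    maf_range: tuple[float, float] = (0.05, 0.5),
    rho: float = 0.0,
    seed: int | None = None,
    chrom_lengths: dict | None = None,
) -> FounderPool:
    """Draw 2*n_founders haplotypes with first-order copying LD.

    Per-SNP allele-1 frequencies are uniform in ``maf_range``.  Within a
    chromosome, each haplotype copies its previous SNP's allele with
    probability ``rho`` and otherwise draws fresh from the site frequency,
    giving adjacent-site correlation ~ rho that decays geometrically with SNP
    separation.  Columns whose realized minor-allele frequency falls outside
    ``maf_range`` are repaired by flipping the minimal number of random
    alleles to the nearest bound (keeps the declared MAF floor exact with a
    minimal LD perturbation).
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    m = len(vmap)
    H = 2 * n_founders
    freqs = rng.uniform(lo, hi, size=m)
    haps = np.empty((H, m), dtype=np.uint8)
    for start, stop, _ in vmap.chrom_blocks():
        haps[:, start] = rng.random(H) < freqs[start]
        for j in range(start + 1, stop):
            fresh = (rng.random(H) < freqs[j]).astype(np.uint8)
            copy = rng.random(H) < rho
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    _repair_maf(haps, lo, hi, rng)
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(vmap.pos_bp[stop - 1]) for start, stop, c in vmap.chrom_blocks()
        }
    return FounderPool(
        haplotypes=haps, freqs=freqs, rho=rho, variants=vmap, chrom_lengths=chrom_lengths
    )


def _repair_maf(haps: np.ndarray, lo: float, hi: float, rng) -> None:
    H = haps.shape[0]
    lo_count = int(np.ceil(lo * H))
    hi_count = int(np.floor(hi * H))
    ones = haps.sum(axis=0)
    minor = np.minimum(ones, H - ones)
    for j in np.nonzero((minor < lo_count) | (minor > hi_count))[0]:
        c1 = int(ones[j])
        minor_allele = 1 if c1 <= H - c1 else 0
        n_minor = min(c1, H - c1)
        target = min(max(n_minor, lo_count), hi_count)
        delta = target - n_minor
        if delta > 0:  # flip majority alleles to the minor allele
            idx = np.nonzero(haps[:, j] != minor_allele)[0]
            haps[rng.choice(idx, size=delta, replace=False), j] = minor_allele
        elif delta < 0:
            idx = np.nonzero(haps[:, j] == minor_allele)[0]
            haps[rng.choice(idx, size=-delta, replace=False), j] = 1 - minor_allele


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def _splice(segs_a, segs_b, breaks, start_on_a):
    """Recombine two origin-segment lists at the given breakpoints.

    A segment list is [(start_bp, origin), ...] sorted, implicitly ending at
    the chromosome end.  Crossovers switch the copied parent haplotype.
    """
    sources = (segs_a, segs_b)
    cur = 0 if start_on_a else 1
    out = []
    prev = 1
    for brk in list(breaks) + [None]:
        src = sources[cur]
        # copy src's origins over [prev, brk)
        k = 0
        for k in range(len(src)):
            if k + 1 == len(src) or src[k + 1][0] > prev:
                break
        while k < len(src) and (brk is None or src[k][0] < brk):
            seg_start = max(src[k][0], prev)
            origin = src[k][1]
            if out and out[-1][1] == origin:
                pass  # merge with previous
            else:
                out.append((seg_start, origin))
            k += 1
        if brk is None:
            break
        prev = brk
        cur = 1 - cur
    return out


def _meiosis(hap_pair, chrom_len_bp, cm_per_mb, rng):
    length_morgan = chrom_len_bp * cm_per_mb / 1e8
    n_x = rng.poisson(length_morgan)
    breaks = np.sort(rng.uniform(1, chrom_len_bp, size=n_x)) if n_x else []
    return _splice(hap_pair[0], hap_pair[1], breaks, rng.integers(2) == 0)


def gene_drop(
    ped: Pedigree,
    pool: FounderPool,
    cm_per_mb: float = 1.0,
    seed: int | None = None,
) -> tuple[GenotypeDataset, IBDTruth]:
    """Drop founder haplotypes through a pedigree with recombination.

    Each founder receives two pool haplotypes; each transmission recombines
    with a Poisson number of crossovers (Haldane, no interference) placed
    uniformly on the genetic map (constant ``cm_per_mb``).  Founder-haplotype
    origin is tracked per segment; true autozygous tracts are the maximal
    runs where an individual's two chromosome copies descend from the same
    founder haplotype.  Genotypes are the sums of the carried alleles.
    """
    if len(ped) == 0:
        raise ValueError("empty pedigree")
    founders = ped.founders()
    if 2 * len(founders) > pool.n_haplotypes:
        raise ValueError(
            f"pedigree has {len(founders)} founders but pool only "
            f"{pool.n_haplotypes // 2} founder slots"
        )
    rng = np.random.default_rng(seed)
    vmap = pool.variants
    blocks = vmap.chrom_blocks()
    chrom_len = {
        str(c): pool.chrom_lengths.get(str(c), int(vmap.pos_bp[stop - 1]))
        for start, stop, c in blocks
    }
    l_auto = int(sum(chrom_len.values()))

    # per individual, per chromosome: two origin-segment lists
    genomes: dict[str, dict[str, tuple[list, list]]] = {}
    next_hap = 0
    for iid in ped.order:
        sire, dam = ped.parents(iid)
        per_chrom: dict[str, tuple[list, list]] = {}
        if sire is None and dam is None:
            h1, h2 = next_hap, next_hap + 1
            next_hap += 2
            for _, _, c in blocks:
                per_chrom[str(c)] = ([(1, h1)], [(1, h2)])
        else:
            for _, _, c in blocks:
                c = str(c)
                L = chrom_len[c]
                gam = []
                for parent in (sire, dam):
                    if parent is None:
                        # unknown parent: fresh founder haplotype, no recombination
                        gam.append([(1, next_hap)])
                        next_hap += 1
                    else:
                        gam.append(_meiosis(genomes[parent][c], L, cm_per_mb, rng))
                per_chrom[c] = (gam[0], gam[1])
        genomes[iid] = per_chrom
    if next_hap > pool.n_haplotypes:
        raise ValueError("founder pool exhausted (unknown parents need extra haplotypes)")

    samples = list(ped.order)
    calls = np.zeros((len(samples), len(vmap)), dtype=np.int8)
    tract_rows = []
    f_true = {}
    for i, iid in enumerate(samples):
        total_ibd = 0
        for start, stop, c in blocks:
            c = str(c)
            L = chrom_len[c]
            pos = vmap.pos_bp[start:stop]
            g1, g2 = genomes[iid][c]
            for segs in (g1, g2):
                starts = np.array([s for s, _ in segs], dtype=np.int64)
                origins = np.array([o for _, o in segs], dtype=np.int64)
                which = np.searchsorted(starts, pos, side="right") - 1
                ori = origins[which]
                calls[i, start:stop] += pool.haplotypes[
                    ori, np.arange(start, stop)
                ].astype(np.int8)
            # IBD tracts: merge the two segment lists, find equal-origin runs
            cuts = sorted(
                {1, L + 1}
                | {s for s, _ in g1}
                | {s for s, _ in g2}
            )
            s1 = np.array([s for s, _ in g1])
            o1 = np.array([o for _, o in g1])
            s2 = np.array([s for s, _ in g2])
            o2 = np.array([o for _, o in g2])
            run_start = None
            for k in range(len(cuts) - 1):
                a, b = cuts[k], cuts[k + 1] - 1
                ori1 = o1[np.searchsorted(s1, a, side="right") - 1]
                ori2 = o2[np.searchsorted(s2, a, side="right") - 1]
                if ori1 == ori2:
                    if run_start is None:
                        run_start = (a, int(ori1))
                    elif run_start[1] != ori1:
                        tract_rows.append((iid, c, run_start[0], a - 1, run_start[1]))
                        total_ibd += a - run_start[0]
                        run_start = (a, int(ori1))
                else:
                    if run_start is not None:
                        tract_rows.append((iid, c, run_start[0], a - 1, run_start[1]))
                        total_ibd += a - run_start[0]
                        run_start = None
            if run_start is not None:
                tract_rows.append((iid, c, run_start[0], L, run_start[1]))
                total_ibd += L - run_start[0] + 1
        f_true[iid] = total_ibd / l_auto

    ds = GenotypeDataset(
        samples=samples, variants=vmap, calls=calls, l_auto_override_bp=max(l_auto, vmap.span_bp())
    )
    truth = IBDTruth(
        tracts=pd.DataFrame(
            tract_rows, columns=["sample", "chrom", "start_bp", "end_bp", "origin"]
        ),
        f_true=pd.Series(f_true, name="f_true"),
        l_auto_bp=l_auto,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# direct tract planting
# ---------------------------------------------------------------------------


def plant_roh(
    ds: GenotypeDataset,
    fraction: float,
    length_dist: tuple[float, str] = (4.11, "exponential"),
    seed: int | None = None,
    min_length_mb: float = 1.0,
) -> tuple[GenotypeDataset, IBDTruth]:
    """Plant autozygous tracts into an existing genotype matrix.

    Per individual, non-overlapping tracts are drawn (length in Mb from
    ``length_dist``: ``(mean, "exponential"|"fixed")``, truncated below at
    ``min_length_mb``) and placed at random SNP positions until the summed
    tract length reaches ``fraction * l_auto``; the final tract is clipped to
    the remaining deficit (not below the minimum) so the realized fraction
    tracks the target.  Inside a tract every site is made homozygous by
    collapsing the genotype onto one randomly drawn allele per heterozygous
    site (equivalent to copying one of the individual's haplotypes under
    random phase).  Tract boundaries are the first/last SNP positions.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    mean_mb, dist = length_dist
    rng = np.random.default_rng(seed)
    vmap = ds.variants
    blocks = vmap.chrom_blocks()
    l_auto = ds.l_auto_bp
    calls = ds.calls.copy()
    tract_rows = []
    f_true = {}
    min_bp = min_length_mb * 1e6
    shortest = min(2, vmap.__len__())
    for i, sid in enumerate(ds.samples):
        target = fraction * l_auto
        if fraction > 0 and target < min_bp and target < 2 * 13_600:
            warnings.warn(f"target autozygous length below shortest placeable tract "
                          f"for sample {sid}; no tracts planted", stacklevel=2)
            f_true[sid] = 0.0
            continue
        if fraction >= 1.0:
            # whole-genome autozygosity: one tract per chromosome
            placed = 0
            for start, stop, c in blocks:
                pos = vmap.pos_bp
                seg = calls[i, start:stop]
                het = np.nonzero(seg == 1)[0]
                seg[het] = 2 * (rng.random(het.size) < 0.5).astype(np.int8)
                tract_rows.append(
                    (sid, str(c), int(pos[start]), int(pos[stop - 1]), -1)
                )
                placed += int(pos[stop - 1] - pos[start] + 1)
            f_true[sid] = placed / l_auto
            continue
        placed = 0
        free = {  # per chrom: list of free [lo, hi] SNP-index intervals
            str(c): [(start, stop - 1)] for start, stop, c in blocks
        }
        bounds = {str(c): (start, stop) for start, stop, c in blocks}
        attempts = 0
        while placed < target and attempts < 10_000:
            attempts += 1
            if target - placed < 0.5 * min_bp:
                break  # stopping here beats overshooting by a full minimum tract
            gaps = [
                (c, lo, hi)
                for c, ivs in free.items()
                for lo, hi in ivs
                if hi - lo + 1 >= shortest
            ]
            if not gaps:
                break
            weights = np.array([hi - lo + 1 for _, lo, hi in gaps], dtype=float)
            c, lo, hi = gaps[rng.choice(len(gaps), p=weights / weights.sum())]
            if dist == "exponential":
                want_bp = max(rng.exponential(mean_mb) * 1e6, min_bp)
            elif dist == "fixed":
                want_bp = mean_mb * 1e6
            else:
                raise ValueError(f"unknown length distribution {dist!r}")
            want_bp = max(min(want_bp, target - placed), min_bp)
            start_idx = int(rng.integers(lo, hi))  # leave room for >=2 SNPs
            pos = vmap.pos_bp
            bstart, bstop = bounds[c]
            end_idx = bstart + int(
                np.searchsorted(
                    pos[bstart:bstop], pos[start_idx] + want_bp, side="right"
                )
                - 1
            )
            end_idx = max(min(end_idx, hi), start_idx + 1)
            length = int(pos[end_idx] - pos[start_idx] + 1)
            if length < min_bp:
                continue  # gap or chromosome end too tight for a legal tract
            # homozygose the tract
            seg = calls[i, start_idx : end_idx + 1]
            het = np.nonzero(seg == 1)[0]
            seg[het] = 2 * (rng.random(het.size) < 0.5).astype(np.int8)
            tract_rows.append(
                (sid, c, int(pos[start_idx]), int(pos[end_idx]), -1)
            )
            placed += length
            # shrink the free interval
            new = []
            for flo, fhi in free[c]:
                if fhi < start_idx or flo > end_idx:
                    new.append((flo, fhi))
                else:
                    if flo <= start_idx - 1:
                        new.append((flo, start_idx - 1))
                    if end_idx + 1 <= fhi:
                        new.append((end_idx + 1, fhi))
            free[c] = new
        f_true[sid] = placed / l_auto
    out = GenotypeDataset(
        samples=list(ds.samples),
        variants=vmap,
        calls=calls,
        l_auto_override_bp=ds.l_auto_override_bp,
    )
    truth = IBDTruth(
        tracts=pd.DataFrame(
            tract_rows, columns=["sample", "chrom", "start_bp", "end_bp", "origin"]
        ),
        f_true=pd.Series(f_true, name="f_true"),
        l_auto_bp=l_auto,
    )
    return out, truth


# ---------------------------------------------------------------------------
# sweep + noise
# ---------------------------------------------------------------------------


def plant_sweep(
    pool: FounderPool,
    focal: int,
    carrier_freq: float,
    core_half_len_bp: int,
    seed: int | None = None,
) -> tuple[FounderPool, SweepTruth]:
    """Overwrite a fraction of haplotypes with one shared core around ``focal``.

    Carriers receive the derived allele (1) at the focal SNP and a copy of a
    single template haplotype over +/- ``core_half_len_bp``, producing the
    extended-homozygosity footprint of a recent sweep.
    """
    if not 0 < carrier_freq < 1:
        raise ValueError("carrier_freq must lie in (0, 1)")
    vmap = pool.variants
    if not 0 <= focal < len(vmap):
        raise ValueError("focal index outside the map")
    rng = np.random.default_rng(seed)
    haps = pool.haplotypes.copy()
    H = haps.shape[0]
    n_car = max(2, int(round(carrier_freq * H)))
    carriers = rng.choice(H, size=n_car, replace=False)
    block = next(
        (s, e) for s, e, c in vmap.chrom_blocks() if s <= focal < e
    )
    pos = vmap.pos_bp
    lo = int(np.searchsorted(pos[block[0]:block[1]], pos[focal] - core_half_len_bp) + block[0])
    hi = int(
        np.searchsorted(pos[block[0]:block[1]], pos[focal] + core_half_len_bp, side="right")
        + block[0]
    )
    template = haps[carriers[0], lo:hi].copy()
    haps[:, focal] = 0
    haps[np.ix_(carriers, np.arange(lo, hi))] = template
    haps[carriers, focal] = 1
    new_pool = FounderPool(
        haplotypes=haps,
        freqs=pool.freqs,
        rho=pool.rho,
        variants=vmap,
        chrom_lengths=dict(pool.chrom_lengths),
    )
    return new_pool, SweepTruth(focal, carrier_freq, core_half_len_bp)


def inject_noise(
    ds: GenotypeDataset,
    miss_rate: float = 0.0,
    het_error_rate: float = 0.0,
    seed: int | None = None,
) -> GenotypeDataset:
    """Independently set calls missing and flip homozygotes to heterozygotes."""
    rng = np.random.default_rng(seed)
    calls = ds.calls.copy()
    if het_error_rate > 0:
        hom = (calls == 0) | (calls == 2)
        flip = hom & (rng.random(calls.shape) < het_error_rate)
        calls[flip] = 1
    if miss_rate > 0:
        calls[rng.random(calls.shape) < miss_rate] = MISSING
    return GenotypeDataset(
        samples=list(ds.samples),
        variants=ds.variants,
        calls=calls,
        l_auto_override_bp=ds.l_auto_override_bp,
    )


def diploids_from_pool(
    pool: FounderPool, n_individuals: int, seed: int | None = None
) -> GenotypeDataset:
    """Pair distinct random pool haplotypes into diploid genotypes.

    Random union of gametes from the founder pool — the non-inbred base
    population downstream stages start from.
    """
    rng = np.random.default_rng(seed)
    H = pool.n_haplotypes
    picks = np.array(
        [rng.choice(H, size=2, replace=False) for _ in range(n_individuals)]
    )
    calls = (
        pool.haplotypes[picks[:, 0], :].astype(np.int8)
        + pool.haplotypes[picks[:, 1], :].astype(np.int8)
    )
    return GenotypeDataset(
        samples=[f"ind{i}" for i in range(n_individuals)],
        variants=pool.variants,
        calls=calls,
        l_auto_override_bp=max(
            sum(pool.chrom_lengths.values()), pool.variants.span_bp()
        )
        if pool.chrom_lengths
        else None,
    )


def hwe_genotypes(
    n_samples: int,
    vmap: VariantMap,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
    l_auto_bp: int | None = None,
) -> GenotypeDataset:
    """Unlinked Hardy-Weinberg genotypes — the null background for calibration."""
    rng = np.random.default_rng(seed)
    m = len(vmap)
    p = rng.uniform(*maf_range, size=m)
    calls = (
        (rng.random((n_samples, m)) < p).astype(np.int8)
        + (rng.random((n_samples, m)) < p).astype(np.int8)
    )
    return GenotypeDataset(
        samples=[f"ind{i}" for i in range(n_samples)],
        variants=vmap,
        calls=calls,
        l_auto_override_bp=l_auto_bp,
    )
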