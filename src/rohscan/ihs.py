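"""Extended haplotype homozygosity and the integrated haplotype score (iHS).

EHH at distance x from a core SNP is the probability that two randomly drawn
carriers of a core allele are identical over the whole stretch from the core
to x.  iHH is the trapezoidal integral of the EHH curve over genetic
distance, truncated where EHH falls below a cutoff (default 0.05, with linear
interpolation to the crossing).  The raw score ln(iHH_ancestral/iHH_derived)
is standardized to mean 0 / sd 1 within derived-allele-frequency bins, and
converted to a -log10 two-sided normal p-value:

    p_iHS = -log10(1 - 2 |Phi(iHS) - 0.5|)

Scores with |iHS| above Phi^-1(1 - p/2) (2.81 at p = 0.005) flag putative
selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import VariantMap
from .islands import IslandRegion, IncidenceTrack

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeSet",
    "IHSResult",
    "ehh",
    "ihs_scan",
    "p_ihs_from_score",
    "significance_threshold",
    "island_ihs_summary",
]


@dataclass
class HaplotypeSet:
    """2n x m binary matrix of phased alleles (1 = the map's ALT allele)."""

    haps: np.ndarray
    variants: VariantMap
    samples: list[str] | None = None

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        if self.haps.shape[1] != len(self.variants):
            raise ValueError("haplotype column count does not match the map")
        if not np.isin(self.haps, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]


@dataclass
class IHSResult:
    """Per-SNP scan results.

    ``table`` columns: chrom, pos_bp, index, daf, ihh_a, ihh_d, ihs_raw,
    ihs_std, p_ihs, flag ('' | 'truncated' | 'skipped').
    """

    table: pd.DataFrame

    def scored(self) -> pd.DataFrame:
        return self.table[self.table["ihs_std"].notna()]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_phased_vcf(path: str) -> HaplotypeSet:
    """Read a fully phased VCF into a 2n x m haplotype matrix.

    Every genotype must be phased ('|' separator) and biallelic; haplotype
    rows 2i and 2i+1 belong to sample i.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = []
    chroms, pos, ids, ref, alt, anc = [], [], [], [], [], []
    any_anc = False
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS}")
        g = np.asarray(v.genotypes, dtype=np.int64)  # n x 3: a0, a1, phased
        if not g[:, 2].all():
            raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}")
        if (g[:, :2] < 0).any():
            raise ValueError(f"missing call in phased input at {v.CHROM}:{v.POS}")
        cols.append(g[:, :2].reshape(-1))
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0])
        aa = v.INFO.get("AA")
        anc.append(aa)
        any_anc = any_anc or aa is not None
    vcf.close()
    vmap = VariantMap(
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        ids=np.array(ids, dtype=object),
        ref_allele=np.array(ref, dtype=object),
        alt_allele=np.array(alt, dtype=object),
        anc_allele=np.array(anc, dtype=object) if any_anc else None,
    )
    haps = (
        np.column_stack(cols).astype(np.uint8)
        if cols
        else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    )
    return HaplotypeSet(haps=haps, variants=vmap, samples=samples)


def write_phased_vcf(haps: HaplotypeSet, path: str) -> None:
    """Write a HaplotypeSet as a minimal phased VCF 4.2."""
    vmap = haps.variants
    n = haps.n_haplotypes // 2
    samples = haps.samples or [f"ind{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if vmap.anc_allele is not None:
            fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for _, _, c in vmap.chrom_blocks():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(len(vmap)):
            info = "."
            if vmap.anc_allele is not None and vmap.anc_allele[j] is not None:
                info = f"AA={vmap.anc_allele[j]}"
            gts = "\t".join(
                f"{haps.haps[2 * i, j]}|{haps.haps[2 * i + 1, j]}" for i in range(n)
            )
            fh.write(
                f"{vmap.chrom[j]}\t{vmap.pos_bp[j]}\t{vmap.ids[j]}\t"
                f"{vmap.ref_allele[j]}\t{vmap.alt_allele[j]}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def _ehh_side(
    haps: np.ndarray,
    carriers: np.ndarray,
    core: int,
    block: tuple[int, int],
    step: int,
    cutoff: float,
):
    """Walk outward from the core; yields (index, ehh); returns truncation flag.

    Haplotype classes are refined one SNP at a time; EHH is the fraction of
    carrier pairs still in the same class.
    """
    n_c = carriers.size
    denom = n_c * (n_c - 1) / 2.0
    labels = np.zeros(n_c, dtype=np.int64)
    out = [(core, 1.0)]
    j = core + step
    lo, hi = block
    truncated = True  # stays True if we hit the chromosome end above cutoff
    while lo <= j < hi:
        pair = labels * 2 + haps[carriers, j]
        _, labels = np.unique(pair, return_inverse=True)
        counts = np.bincount(labels)
        ehh_j = float((counts * (counts - 1) / 2.0).sum() / denom)
        out.append((j, ehh_j))
        if ehh_j < cutoff:
            truncated = False
            break
        j += step
    return out, truncated


def ehh(
    haps: HaplotypeSet,
    core_snp: int,
    core_allele: int,
    ehh_cutoff: float = 0.05,
) -> dict:
    """EHH decay curve around a core SNP for carriers of ``core_allele``.

    Returns {"index", "pos_bp", "ehh", "truncated"}; positions are ordered
    along the chromosome with the core included once.  Raises if the core
    allele has fewer than 2 carriers.
    """
    vmap = haps.variants
    block = next(
        ((s, e) for s, e, _ in vmap.chrom_blocks() if s <= core_snp < e), None
    )
    if block is None:
        raise IndexError(f"core SNP {core_snp} outside the map")
    carriers = np.nonzero(haps.haps[:, core_snp] == core_allele)[0]
    if carriers.size < 2:
        raise ValueError(
            f"core allele {core_allele} at SNP {core_snp} has <2 carriers"
        )
    left, trunc_l = _ehh_side(haps.haps, carriers, core_snp, block, -1, ehh_cutoff)
    right, trunc_r = _ehh_side(haps.haps, carriers, core_snp, block, +1, ehh_cutoff)
    pts = sorted(set(left) | set(right))
    index = np.array([i for i, _ in pts])
    return {
        "index": index,
        "pos_bp": vmap.pos_bp[index],
        "ehh": np.array([e for _, e in pts]),
        "truncated": trunc_l or trunc_r,
    }


def _ihh_side(
    haps: np.ndarray,
    carriers: np.ndarray,
    core: int,
    block: tuple[int, int],
    step: int,
    cutoff: float,
    pos_morgan: np.ndarray,
) -> tuple[float, bool]:
    """Integrated EHH on one side: trapezoids down to the cutoff crossing."""
    pts, truncated = _ehh_side(haps, carriers, core, block, step, cutoff)
    total = 0.0
    for (i0, e0), (i1, e1) in zip(pts[:-1], pts[1:]):
        d = abs(pos_morgan[i1] - pos_morgan[i0])
        if e1 >= cutoff:
            total += 0.5 * (e0 + e1) * d
        else:
            # partial trapezoid down to the interpolated cutoff crossing
            frac = (e0 - cutoff) / (e0 - e1) if e0 > e1 else 0.0
            total += 0.5 * (e0 + cutoff) * d * frac
            break
    return total, truncated


def ihs_scan(
    haps: HaplotypeSet,
    maf_min: float = 0.05,
    bin_width: float = 0.05,
    cm_per_mb: float = 1.0,
    ehh_cutoff: float = 0.05,
    keep_truncated: bool = False,
    min_bin_size: int = 10,
) -> IHSResult:
    """Genome scan of the standardized integrated haplotype score.

    The ancestral allele comes from the map's ``anc_allele`` column; if it is
    absent the major allele is used as ancestral with a loud warning.  SNPs
    with derived-allele frequency outside [maf_min, 1 - maf_min] are skipped;
    SNPs whose EHH curve reaches a chromosome end above the cutoff are
    flagged 'truncated' and excluded unless ``keep_truncated``.
    Standardization subtracts the mean and divides by the sd of the raw score
    within derived-allele-frequency bins of width ``bin_width`` (bins with
    fewer than ``min_bin_size`` scored SNPs are left unstandardized/NaN).
    """
    vmap = haps.variants
    H = haps.haps
    m = len(vmap)
    pos_morgan = vmap.pos_bp * cm_per_mb / 1e8

    if vmap.anc_allele is not None:
        anc_is_alt = np.array(
            [a == vmap.alt_allele[j] for j, a in enumerate(vmap.anc_allele)]
        )
    else:
        warnings.warn(
            "no ancestral-allele annotation: falling back to the major allele "
            "as ancestral — iHS signs are unreliable",
            stacklevel=2,
        )
        anc_is_alt = H.mean(axis=0) > 0.5

    freq_alt = H.mean(axis=0)
    daf = np.where(anc_is_alt, 1.0 - freq_alt, freq_alt)

    blocks = vmap.chrom_blocks()
    block_of = np.empty(m, dtype=object)
    for s, e, _ in blocks:
        for j in range(s, e):
            block_of[j] = (s, e)

    rows = []
    for j in range(m):
        d = daf[j]
        if not maf_min <= d <= 1.0 - maf_min:
            rows.append((j, d, np.nan, np.nan, np.nan, "skipped"))
            continue
        anc_val = 1 if anc_is_alt[j] else 0
        der_val = 1 - anc_val
        blk = block_of[j]
        res = {}
        truncated = False
        failed = False
        for name, allele in (("a", anc_val), ("d", der_val)):
            carriers = np.nonzero(H[:, j] == allele)[0]
            if carriers.size < 2:
                failed = True
                break
            l_int, tl = _ihh_side(H, carriers, j, blk, -1, ehh_cutoff, pos_morgan)
            r_int, tr = _ihh_side(H, carriers, j, blk, +1, ehh_cutoff, pos_morgan)
            res[name] = l_int + r_int
            truncated = truncated or tl or tr
        if failed or res["d"] <= 0 or res["a"] <= 0:
            rows.append((j, d, res.get("a", np.nan), res.get("d", np.nan),
                         np.nan, "skipped"))
            continue
        raw = float(np.log(res["a"] / res["d"]))
        flag = "truncated" if truncated else ""
        rows.append((j, d, res["a"], res["d"], raw, flag))

    table = pd.DataFrame(
        rows, columns=["index", "daf", "ihh_a", "ihh_d", "ihs_raw", "flag"]
    )
    table.insert(0, "pos_bp", vmap.pos_bp[table["index"]])
    table.insert(0, "chrom", vmap.chrom[table["index"]])

    # within-bin standardization over the usable scores
    usable = table["ihs_raw"].notna() & (
        (table["flag"] == "") | (keep_truncated & (table["flag"] == "truncated"))
    )
    table["ihs_std"] = np.nan
    bins = np.floor(table["daf"] / bin_width).clip(upper=int(1 / bin_width) - 1)
    for _, idx in table[usable].groupby(bins[usable]).groups.items():
        vals = table.loc[idx, "ihs_raw"]
        if len(idx) < max(min_bin_size, 2) or vals.std(ddof=0) == 0:
            continue
        table.loc[idx, "ihs_std"] = (vals - vals.mean()) / vals.std(ddof=0)
    table["p_ihs"] = p_ihs_from_score(table["ihs_std"].to_numpy())
    return IHSResult(table=table)


def p_ihs_from_score(score):
    """p_iHS = -log10(1 - 2|Phi(score) - 0.5|), the -log10 two-sided p-value.

    Evaluated as -log10(2 Phi(-|score|)) — algebraically identical but free
    of the catastrophic cancellation the literal form suffers for |score| > 5.
    """
    score = np.asarray(score, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return -np.log10(2.0 * norm.sf(np.abs(score)))


def significance_threshold(p_two_sided: float) -> float:
    """|score| threshold for a two-sided normal p-value: Phi^-1(1 - p/2)."""
    if not 0 < p_two_sided <= 1:
        raise ValueError("p must lie in (0, 1]")
    return float(norm.ppf(1.0 - p_two_sided / 2.0))


def island_ihs_summary(
    islands: list[IslandRegion],
    result: IHSResult,
    track: IncidenceTrack | None = None,
) -> tuple[list[IslandRegion], float | None]:
    """Fill each island's mean |iHS| and correlate incidence with |iHS|.

    The mean is over scored SNPs inside the island (NaN if none).  If an
    incidence track is given, also returns the Pearson correlation between
    per-SNP ROH incidence and |standardized iHS| over jointly defined SNPs.
    """
    tab = result.table
    for isl in islands:
        sel = tab[
            (tab["chrom"].astype(str) == isl.chrom)
            & (tab["pos_bp"] >= isl.start_bp)
            & (tab["pos_bp"] <= isl.end_bp)
            & tab["ihs_std"].notna()
        ]
        isl.mean_abs_ihs = float(sel["ihs_std"].abs().mean()) if len(sel) else np.nan
    r = None
    if track is not None:
        abs_ihs = np.full(len(track.variants), np.nan)
        abs_ihs[tab["index"].to_numpy()] = np.abs(tab["ihs_std"].to_numpy())
        ok = ~np.isnan(abs_ihs)
        if ok.sum() >= 3 and np.std(track.proportions[ok]) > 0:
            r = float(np.corrcoef(track.proportions[ok], abs_ihs[ok])[0, 1])
    return islands, r
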