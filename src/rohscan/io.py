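"""Genotype, map, pedigree and interval I/O plus marker QC.

Genotypes are held as a samples x variants matrix of counted-allele copies
(0, 1, 2; ``MISSING`` = -1), with a physical map of 1-based positions.  The
counted allele is the ALT allele for VCF input.  All interval coordinates are
1-based inclusive internally; BED export shifts to 0-based half-open.
"""

from __future__ import annotations

import graphlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING: int = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantMap:
    """Physical map of biallelic markers.

    Positions must be strictly increasing within each chromosome and
    chromosomes must form contiguous blocks (file order).
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    ids: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    anc_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        if self.anc_allele is not None:
            self.anc_allele = np.asarray(self.anc_allele, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.pos_bp)
        for arr in (self.chrom, self.ids, self.ref_allele, self.alt_allele):
            if len(arr) != n:
                raise ValueError("VariantMap field lengths disagree")
        seen: dict[object, int] = {}
        for start, stop, c in self.chrom_blocks():
            if c in seen:
                raise ValueError(f"chromosome {c} appears in non-contiguous blocks")
            seen[c] = start
            pos = self.pos_bp[start:stop]
            if np.any(np.diff(pos) <= 0):
                bad = start + int(np.nonzero(np.diff(pos) <= 0)[0][0]) + 1
                raise ValueError(
                    f"positions not strictly increasing at {self.chrom[bad]}:{self.pos_bp[bad]}"
                )

    def __len__(self) -> int:
        return len(self.pos_bp)

    def chrom_blocks(self) -> list[tuple[int, int, object]]:
        """(start, stop, chrom) index ranges, one per chromosome, in file order."""
        out: list[tuple[int, int, object]] = []
        n = len(self.pos_bp)
        i = 0
        while i < n:
            c = self.chrom[i]
            j = i
            while j < n and self.chrom[j] == c:
                j += 1
            out.append((i, j, c))
            i = j
        return out

    def chromosomes(self) -> list[object]:
        return [c for _, _, c in self.chrom_blocks()]

    def span_bp(self) -> int:
        """Sum over chromosomes of (max pos - min pos + 1)."""
        return int(
            sum(
                self.pos_bp[stop - 1] - self.pos_bp[start] + 1
                for start, stop, _ in self.chrom_blocks()
            )
        )

    def take(self, idx: np.ndarray) -> "VariantMap":
        return VariantMap(
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            ids=self.ids[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            anc_allele=None if self.anc_allele is None else self.anc_allele[idx],
        )


@dataclass
class GenotypeDataset:
    """Samples x variants matrix of counted-allele copies with its map.

    ``calls[i, j]`` is the number of copies of the counted (ALT) allele that
    sample ``i`` carries at variant ``j``: 0, 1, 2 or ``MISSING``.
    ``l_auto_bp`` is the mapped autosome length used as the denominator of
    ROH-based inbreeding; it defaults to the SNP-covered span but is
    overridable (studies often quote a fixed genome length instead).
    """

    samples: list[str]
    variants: VariantMap
    calls: np.ndarray
    l_auto_override_bp: int | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1, 2 or MISSING")
        if self.l_auto_override_bp is not None and self.l_auto_override_bp < self.variants.span_bp():
            raise ValueError("l_auto_bp smaller than the SNP-covered span")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def l_auto_bp(self) -> int:
        if self.l_auto_override_bp is not None:
            return self.l_auto_override_bp
        return self.variants.span_bp()

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per variant, from non-missing calls only.

        Variants with no non-missing calls get NaN.
        """
        calls = self.calls
        obs = calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def take_variants(self, idx: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            samples=list(self.samples),
            variants=self.variants.take(idx),
            calls=self.calls[:, idx],
            l_auto_override_bp=self.l_auto_override_bp,
        )


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, inclusive interval."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"start {self.start_bp} > end {self.end_bp}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class Pedigree:
    """Sire/dam pedigree stored in topological order (parents first).

    ``records`` maps id -> (sire, dam); an unknown parent is ``None``.
    """

    records: dict[str, tuple[str | None, str | None]]
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.order:
            self.order = self._toposort()
        self._index = {iid: k for k, iid in enumerate(self.order)}

    def _toposort(self) -> list[str]:
        graph = {
            iid: [p for p in parents if p is not None]
            for iid, parents in self.records.items()
        }
        try:
            return list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            cycle = exc.args[1]
            raise ValueError(f"pedigree contains a cycle: {' -> '.join(map(str, cycle))}")

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        return self.records[iid]

    def founders(self) -> list[str]:
        return [i for i in self.order if self.records[i] == (None, None)]

    def depth_index(self, iid: str) -> int:
        return self._index[iid]

    def __contains__(self, iid: str) -> bool:
        return iid in self.records

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_vcf(path: str, skip_multiallelic: bool = False) -> GenotypeDataset:
    """Read a VCF (GT field required, biallelic records) into a dataset.

    Calls are coded as ALT-allele counts.  Multiallelic records raise unless
    ``skip_multiallelic``; unsorted positions always raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    pos: list[int] = []
    ids: list[str] = []
    ref: list[str] = []
    alt: list[str] = []
    anc: list[object] = []
    rows: list[np.ndarray] = []
    any_anc = False
    for v in vcf:
        if len(v.ALT) != 1:
            if skip_multiallelic:
                continue
            raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0])
        aa = v.INFO.get("AA")
        anc.append(aa)
        any_anc = any_anc or aa is not None
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    vcf.close()

    vmap_kwargs = dict(
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        ids=np.array(ids, dtype=object),
        ref_allele=np.array(ref, dtype=object),
        alt_allele=np.array(alt, dtype=object),
        anc_allele=np.array(anc, dtype=object) if any_anc else None,
    )
    try:
        vmap = VariantMap(**vmap_kwargs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    calls = (
        np.asarray(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeDataset(samples=samples, variants=vmap, calls=calls)


def write_vcf(ds: GenotypeDataset, path: str) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes (and AA INFO if known)."""
    vmap = ds.variants
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if vmap.anc_allele is not None:
            fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for _, _, c in vmap.chrom_blocks():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.samples) + "\n")
        for j in range(ds.n_variants):
            info = "."
            if vmap.anc_allele is not None and vmap.anc_allele[j] is not None:
                info = f"AA={vmap.anc_allele[j]}"
            fields = [
                str(vmap.chrom[j]),
                str(vmap.pos_bp[j]),
                str(vmap.ids[j]),
                str(vmap.ref_allele[j]),
                str(vmap.alt_allele[j]),
                ".",
                ".",
                info,
                "GT",
            ]
            fields.extend(gt_strings[int(g)] for g in ds.calls[:, j])
            fh.write("\t".join(fields) + "\n")


def read_plink_text(
    ped_path: str,
    map_path: str,
    counted_alleles: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Read PLINK 1.x text PED/MAP.

    The counted allele defaults to the first-listed alternate per site: the
    first non-missing allele symbol encountered at a site is treated as the
    reference (count 0) and the first differing symbol as the counted
    alternate.  Pass ``counted_alleles`` to pin the coding (e.g. for
    cross-format agreement with a VCF).
    """
    chroms: list[str] = []
    ids: list[str] = []
    pos: list[int] = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"MAP line with <4 columns: {line!r}")
            chroms.append(parts[0])
            ids.append(parts[1])
            pos.append(int(parts[3]))
    m = len(pos)

    samples: list[str] = []
    pairs_per_sample: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED sample {parts[1] if len(parts) > 1 else '?'}: "
                    f"expected {2 * m} allele columns, got {len(parts) - 6}"
                )
            samples.append(parts[1])
            pairs_per_sample.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
            )

    n = len(samples)
    ref = [None] * m
    alt = [None] * m
    if counted_alleles is not None:
        alt = list(counted_alleles)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        for i in range(n):
            a, b = pairs_per_sample[i][j]
            if a == "0" or b == "0":
                continue
            for al in (a, b):
                if counted_alleles is None:
                    if ref[j] is None:
                        ref[j] = al
                    elif alt[j] is None and al != ref[j]:
                        alt[j] = al
                elif ref[j] is None and al != alt[j]:
                    ref[j] = al
            calls[i, j] = (a == alt[j]) + (b == alt[j]) if alt[j] is not None else 0
        if ref[j] is None:
            ref[j] = "A"  # site entirely missing
        if alt[j] is None:
            alt[j] = "B"  # monomorphic site: placeholder alternate

    vmap = VariantMap(
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        ids=np.array(ids, dtype=object),
        ref_allele=np.array(ref, dtype=object),
        alt_allele=np.array(alt, dtype=object),
    )
    return GenotypeDataset(samples=samples, variants=vmap, calls=calls)


def write_plink_text(ds: GenotypeDataset, ped_path: str, map_path: str) -> None:
    """Write PLINK 1.x text PED/MAP (genetic distance column set to 0)."""
    vmap = ds.variants
    with open(map_path, "w") as fh:
        for j in range(ds.n_variants):
            fh.write(f"{vmap.chrom[j]}\t{vmap.ids[j]}\t0\t{vmap.pos_bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.samples):
            fields = ["FAM", sid, "0", "0", "0", "-9"]
            for j in range(ds.n_variants):
                g = int(ds.calls[i, j])
                r, a = vmap.ref_allele[j], vmap.alt_allele[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [r, r]
                elif g == 1:
                    fields += [r, a]
                else:
                    fields += [a, a]
            fh.write(" ".join(map(str, fields)) + "\n")


def read_pedigree(path: str) -> Pedigree:
    """Read a 3+ column id/sire/dam table (CSV, TSV or whitespace).

    Unknown parents are coded ``0`` or empty.  Parents referenced but not
    listed are auto-added as founders with a warning.
    """
    records: dict[str, tuple[str | None, str | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = "," if "," in line else ("\t" if "\t" in line else None)
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            if lineno == 1 and parts[0].lower() in ("id", "iid", "animal"):
                continue
            iid, sire, dam = parts[0], parts[1], parts[2]
            records[iid] = (
                None if sire in ("0", "") else sire,
                None if dam in ("0", "") else dam,
            )
    referenced = {
        p for parents in records.values() for p in parents if p is not None
    }
    for p in sorted(referenced - set(records)):
        warnings.warn(f"parent {p} not listed; added as founder", stacklevel=2)
        records[p] = (None, None)
    return Pedigree(records=records)


def write_pedigree(ped: Pedigree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id,sire,dam\n")
        for iid in ped.order:
            s, d = ped.records[iid]
            fh.write(f"{iid},{s or 0},{d or 0}\n")


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    """BED3 export: 1-based inclusive -> 0-based half-open."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0] in ("track", "browser"):
                continue
            out.append(
                GenomicInterval(parts[0], int(parts[1]) + 1, int(parts[2]))
            )
    return out


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_kept: int
    n_dropped_maf: int
    n_dropped_call_rate: int
    n_dropped_chrom: int
    sample_call_rate: np.ndarray


def filter_variants(
    ds: GenotypeDataset,
    maf_min: float = 0.05,
    sample_genotyped_min: float = 0.30,
    autosomes: set | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Marker QC: MAF >= maf_min, call rate > sample_genotyped_min, autosomes only.

    The genotyped threshold is applied per variant (fraction of samples with a
    call, strictly greater than the threshold); a per-sample call-rate vector
    is returned in the report for inspection.  Returns the filtered dataset
    and a :class:`QCReport` of kept/dropped counts.
    """
    if not (0 <= maf_min <= 1 and 0 <= sample_genotyped_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    maf = ds.maf()
    rate = ds.call_rate()
    with np.errstate(invalid="ignore"):
        ok_maf = np.nan_to_num(maf, nan=-1.0) >= maf_min
    ok_rate = rate > sample_genotyped_min
    if autosomes is None:
        ok_chrom = np.ones(ds.n_variants, dtype=bool)
    else:
        auto = {str(c) for c in autosomes}
        ok_chrom = np.array([str(c) in auto for c in ds.variants.chrom])
    keep = ok_maf & ok_rate & ok_chrom
    report = QCReport(
        n_input=ds.n_variants,
        n_kept=int(keep.sum()),
        n_dropped_maf=int((~ok_maf & ok_rate & ok_chrom).sum()),
        n_dropped_call_rate=int((~ok_rate & ok_chrom).sum()),
        n_dropped_chrom=int((~ok_chrom).sum()),
        sample_call_rate=ds.sample_call_rate(),
    )
    if report.n_kept == 0:
        warnings.warn("QC removed every variant", stacklevel=2)
    logger.info(
        "QC: kept %d/%d variants (MAF drop %d, call-rate drop %d, chrom drop %d)",
        report.n_kept,
        report.n_input,
        report.n_dropped_maf,
        report.n_dropped_call_rate,
        report.n_dropped_chrom,
    )
    out = ds.take_variants(np.nonzero(keep)[0])
    return out, report
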