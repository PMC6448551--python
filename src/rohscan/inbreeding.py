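"""Pedigree and genomic inbreeding coefficients.

Four families of estimators are provided:

* ``f_ped`` — the classical pedigree inbreeding coefficient, F(x) =
  kinship(sire, dam), computed by the recursive (tabular) kinship method
  with memoization.
* ``f_roh`` — the fraction of the mapped autosome covered by ROH,
  F_ROH = L_ROH / L_auto, optionally restricted to a segment length class
  (longer classes reflect more recent common ancestors).
* ``f_snp`` — three marker-by-marker estimators relative to current-sample
  allele frequencies: variance of additive genotypes (1), excess homozygosity
  (2), and correlation of uniting gametes (3).  With Y the counted-allele
  dosage, p the sample frequency and h = 2p(1-p):

      F1 = (1/n) sum (Y - 2p)^2 / h  -  1
      F2 = 1 - (1/n) sum Y(2 - Y) / h
      F3 = (1/n) sum [Y^2 - Y(1 + 2p) + 2 p^2] / h

  These are centered on the current population, so they can be negative.
"""

from __future__ import annotations

import sys
import warnings

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, Pedigree
from .roh import ROHSet

__all__ = [
    "kinship",
    "f_ped",
    "f_ped_all",
    "f_roh",
    "f_roh_all",
    "f_snp",
    "inbreeding_table",
    "inbreeding_correlations",
    "COEFFICIENT_COLUMNS",
]

COEFFICIENT_COLUMNS = [
    "f_ped",
    "f_roh_1_5",
    "f_roh_5_10",
    "f_roh_gt10",
    "f_roh_all",
    "f_snp1",
    "f_snp2",
    "f_snp3",
]


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


class KinshipCalculator:
    """Memoized recursive kinship over a pedigree.

    kinship(a, a) = (1 + F(a)) / 2 with F(a) = kinship(sire_a, dam_a);
    kinship(a, b) descends the younger individual:
    kinship(a, b) = [kinship(sire_a, b) + kinship(dam_a, b)] / 2.
    An unknown parent contributes 0 (founders unrelated and non-inbred).
    """

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if self.ped.depth_index(a) < self.ped.depth_index(b):
            a, b = b, a  # a is the younger (larger depth index)
        key = (a, b)
        if key in self._cache:
            return self._cache[key]
        sire, dam = self.ped.parents(a)
        if a == b:
            val = 0.5 * (1.0 + self(sire, dam))
        else:
            val = 0.5 * (self(sire, b) + self(dam, b))
        self._cache[key] = val
        return val


def kinship(ped: Pedigree, a: str, b: str) -> float:
    for iid in (a, b):
        if iid not in ped:
            raise KeyError(f"{iid} not in pedigree")
    return KinshipCalculator(ped)(a, b)


def f_ped(ped: Pedigree, iid: str, _calc: KinshipCalculator | None = None) -> float:
    """Pedigree inbreeding coefficient = kinship of the parents."""
    if iid not in ped:
        raise KeyError(f"{iid} not in pedigree")
    calc = _calc or KinshipCalculator(ped)
    sire, dam = ped.parents(iid)
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(ped) + 100))
    try:
        return calc(sire, dam)
    finally:
        sys.setrecursionlimit(old)


def f_ped_all(ped: Pedigree) -> pd.Series:
    calc = KinshipCalculator(ped)
    return pd.Series(
        {iid: f_ped(ped, iid, _calc=calc) for iid in ped.order}, name="f_ped"
    )


# ---------------------------------------------------------------------------
# ROH-based
# ---------------------------------------------------------------------------


def f_roh(
    rohset: ROHSet,
    sample: str,
    l_auto_bp: float,
    length_class_mb: tuple[float, float] | None = None,
) -> float:
    """F_ROH = summed ROH length / mapped autosome length.

    ``length_class_mb=(lo, hi)`` restricts to segments with lo <= Mb < hi.
    """
    seg = rohset.segments
    seg = seg[seg["sample"] == sample]
    if length_class_mb is not None:
        mb = seg["length_bp"] / 1e6
        seg = seg[(mb >= length_class_mb[0]) & (mb < length_class_mb[1])]
    return float(seg["length_bp"].sum() / l_auto_bp)


def f_roh_all(rohset: ROHSet, l_auto_bp: float, samples: list[str]) -> pd.DataFrame:
    """Per-sample F_ROH by length class plus the all-lengths total."""
    seg = rohset.segments
    mb = seg["length_bp"] / 1e6
    out = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for col, lo, hi in [
        ("f_roh_1_5", 1.0, 5.0),
        ("f_roh_5_10", 5.0, 10.0),
        ("f_roh_gt10", 10.0, np.inf),
    ]:
        sums = seg[(mb >= lo) & (mb < hi)].groupby("sample")["length_bp"].sum()
        out[col] = sums.reindex(samples).fillna(0).to_numpy() / l_auto_bp
    out["f_roh_all"] = out[["f_roh_1_5", "f_roh_5_10", "f_roh_gt10"]].sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# SNP-by-SNP
# ---------------------------------------------------------------------------


def f_snp(ds: GenotypeDataset, estimator: int) -> pd.Series:
    """One of the three marker-based estimators (see module docstring).

    Allele frequencies come from the current sample; monomorphic SNPs (h = 0)
    are excluded; per sample, missing calls are skipped and n reduced
    accordingly.  A sample with zero usable SNPs gets NaN with a warning.
    """
    if estimator not in (1, 2, 3):
        raise ValueError("estimator must be 1, 2 or 3")
    p = ds.allele_freq()
    with np.errstate(invalid="ignore"):
        poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    p = p[poly]
    h = 2.0 * p * (1.0 - p)
    Y = ds.calls[:, poly].astype(np.float64)
    obs = Y != MISSING
    Y = np.where(obs, Y, 0.0)
    if estimator == 1:
        term = (Y - 2.0 * p) ** 2 / h
        offset = -1.0
        sign = 1.0
    elif estimator == 2:
        term = Y * (2.0 - Y) / h
        offset = 1.0
        sign = -1.0
    else:
        term = (Y**2 - Y * (1.0 + 2.0 * p) + 2.0 * p**2) / h
        offset = 0.0
        sign = 1.0
    term = np.where(obs, term, 0.0)
    n = obs.sum(axis=1).astype(np.float64)
    empty = n == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} sample(s) have no usable SNPs; F_SNP undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = offset + sign * term.sum(axis=1) / n
    vals = np.where(empty, np.nan, vals)
    return pd.Series(vals, index=pd.Index(ds.samples, name="sample"),
                     name=f"f_snp{estimator}")


# ---------------------------------------------------------------------------
# combined table + correlations
# ---------------------------------------------------------------------------


def inbreeding_table(
    ds: GenotypeDataset,
    rohset: ROHSet,
    ped: Pedigree | None = None,
    l_auto_bp: float | None = None,
) -> pd.DataFrame:
    """One row per sample with all eight coefficients.

    ``f_ped`` is NaN for samples absent from the pedigree (or when no
    pedigree is given).
    """
    l_auto = l_auto_bp if l_auto_bp is not None else ds.l_auto_bp
    out = f_roh_all(rohset, l_auto, ds.samples)
    if ped is not None:
        calc = KinshipCalculator(ped)
        out.insert(
            0,
            "f_ped",
            [f_ped(ped, s, _calc=calc) if s in ped else np.nan for s in ds.samples],
        )
    else:
        out.insert(0, "f_ped", np.nan)
    for k in (1, 2, 3):
        out[f"f_snp{k}"] = f_snp(ds, k).to_numpy()
    return out[COEFFICIENT_COLUMNS]


def inbreeding_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the coefficient columns.

    Computed over samples with complete values in every retained column;
    all-NaN columns (e.g. no pedigree) are dropped first.
    """
    cols = [c for c in table.columns if table[c].notna().any()]
    complete = table[cols].dropna()
    corr = complete.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)  # constant columns: off-diagonals stay NaN
    return corr


def summary_stats(table: pd.DataFrame) -> pd.DataFrame:
    """mean / min / max / sd / n per coefficient column."""
    return pd.DataFrame(
        {
            "mean": table.mean(),
            "min": table.min(),
            "max": table.max(),
            "sd": table.std(ddof=1),
            "n": table.notna().sum(),
        }
    )
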