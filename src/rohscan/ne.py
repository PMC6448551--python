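"""Historical effective population size from LD decay.

Under drift-recombination equilibrium the expected adjusted LD between loci
at recombination fraction c is E[r2_adj] = 1 / (alpha + 4 Ne c), so each
distance bin yields a point estimate

    Ne(t) = (4 c)^-1 (1 / mean_r2adj - alpha),      t = 1 / (2 c)

generations ago, with alpha = 1 for pure drift (2 or 2.2 adding a mutation
correction).  Recombination fractions come from physical distance through a
map function (Haldane by default) at a constant cM/Mb rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import LDBin

__all__ = ["NeTrajectory", "physical_to_c", "ne_trajectory", "expected_r2_drift"]


def physical_to_c(d_bp: float, cm_per_mb: float = 1.0, mapping: str = "haldane") -> float:
    """Recombination fraction for a physical distance.

    Genetic distance d = d_bp * cm_per_mb / 1e8 Morgan; then
    haldane: c = (1 - exp(-2d))/2;  sved: c = d/(1 + 2d) (hyperbolic
    approximation);  linear: c = min(d, 0.5).
    """
    if d_bp < 0:
        raise ValueError("distance must be non-negative")
    d = d_bp * cm_per_mb / 1e8
    if mapping == "haldane":
        return 0.5 * (1.0 - math.exp(-2.0 * d))
    if mapping == "sved":
        return d / (1.0 + 2.0 * d)
    if mapping == "linear":
        return min(d, 0.5)
    raise ValueError(f"unknown mapping {mapping!r}")


@dataclass
class NeTrajectory:
    """Per-bin Ne estimates; ``table`` columns: t_gen, ne, c_t, mean_r2adj, n_pairs, defined."""

    table: pd.DataFrame

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def ne_trajectory(
    bins: list[LDBin],
    alpha: float = 1.0,
    min_pairs: int = 50,
) -> NeTrajectory:
    """Point-estimate Ne per LD bin (see module docstring).

    Bins with fewer than ``min_pairs`` pairs are dropped; bins whose adjusted
    LD is <= 1/alpha's reciprocal bound (non-positive Ne) are kept but flagged
    undefined.
    """
    usable = [b for b in bins if b.n_pairs >= min_pairs]
    if not usable:
        raise ValueError("no LD bins with enough pairs")
    rows = []
    for b in usable:
        c = b.c_t
        t = 1.0 / (2.0 * c)
        if b.mean_r2adj > 0:
            ne = (1.0 / b.mean_r2adj - alpha) / (4.0 * c)
        else:
            ne = np.nan
        rows.append(
            {
                "t_gen": t,
                "ne": ne if (not np.isnan(ne) and ne > 0) else np.nan,
                "c_t": c,
                "mean_r2adj": b.mean_r2adj,
                "n_pairs": b.n_pairs,
                "defined": bool(not np.isnan(ne) and ne > 0),
            }
        )
    table = pd.DataFrame(rows).sort_values("t_gen").reset_index(drop=True)
    return NeTrajectory(table=table)


def expected_r2_drift(n_e: float, c: float, alpha: float = 1.0) -> float:
    """Sved's drift-recombination expectation E[r2_adj] = 1/(alpha + 4 Ne c)."""
    if n_e <= 0 or not 0 < c <= 0.5:
        raise ValueError("need n_e > 0 and c in (0, 0.5]")
    return 1.0 / (alpha + 4.0 * n_e * c)
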