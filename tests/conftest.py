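import numpy as np
import pytest

import rohscan as rs
from rohscan.io import GenotypeDataset, Pedigree, VariantMap


def simple_map(n_snps: int, spacing_bp: int = 13_600, chrom: str = "1") -> VariantMap:
    """Evenly spaced single-chromosome map with A/G alleles (A ancestral)."""
    pos = np.arange(1, n_snps + 1, dtype=np.int64) * spacing_bp
    return VariantMap(
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos_bp=pos,
        ids=np.array([f"snp{i}" for i in range(n_snps)], dtype=object),
        ref_allele=np.array(["A"] * n_snps, dtype=object),
        alt_allele=np.array(["G"] * n_snps, dtype=object),
        anc_allele=np.array(["A"] * n_snps, dtype=object),
    )


def dataset_from_calls(calls, spacing_bp: int = 13_600, chrom: str = "1") -> GenotypeDataset:
    calls = np.asarray(calls, dtype=np.int8)
    vmap = simple_map(calls.shape[1], spacing_bp, chrom)
    return GenotypeDataset(
        samples=[f"s{i}" for i in range(calls.shape[0])],
        variants=vmap,
        calls=calls,
    )


@pytest.fixture(scope="session")
def small_pool():
    vmap, cl = rs.make_map({"1": 20_000_000, "2": 20_000_000}, seed=101)
    return rs.sample_founders(30, vmap, rho=0.8, seed=102, chrom_lengths=cl)


@pytest.fixture(scope="session")
def planted_dataset(small_pool):
    """50 diploids with ~15% planted autozygosity plus the truth."""
    from rohscan.pipeline import _diploids_from_pool

    base = _diploids_from_pool(small_pool, 50, seed=103)
    return rs.plant_roh(base, 0.15, (4.11, "exponential"), seed=104)


@pytest.fixture
def fullsib_pedigree():
    return Pedigree(
        {
            "A": (None, None),
            "B": (None, None),
            "C": ("A", "B"),
            "D": ("A", "B"),
            "X": ("C", "D"),
        }
    )
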