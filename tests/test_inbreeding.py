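import numpy as np
import pandas as pd
import pytest

import rohscan as rs
from rohscan.io import GenotypeDataset, Pedigree
from rohscan.inbreeding import (
    f_ped,
    f_roh,
    f_roh_all,
    f_snp,
    inbreeding_correlations,
    inbreeding_table,
    kinship,
)
from rohscan.roh import segments_from_table
from rohscan.pipeline import _diploids_from_pool

from conftest import dataset_from_calls, simple_map


def mc_inbreeding(ped: Pedigree, iid: str, n_rep: int, seed: int) -> float:
    """Single-locus allele-drop estimate of F — an oracle independent of the
    kinship recursion: drop labelled founder alleles through the pedigree and
    count how often the target receives two copies of the same founder allele."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        alleles: dict[str, tuple[int, int]] = {}
        counter = 0
        for x in ped.order:
            sire, dam = ped.parents(x)
            pair = []
            for parent in (sire, dam):
                if parent is None:
                    pair.append(counter)
                    counter += 1
                else:
                    pair.append(alleles[parent][rng.integers(2)])
            alleles[x] = (pair[0], pair[1])
        hits += alleles[iid][0] == alleles[iid][1]
    return hits / n_rep


class TestFPed:
    def test_founder_zero(self, fullsib_pedigree):
        assert f_ped(fullsib_pedigree, "A") == 0.0

    def test_fullsib_quarter(self, fullsib_pedigree):
        assert f_ped(fullsib_pedigree, "X") == 0.25

    def test_halfsib_and_parent_offspring(self):
        ped = Pedigree(
            {
                "A": (None, None),
                "B": (None, None),
                "C": (None, None),
                "H1": ("A", "B"),
                "H2": ("A", "C"),
                "Y": ("H1", "H2"),
                "Z": ("A", "H1"),
            }
        )
        assert f_ped(ped, "Y") == 0.125
        assert f_ped(ped, "Z") == 0.25

    def test_against_allele_drop_oracle(self):
        """Recursive kinship agrees with Monte-Carlo gene dropping on a
        pedigree with overlapping loops."""
        ped = Pedigree(
            {
                "A": (None, None),
                "B": (None, None),
                "C": ("A", "B"),
                "D": ("A", "B"),
                "E": ("C", "D"),
                "F": ("C", "D"),
                "G": ("E", "F"),
            }
        )
        for iid in ("E", "G"):
            mc = mc_inbreeding(ped, iid, n_rep=20000, seed=3)
            assert f_ped(ped, iid) == pytest.approx(mc, abs=0.015)

    def test_missing_id_error(self, fullsib_pedigree):
        with pytest.raises(KeyError):
            f_ped(fullsib_pedigree, "nope")

    def test_kinship_symmetry(self, fullsib_pedigree):
        assert kinship(fullsib_pedigree, "C", "D") == kinship(fullsib_pedigree, "D", "C")


class TestFRoh:
    def make_rohset(self, rows):
        seg = pd.DataFrame(rows, columns=["sample", "chrom", "start_bp", "end_bp"])
        return segments_from_table(seg, n_samples=2, samples=["s0", "s1"])

    def test_no_segments_zero(self):
        rohset = self.make_rohset([])
        assert f_roh(rohset, "s0", 1e8) == 0.0

    def test_whole_genome_one(self):
        rohset = self.make_rohset([("s0", "1", 1, 100_000_000)])
        assert f_roh(rohset, "s0", 1e8) == pytest.approx(1.0)

    def test_class_additivity_exact(self, planted_dataset):
        """f_roh_all equals the sum of its three class parts to the bit."""
        ds, _ = planted_dataset
        rohset = rs.call_roh(ds)
        tab = f_roh_all(rohset, ds.l_auto_bp, ds.samples)
        total = tab["f_roh_1_5"] + tab["f_roh_5_10"] + tab["f_roh_gt10"]
        assert (tab["f_roh_all"] == total).all()

    def test_length_class_restriction(self):
        rohset = self.make_rohset(
            [("s0", "1", 1, 2_000_000), ("s0", "1", 3_000_000, 9_999_999)]
        )
        assert f_roh(rohset, "s0", 1e8, (1.0, 5.0)) == pytest.approx(0.02)
        assert f_roh(rohset, "s0", 1e8, (5.0, 10.0)) == pytest.approx(0.07)


class TestFSnp:
    def test_fully_homozygous_sample_fsnp2_one(self):
        calls = np.array([[0, 2, 2, 0], [0, 1, 1, 2], [1, 1, 0, 2]], dtype=np.int8)
        ds = dataset_from_calls(calls)
        vals = f_snp(ds, 2)
        assert vals["s0"] == pytest.approx(1.0)

    def test_per_snp_terms_at_half_frequency(self):
        """A heterozygote at p = 0.5 contributes 0 / -1 / -1 to the three sums."""
        # two samples [1, 1] at every SNP -> p = 0.5 exactly, all terms identical
        calls = np.ones((2, 4), dtype=np.int8)
        ds = dataset_from_calls(calls)
        assert f_snp(ds, 1).iloc[0] == pytest.approx((1 - 1) ** 2 / 0.5 - 1 + 1 - 1)  # 0 - 1... see below
        # spelled out: F1 = mean((Y-2p)^2/h) - 1 = 0/0.5 - 1 = -1
        assert f_snp(ds, 1).iloc[0] == pytest.approx(-1.0)
        assert f_snp(ds, 2).iloc[0] == pytest.approx(1 - (1 * 1) / 0.5)  # -1
        assert f_snp(ds, 3).iloc[0] == pytest.approx((1 - 2 + 0.5) / 0.5)  # -1

    def test_against_direct_per_sample_recompute(self):
        """Vectorized estimators match a naive per-sample loop."""
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(20, 60)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = rs.MISSING
        ds = dataset_from_calls(calls)
        p = ds.allele_freq()
        for est in (1, 2, 3):
            got = f_snp(ds, est)
            for i in range(20):
                terms = []
                for j in range(60):
                    y = calls[i, j]
                    pj = p[j]
                    if y == rs.MISSING or pj in (0.0, 1.0):
                        continue
                    h = 2 * pj * (1 - pj)
                    if est == 1:
                        terms.append((y - 2 * pj) ** 2 / h)
                    elif est == 2:
                        terms.append(y * (2 - y) / h)
                    else:
                        terms.append((y * y - y * (1 + 2 * pj) + 2 * pj * pj) / h)
                expect = {
                    1: np.mean(terms) - 1,
                    2: 1 - np.mean(terms),
                    3: np.mean(terms),
                }[est]
                assert got.iloc[i] == pytest.approx(expect)

    def test_hwe_null_means(self):
        """Under random mating all three estimators average ~0."""
        ds = rs.hwe_genotypes(500, simple_map(5000), seed=77)
        for est in (1, 2, 3):
            assert abs(f_snp(ds, est).mean()) <= 0.01

    def test_invalid_estimator(self):
        ds = dataset_from_calls(np.array([[0, 1], [1, 2]], dtype=np.int8))
        with pytest.raises(ValueError):
            f_snp(ds, 4)


class TestCorrelations:
    def test_matrix_shape_symmetry_diagonal(self, planted_dataset):
        ds, _ = planted_dataset
        rohset = rs.call_roh(ds)
        table = inbreeding_table(ds, rohset)
        corr = inbreeding_correlations(table)
        assert np.allclose(corr, corr.T, equal_nan=True)
        assert np.allclose(np.diag(corr), 1.0)
        assert "f_ped" not in corr.columns  # all-NaN without a pedigree

    def test_homozygosity_estimators_track_froh(self, small_pool):
        """The homozygosity-driven estimators (F_SNP2, and F_SNP3 which mixes
        in the same signal) track F_ROH far better than the additive-variance
        estimator F_SNP1 when the inbreeding signal is planted homozygosity."""
        base = _diploids_from_pool(small_pool, 60, seed=41)
        rng = np.random.default_rng(42)
        parts = []
        truths = []
        for k, frac in enumerate((0.02, 0.1, 0.2, 0.35)):
            sub = GenotypeDataset(
                samples=[f"g{k}_{s}" for s in base.samples[: 15]],
                variants=base.variants,
                calls=base.calls[:15],
                l_auto_override_bp=base.l_auto_override_bp,
            )
            ds_k, tr = rs.plant_roh(sub, frac, seed=43 + k)
            parts.append(ds_k)
            truths.append(tr)
        calls = np.vstack([d.calls for d in parts])
        samples = sum((d.samples for d in parts), [])
        ds = GenotypeDataset(samples=samples, variants=base.variants, calls=calls,
                             l_auto_override_bp=base.l_auto_override_bp)
        rohset = rs.call_roh(ds)
        table = inbreeding_table(ds, rohset)
        corr = inbreeding_correlations(table)
        r1 = corr.loc["f_snp1", "f_roh_all"]
        r2 = corr.loc["f_snp2", "f_roh_all"]
        r3 = corr.loc["f_snp3", "f_roh_all"]
        assert r2 > 0.8
        assert r2 > r1
        assert r3 > r1

    def test_recovery_correlation_with_truth(self, small_pool):
        """r(f_true, f_roh_all) >= 0.9 across a spread of planted fractions."""
        fts, frs = [], []
        for k, frac in enumerate((0.05, 0.15, 0.30)):
            base = _diploids_from_pool(small_pool, 20, seed=50 + k)
            ds, truth = rs.plant_roh(base, frac, seed=60 + k)
            rohset = rs.call_roh(ds)
            fr = f_roh_all(rohset, ds.l_auto_bp, ds.samples)["f_roh_all"]
            fts += list(truth.f_true[ds.samples])
            frs += list(fr)
        r = np.corrcoef(fts, frs)[0, 1]
        assert r >= 0.9
        slope = np.polyfit(fts, frs, 1)[0]
        assert 0.8 <= slope <= 1.1
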