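import numpy as np
import pytest

import rohscan as rs
from rohscan.io import MISSING, Pedigree
from rohscan.pipeline import _diploids_from_pool

from conftest import simple_map


class TestSampleFounders:
    def test_deterministic_under_seed(self):
        vmap = simple_map(500)
        a = rs.sample_founders(10, vmap, rho=0.5, seed=7)
        b = rs.sample_founders(10, vmap, rho=0.5, seed=7)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_too_few_founders(self):
        with pytest.raises(ValueError, match="founders"):
            rs.sample_founders(1, simple_map(10))

    def test_maf_bounds_respected(self):
        vmap = simple_map(2000)
        pool = rs.sample_founders(25, vmap, maf_range=(0.1, 0.4), rho=0.7, seed=3)
        f = pool.haplotypes.mean(axis=0)
        maf = np.minimum(f, 1 - f)
        assert maf.min() >= 0.1 - 1e-12
        assert maf.max() <= 0.4 + 1.0 / pool.n_haplotypes  # integer rounding slack

    def test_rho_zero_independent_sites(self):
        """Without copying, adjacent sites are uncorrelated."""
        vmap = simple_map(5000)
        pool = rs.sample_founders(50, vmap, rho=0.0, seed=11)
        h = pool.haplotypes.astype(float)
        rr = [
            np.corrcoef(h[:, j], h[:, j + 1])[0, 1]
            for j in range(0, 4999, 5)
        ]
        assert abs(np.mean(rr)) < 0.05

    def test_ld_decays_with_distance(self):
        """rho = 0.95: adjacent-pair r2 far exceeds r2 at 100-SNP separation."""
        vmap = simple_map(3000)
        pool = rs.sample_founders(50, vmap, rho=0.95, seed=13)
        h = pool.haplotypes.astype(float)

        def mean_r2(sep):
            vals = []
            for j in range(0, 3000 - sep, 17):
                r = np.corrcoef(h[:, j], h[:, j + sep])[0, 1]
                if not np.isnan(r):
                    vals.append(r * r)
            return np.mean(vals)

        assert mean_r2(1) > mean_r2(100)


class TestGeneDrop:
    def test_offspring_of_unrelated_founders(self):
        vmap = simple_map(200, spacing_bp=100_000)
        pool = rs.sample_founders(2, vmap, seed=1)
        ped = Pedigree({"A": (None, None), "B": (None, None), "C": ("A", "B")})
        _, truth = rs.gene_drop(ped, pool, seed=2)
        assert truth.f_true["C"] == 0.0

    def test_empty_pedigree(self):
        vmap = simple_map(10)
        pool = rs.sample_founders(2, vmap, seed=1)
        with pytest.raises(ValueError, match="empty"):
            rs.gene_drop(Pedigree({}), pool)

    def test_selfing_expectation(self):
        """Selfed offspring on a 1 Morgan chromosome: E[f_true] = 0.5."""
        vmap, cl = rs.make_map({"1": 100_000_000}, spacing_bp=500_000, seed=5)
        pool = rs.sample_founders(2, vmap, seed=6, chrom_lengths=cl)
        ped = Pedigree({"A": (None, None), "S": ("A", "A")})
        fs = [rs.gene_drop(ped, pool, seed=r)[1].f_true["S"] for r in range(500)]
        assert abs(np.mean(fs) - 0.5) < 0.03

    def test_fullsib_expectation(self, fullsib_pedigree):
        """Full-sib offspring: E[f_true] = 0.25 (classical F)."""
        vmap, cl = rs.make_map({"1": 100_000_000}, spacing_bp=500_000, seed=5)
        pool = rs.sample_founders(4, vmap, seed=6, chrom_lengths=cl)
        fs = [
            rs.gene_drop(fullsib_pedigree, pool, seed=r)[1].f_true["X"]
            for r in range(500)
        ]
        assert abs(np.mean(fs) - 0.25) < 0.03

    def test_truth_sites_homozygous(self, fullsib_pedigree):
        """Every SNP inside a true autozygous tract is homozygous."""
        vmap, cl = rs.make_map({"1": 50_000_000, "2": 50_000_000}, seed=21)
        pool = rs.sample_founders(4, vmap, rho=0.5, seed=22, chrom_lengths=cl)
        ds, truth = rs.gene_drop(fullsib_pedigree, pool, seed=23)
        for row in truth.tracts.itertuples():
            i = ds.samples.index(row.sample)
            blk = next(
                b for b in ds.variants.chrom_blocks() if str(b[2]) == str(row.chrom)
            )
            pos = ds.variants.pos_bp[blk[0] : blk[1]]
            lo = blk[0] + np.searchsorted(pos, row.start_bp)
            hi = blk[0] + np.searchsorted(pos, row.end_bp, side="right")
            assert not np.any(ds.calls[i, lo:hi] == 1)

    def test_mean_f_true_matches_f_ped(self):
        """Gene-drop mean autozygosity converges to the pedigree coefficient."""
        ped = Pedigree(
            {
                "A": (None, None),
                "B": (None, None),
                "C": ("A", "B"),
                "D": ("A", "B"),
                "X": ("C", "D"),
                "Y": ("X", "D"),
            }
        )
        vmap, cl = rs.make_map({"1": 120_000_000}, spacing_bp=1_000_000, seed=31)
        pool = rs.sample_founders(4, vmap, seed=32, chrom_lengths=cl)
        reps = np.array(
            [
                [rs.gene_drop(ped, pool, seed=r)[1].f_true[s] for s in ("X", "Y")]
                for r in range(400)
            ]
        )
        for k, s in enumerate(("X", "Y")):
            assert abs(reps[:, k].mean() - rs.f_ped(ped, s)) < 0.04


class TestPlantRoh:
    def test_fraction_zero_is_identity(self, small_pool):
        base = _diploids_from_pool(small_pool, 5, seed=1)
        ds, truth = rs.plant_roh(base, 0.0, seed=2)
        assert np.array_equal(ds.calls, base.calls)
        assert (truth.f_true == 0).all()

    def test_fraction_one_all_homozygous(self, small_pool):
        base = _diploids_from_pool(small_pool, 3, seed=1)
        ds, truth = rs.plant_roh(base, 1.0, seed=2)
        assert not np.any(ds.calls == 1)
        assert truth.f_true.min() > 0.95

    def test_realized_fraction_tracks_target(self, planted_dataset):
        """Target 0.15 with mean 4.11 Mb tracts: realized mean within 0.02."""
        _, truth = planted_dataset
        assert abs(truth.f_true.mean() - 0.15) < 0.02

    def test_tracts_non_overlapping(self, planted_dataset):
        _, truth = planted_dataset
        for (_, _), grp in truth.tracts.groupby(["sample", "chrom"]):
            g = grp.sort_values("start_bp")
            assert (g["start_bp"].to_numpy()[1:] > g["end_bp"].to_numpy()[:-1]).all()


class TestPlantSweep:
    def test_core_identity_of_carriers(self, small_pool):
        swept, truth = rs.plant_sweep(
            small_pool, focal=700, carrier_freq=0.5, core_half_len_bp=2_000_000, seed=3
        )
        haps = swept.to_haplotype_set()
        curve = rs.ehh(haps, 700, 1)
        pos0 = haps.variants.pos_bp[700]
        within = np.abs(curve["pos_bp"] - pos0) <= 1_000_000
        assert np.all(curve["ehh"][within] == 1.0)

    def test_zero_core_changes_only_focal(self, small_pool):
        swept, _ = rs.plant_sweep(
            small_pool, focal=700, carrier_freq=0.4, core_half_len_bp=0, seed=3
        )
        diff_cols = np.nonzero(
            (swept.haplotypes != small_pool.haplotypes).any(axis=0)
        )[0]
        assert diff_cols.tolist() == [700]

    def test_bad_carrier_freq(self, small_pool):
        with pytest.raises(ValueError, match="carrier_freq"):
            rs.plant_sweep(small_pool, 10, 1.0, 1000)


class TestInjectNoise:
    def test_zero_rates_identity(self, planted_dataset):
        ds, _ = planted_dataset
        out = rs.inject_noise(ds, 0.0, 0.0, seed=1)
        assert np.array_equal(out.calls, ds.calls)

    def test_missing_rate_binomial(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(500, 2000)).astype(np.int8)
        ds = rs.GenotypeDataset(
            samples=[f"s{i}" for i in range(500)],
            variants=simple_map(2000),
            calls=calls,
        )
        out = rs.inject_noise(ds, miss_rate=0.02, seed=5)
        frac = (out.calls == MISSING).mean()
        assert abs(frac - 0.02) < 0.002

    def test_het_errors_survive_window_allowance(self, small_pool):
        """A planted tract with rare het miscalls is still called as one ROH."""
        base = _diploids_from_pool(small_pool, 10, seed=7)
        ds, truth = rs.plant_roh(base, 0.2, (6.0, "fixed"), seed=8, min_length_mb=4.0)
        noisy = rs.inject_noise(ds, het_error_rate=0.001, seed=9)
        roh = rs.call_roh(noisy)
        covered = 0
        for row in truth.tracts.itertuples():
            seg = roh.segments
            hit = seg[
                (seg["sample"] == row.sample)
                & (seg["chrom"].astype(str) == str(row.chrom))
                & (seg["start_bp"] <= row.start_bp + 500_000)
                & (seg["end_bp"] >= row.end_bp - 500_000)
            ]
            covered += len(hit) > 0
        assert covered / len(truth.tracts) > 0.95
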