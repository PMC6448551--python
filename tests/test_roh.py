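import numpy as np
import pandas as pd
import pytest

import rohscan as rs
from rohscan.io import MISSING, GenotypeDataset, VariantMap
from rohscan.roh import ROHParams, call_roh, call_roh_exact, segments_from_table, summarize_roh
from rohscan.pipeline import _diploids_from_pool

from conftest import dataset_from_calls, simple_map


def one_sample_dataset(calls_row, pos_bp, chrom="1"):
    m = len(pos_bp)
    vmap = VariantMap(
        chrom=np.array([chrom] * m, dtype=object),
        pos_bp=np.asarray(pos_bp, dtype=np.int64),
        ids=np.array([f"v{i}" for i in range(m)], dtype=object),
        ref_allele=np.array(["A"] * m, dtype=object),
        alt_allele=np.array(["G"] * m, dtype=object),
    )
    return GenotypeDataset(
        samples=["s0"],
        variants=vmap,
        calls=np.asarray(calls_row, dtype=np.int8).reshape(1, -1),
    )


def tract_fixture(span_bp: int, n_tract: int = 150, n_flank: int = 100):
    """A homozygous tract filling chromosome 1; het background on chromosome 2.

    Judging edge SNPs on the windows that exist means a clean whole-chromosome
    run is called end to end.
    """
    step = span_bp // (n_tract - 1)
    tract_pos = [1_000_000 + i * step for i in range(n_tract - 1)]
    tract_pos.append(1_000_000 + span_bp - 1)  # exact span
    flank_pos = [10_000 * (i + 1) for i in range(n_flank)]
    m = n_tract + n_flank
    vmap = VariantMap(
        chrom=np.array(["1"] * n_tract + ["2"] * n_flank, dtype=object),
        pos_bp=np.asarray(tract_pos + flank_pos, dtype=np.int64),
        ids=np.array([f"v{i}" for i in range(m)], dtype=object),
        ref_allele=np.array(["A"] * m, dtype=object),
        alt_allele=np.array(["G"] * m, dtype=object),
    )
    calls = np.asarray([2] * n_tract + [1] * n_flank, dtype=np.int8).reshape(1, -1)
    ds = GenotypeDataset(samples=["s0"], variants=vmap, calls=calls)
    return ds, tract_pos[0], tract_pos[-1]


class TestCallRoh:
    def test_single_clean_tract(self):
        """150 homozygous SNPs spanning 2 Mb give exactly one 150-SNP segment."""
        ds, start, end = tract_fixture(2_000_000)
        for caller in (call_roh, call_roh_exact):
            seg = caller(ds).segments
            assert len(seg) == 1
            row = seg.iloc[0]
            assert row.n_snps == 150
            assert (row.start_bp, row.end_bp) == (start, end)

    def test_short_tract_rejected_by_length(self):
        """The same tract squeezed into 0.9 Mb fails the 1 Mb minimum."""
        ds, _, _ = tract_fixture(900_000)
        assert call_roh(ds).n_segments == 0

    def test_all_het_individual_empty(self):
        ds = dataset_from_calls(np.ones((1, 300), dtype=np.int8))
        assert call_roh(ds).n_segments == 0

    def test_all_hom_chromosome_single_segment(self):
        ds = dataset_from_calls(np.full((1, 300), 2, dtype=np.int8))
        seg = call_roh(ds).segments
        assert len(seg) == 1
        assert seg.iloc[0].start_bp == ds.variants.pos_bp[0]
        assert seg.iloc[0].end_bp == ds.variants.pos_bp[-1]
        assert seg.iloc[0].n_snps == 300

    def test_planted_tract_with_het_survives(self, small_pool):
        """One miscalled het inside a 4 Mb tract does not break the segment."""
        base = _diploids_from_pool(small_pool, 1, seed=3)
        ds, truth = rs.plant_roh(base, 0.12, (4.5, "fixed"), seed=4, min_length_mb=4.0)
        tract = truth.tracts.iloc[0]
        blk = next(b for b in ds.variants.chrom_blocks() if str(b[2]) == str(tract.chrom))
        pos = ds.variants.pos_bp[blk[0] : blk[1]]
        mid = blk[0] + int(
            np.searchsorted(pos, (tract.start_bp + tract.end_bp) / 2)
        )
        calls = ds.calls.copy()
        calls[0, mid] = 1
        noisy = GenotypeDataset(samples=ds.samples, variants=ds.variants, calls=calls,
                                l_auto_override_bp=ds.l_auto_override_bp)
        seg = call_roh(noisy).segments
        hit = seg[
            (seg["chrom"].astype(str) == str(tract.chrom))
            & (seg["start_bp"] <= tract.start_bp + 200_000)
            & (seg["end_bp"] >= tract.end_bp - 200_000)
        ]
        assert len(hit) == 1

    def test_small_chromosome_skipped_with_warning(self):
        ds = dataset_from_calls(np.full((1, 10), 2, dtype=np.int8))
        with pytest.warns(UserWarning, match="fewer SNPs"):
            out = call_roh(ds)
        assert out.n_segments == 0

    def test_segment_invariants(self, planted_dataset):
        """Every emitted segment satisfies the count/length/density filters."""
        ds, _ = planted_dataset
        noisy = rs.inject_noise(ds, miss_rate=0.01, het_error_rate=0.001, seed=5)
        p = ROHParams()
        seg = call_roh(noisy, p).segments
        assert len(seg) > 0
        assert (seg["length_bp"] == seg["end_bp"] - seg["start_bp"] + 1).all()
        assert (seg["n_snps"] >= p.min_snps).all()
        assert (seg["length_bp"] >= p.min_length_kb * 1000).all()
        assert (seg["length_bp"] / seg["n_snps"] <= p.max_kb_per_snp * 1000).all()

    def test_monotonicity(self, planted_dataset):
        """Stricter length/het settings never call more ROH."""
        ds, _ = planted_dataset
        base = call_roh(ds, ROHParams())
        longer = call_roh(ds, ROHParams(min_length_kb=2000))
        assert longer.n_segments <= base.n_segments
        strict_het = call_roh(ds, ROHParams(window_max_het=0))
        assert (
            strict_het.segments["length_bp"].sum() <= base.segments["length_bp"].sum()
        )

    def test_oracle_equivalence_random(self, small_pool):
        """Windowed caller equals the brute-force enumeration on noisy data."""
        base = _diploids_from_pool(small_pool, 8, seed=11)
        ds, _ = rs.plant_roh(base, 0.2, seed=12)
        ds = rs.inject_noise(ds, miss_rate=0.02, het_error_rate=0.002, seed=13)
        a = call_roh(ds).segments.reset_index(drop=True)
        b = call_roh_exact(ds).segments.reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_recovery_of_long_tracts(self, small_pool):
        """Planted tracts >= 2 Mb: >=99% of tract length is recovered and
        called-but-not-planted length stays under 2% of the genome."""
        base = _diploids_from_pool(small_pool, 30, seed=21)
        ds, truth = rs.plant_roh(base, 0.15, (4.11, "exponential"), seed=22,
                                 min_length_mb=2.0)
        seg = call_roh(ds).segments
        covered = 0
        planted_total = 0
        called_total = seg["length_bp"].sum()
        overlap_total = 0
        for row in truth.tracts.itertuples():
            planted_total += row.end_bp - row.start_bp + 1
            s = seg[(seg["sample"] == row.sample) & (seg["chrom"].astype(str) == str(row.chrom))]
            ov = np.minimum(s["end_bp"], row.end_bp) - np.maximum(s["start_bp"], row.start_bp) + 1
            overlap_total += ov[ov > 0].sum()
        assert overlap_total / planted_total >= 0.99
        false_positive = called_total - overlap_total
        assert false_positive / (ds.n_samples * ds.l_auto_bp) <= 0.02


class TestSummarize:
    def test_percent_and_coverage_arithmetic(self):
        """Percent-of-count and coverage columns from a constructed segment set."""
        rows = []
        for count, mean_mb, klass in [(6, 2.0, "1-5"), (3, 6.0, "5-10"), (1, 12.0, ">10")]:
            for k in range(count):
                rows.append(("s0", "1", 1, int(mean_mb * 1e6)))
        seg = pd.DataFrame(rows, columns=["sample", "chrom", "start_bp", "length_bp"])
        seg["end_bp"] = seg["start_bp"] + seg["length_bp"] - 1
        rohset = segments_from_table(seg[["sample", "chrom", "start_bp", "end_bp"]], 5)
        tab = summarize_roh(rohset, l_auto_bp=100e6, n_samples=5)
        assert tab.loc["1-5", "count"] == 6
        assert tab.loc["1-5", "pct_of_count"] == pytest.approx(60.0)
        assert tab.loc["5-10", "pct_of_count"] == pytest.approx(30.0)
        # coverage: 6*2 Mb / (5 * 100 Mb) = 2.4%
        assert tab.loc["1-5", "coverage_pct"] == pytest.approx(2.4)
        assert tab.loc["Total (>1)", "coverage_pct"] == pytest.approx(
            (12 + 18 + 12) / 500 * 100
        )

    def test_empty_rohset_zero_table(self):
        empty = segments_from_table(
            pd.DataFrame(columns=["sample", "chrom", "start_bp", "end_bp"]), 5
        )
        tab = summarize_roh(empty, l_auto_bp=1e8, n_samples=5)
        assert (tab["count"] == 0).all()
        assert (tab["coverage_pct"] == 0).all()


class TestExpectedLength:
    @pytest.mark.parametrize(
        "g,cm_per_mb,expected_mb",
        [(50, 1.0, 1.0), (5, 1.0, 10.0), (10, 1.0, 5.0), (50, 2.0, 0.5)],
    )
    def test_values(self, g, cm_per_mb, expected_mb):
        assert rs.expected_roh_length(g, cm_per_mb) == pytest.approx(expected_mb)

    def test_vanishes_for_deep_ancestry(self):
        assert rs.expected_roh_length(1e9) < 1e-6

    def test_invalid(self):
        with pytest.raises(ValueError):
            rs.expected_roh_length(0)
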