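"""Down-sampling, binning, BLISS+ calling, merging, union, overlaps."""

import numpy as np
import pandas as pd
import pytest

import trcmap as t
from conftest import bitmap_union


def events(chrom_pos_counts):
    return pd.DataFrame(
        [{"chrom": c, "pos": p, "umi_count": k} for c, p, k in chrom_pos_counts]
    )


def regions(triples):
    return pd.DataFrame(triples, columns=["Chromosome", "Start", "End"])


class TestDownsample:
    def test_single_sample_unchanged(self):
        ev = events([("chr1", 10, 3), ("chr1", 50, 2)])
        out = t.downsample({"a": ev}, seed=0)
        assert out["a"].umi_count.sum() == 5

    def test_totals_match_minimum(self):
        by = {
            "a": events([("chr1", i * 10, 2) for i in range(50)]),   # 100
            "b": events([("chr1", i * 10, 5) for i in range(50)]),   # 250
            "c": events([("chr1", i * 10, 3) for i in range(40)]),   # 120
        }
        out = t.downsample(by, seed=1)
        assert all(int(df.umi_count.sum()) == 100 for df in out.values())

    def test_deterministic_and_dict_order_independent(self):
        by = {
            "a": events([("chr1", i, 2) for i in range(30)]),
            "b": events([("chr1", i, 1) for i in range(40)]),
        }
        out1 = t.downsample(by, seed=5)
        out2 = t.downsample(dict(reversed(list(by.items()))), seed=5)
        for s in by:
            pd.testing.assert_frame_equal(out1[s], out2[s])

    def test_per_umi_inclusion_uniform(self):
        """Each UMI unit kept with frequency ~ min/total (3 sigma)."""
        big = events([("chr1", i * 10, c) for i, c in enumerate([1, 2, 3, 4] * 10)])
        small = events([("chr1", 5, 40)])
        total, target = int(big.umi_count.sum()), 40
        p = target / total
        n_seeds = 50
        kept = np.zeros(len(big))
        for seed in range(n_seeds):
            out = t.downsample({"big": big, "small": small}, seed=seed)
            got = out["big"].set_index("pos")["umi_count"]
            kept += big.pos.map(got).fillna(0).to_numpy()
        expect = big.umi_count.to_numpy() * p * n_seeds
        sigma = np.sqrt(big.umi_count.to_numpy() * n_seeds * p * (1 - p))
        assert (np.abs(kept - expect) <= 3 * sigma + 1e-9).all()


class TestBinCoverage:
    def test_bin_boundaries(self):
        ev = events([("chr1", 1999, 1), ("chr1", 2000, 1)])
        bins = t.bin_coverage(ev, {"chr1": 10_000})
        cov = bins.set_index("bin_index")["coverage"]
        assert cov[0] == 1 and cov[1] == 1

    def test_no_events_all_zero(self):
        bins = t.bin_coverage(events([]), {"chr1": 6000}, bin_size=2000)
        assert len(bins) == 3 and (bins.coverage == 0).all()
        assert bins.End.iloc[-1] == 6000

    def test_short_trailing_bin(self):
        bins = t.bin_coverage(events([]), {"chr1": 5000}, bin_size=2000)
        assert list(bins.End) == [2000, 4000, 5000]

    def test_matches_histogram_oracle(self):
        rng = np.random.default_rng(8)
        ev = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 10_000),
            "pos": rng.integers(0, 100_000, 10_000),
            "umi_count": rng.integers(1, 4, 10_000),
        })
        bins = t.bin_coverage(ev, {"chr1": 100_000, "chr2": 100_000})
        for chrom in ("chr1", "chr2"):
            sub = ev[ev.chrom == chrom]
            hist, _ = np.histogram(
                sub.pos, bins=50, range=(0, 100_000), weights=sub.umi_count
            )
            got = bins[bins.Chromosome == chrom].coverage.to_numpy()
            assert (got == hist).all()

    def test_out_of_bounds_event_named_in_error(self):
        ev = events([("chr1", 7000, 1)])
        with pytest.raises(ValueError, match="chr1:7000"):
            t.bin_coverage(ev, {"chr1": 6000})

    def test_conservation(self):
        rng = np.random.default_rng(1)
        ev = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 9999, 500),
                           "umi_count": rng.integers(1, 5, 500)})
        bins = t.bin_coverage(ev, {"chr1": 10_000})
        assert bins.coverage.sum() == ev.umi_count.sum()


class TestCallAndMerge:
    def test_threshold_strictly_above(self):
        bins = pd.DataFrame({"Chromosome": "chr1", "bin_index": [0, 1],
                             "Start": [0, 2000], "End": [2000, 4000],
                             "coverage": [22, 23]})
        called = t.call_positive_bins(bins)
        assert list(called.coverage) == [23]
        assert len(t.call_positive_bins(bins, strict=False)) == 2

    def test_threshold_zero_calls_every_nonzero_bin(self):
        bins = pd.DataFrame({"Chromosome": "chr1", "bin_index": [0, 1, 2],
                             "Start": [0, 2000, 4000], "End": [2000, 4000, 6000],
                             "coverage": [0, 1, 5]})
        assert len(t.call_positive_bins(bins, threshold=0)) == 2

    def test_called_set_equals_filter_oracle(self):
        rng = np.random.default_rng(2)
        cov = rng.integers(0, 50, 1000)
        bins = pd.DataFrame({"Chromosome": "chr1", "bin_index": range(1000),
                             "Start": np.arange(1000) * 2000,
                             "End": (np.arange(1000) + 1) * 2000, "coverage": cov})
        assert len(t.call_positive_bins(bins)) == int((cov > 22).sum())

    def test_adjacent_bins_merge(self):
        bins = pd.DataFrame({"Chromosome": "chr1", "bin_index": [0, 1],
                             "Start": [0, 2000], "End": [2000, 4000],
                             "coverage": [30, 40]})
        regs = t.merge_bins(bins)
        assert len(regs) == 1
        r = regs.iloc[0]
        assert (r.Start, r.End, r.n_bins, r.total_coverage) == (0, 4000, 2, 70)

    def test_gap_2000_merges_2001_does_not(self):
        def mk(gap):
            return pd.DataFrame({"Chromosome": "chr1", "bin_index": [0, 2],
                                 "Start": [0, 2000 + gap], "End": [2000, 4000 + gap],
                                 "coverage": [30, 30]})
        assert len(t.merge_bins(mk(2000))) == 1
        assert len(t.merge_bins(mk(2001))) == 2

    def test_merge_idempotent(self):
        rng = np.random.default_rng(4)
        starts = np.sort(rng.choice(np.arange(0, 100_000, 2000), 20, replace=False))
        bins = pd.DataFrame({"Chromosome": "chr1", "bin_index": starts // 2000,
                             "Start": starts, "End": starts + 2000,
                             "coverage": rng.integers(23, 60, 20)})
        regs = t.merge_bins(bins)
        again = t.merge_bins(regs.rename(columns={"total_coverage": "coverage"}))
        assert list(again.Start) == list(regs.Start)
        assert list(again.End) == list(regs.End)


class TestUnionAndOverlap:
    def test_single_replicate_identity(self):
        r = regions([("chr1", 0, 2000)])
        out = t.union_regions([r])
        assert list(out.itertuples(index=False)) == [("chr1", 0, 2000)]

    def test_overlapping_intervals_coalesce(self):
        out = t.union_regions([regions([("chr1", 0, 2000)]),
                               regions([("chr1", 1000, 4000)])])
        assert len(out) == 1 and out.End.iloc[0] == 4000

    def test_matches_bitmap_oracle(self):
        rng = np.random.default_rng(6)
        sets = []
        for _ in range(3):
            starts = rng.integers(0, 95_000, 15)
            sets.append(regions([("chr1", int(s), int(s + rng.integers(500, 5000)))
                                 for s in starts]))
        got = [tuple(r) for r in t.union_regions(sets).itertuples(index=False)]
        assert got == bitmap_union(sets)

    def test_union_idempotent_and_commutative(self):
        a = regions([("chr1", 0, 1000), ("chr1", 5000, 8000)])
        b = regions([("chr1", 500, 6000)])
        ab = t.union_regions([a, b])
        ba = t.union_regions([b, a])
        pd.testing.assert_frame_equal(ab, ba)
        pd.testing.assert_frame_equal(t.union_regions([ab]), ab)

    def test_overlap_matrix_identical_and_disjoint(self):
        a = regions([("chr1", 0, 1000), ("chr1", 5000, 6000)])
        b = regions([("chr1", 10_000, 11_000)])
        mat = t.overlap_matrix({"x": a, "y": a.copy()})
        assert (mat.to_numpy() == 1.0).all()
        mat2 = t.overlap_matrix({"x": a, "z": b})
        assert mat2.loc["x", "z"] == 0.0 and mat2.loc["z", "x"] == 0.0
        assert mat2.loc["x", "x"] == 1.0

    def test_overlap_matrix_hand_computed(self):
        a = regions([("chr1", 0, 1000), ("chr1", 2000, 3000), ("chr1", 9000, 9500)])
        b = regions([("chr1", 900, 2100), ("chr1", 4000, 5000)])
        mat = t.overlap_matrix({"A": a, "B": b})
        assert mat.loc["A", "B"] == pytest.approx(2 / 3)
        assert mat.loc["B", "A"] == pytest.approx(1 / 2)

    def test_empty_set_warns_and_zero_row(self):
        a = regions([("chr1", 0, 1000)])
        empty = regions([])
        with pytest.warns(UserWarning):
            mat = t.overlap_matrix({"A": a, "E": empty})
        assert (mat.loc["E"] == 0).all()
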