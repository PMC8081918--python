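"""Binning, downsampling, blacklist masking, and threshold spot calling."""

import numpy as np
import pandas as pd
import pytest

import repairspot as rp


class TestMakeBins:
    def test_even_tiling(self):
        bins = rp.make_bins({"c1": 10_000}, 50)
        assert bins.n_bins == 200
        assert (bins.starts[0], bins.ends[0]) == (0, 50)
        assert (bins.starts[-1], bins.ends[-1]) == (9950, 10_000)
        assert not bins.partial.any()

    def test_partial_final_bin_retained_and_flagged(self):
        bins = rp.make_bins({"c1": 101}, 50)
        assert bins.n_bins == 3
        assert (bins.starts[-1], bins.ends[-1]) == (100, 101)
        assert bins.partial[-1] and not bins.partial[:-1].any()

    def test_default_width_is_50(self):
        assert rp.spots.DEFAULT_BIN_WIDTH == 50
        bins = rp.make_bins({"c1": 500})
        assert bins.bin_width == 50

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rp.make_bins({"c1": 0}, 50)
        with pytest.raises(ValueError):
            rp.make_bins({"c1": 100}, 0)


class TestDownsample:
    def _rs(self, n):
        df = pd.DataFrame({"chrom": "c1", "start": np.arange(n),
                           "end": np.arange(n) + 26, "name": [f"r{i}" for i in range(n)],
                           "mapq": 60, "strand": "+"})
        return rp.ReadSet(df=df, sample_id="s")

    def test_exact_subset_without_replacement(self):
        rs = self._rs(10_000)
        out = rp.downsample_reads(rs, 1000, seed=1)
        assert len(out) == 1000
        assert out.df["name"].is_unique
        assert set(out.df["name"]) <= set(rs.df["name"])

    def test_seed_reproducible(self):
        rs = self._rs(5000)
        a = rp.downsample_reads(rs, 500, seed=7)
        b = rp.downsample_reads(rs, 500, seed=7)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_short_sample_errors_unless_allowed(self):
        rs = self._rs(100)
        with pytest.raises(ValueError, match="fewer than the requested depth"):
            rp.downsample_reads(rs, 200)
        assert len(rp.downsample_reads(rs, 200, allow_short=True)) == 100

    def test_pipeline_default_depth(self):
        assert rp.spots.DEFAULT_DOWNSAMPLE_DEPTH == 7_700_000


class TestCountReadsPerBin:
    def _bins(self):
        return rp.make_bins({"c1": 1000}, 50)

    def test_single_plus_read_assigned_by_5prime_end(self):
        df = pd.DataFrame([("c1", 75, 101, "r", 60, "+")],
                          columns=["chrom", "start", "end", "name", "mapq", "strand"])
        col, skipped = rp.count_reads_per_bin(rp.ReadSet(df=df), self._bins(), "+")
        assert skipped == 0
        assert col[1] == 1 and col.sum() == 1  # bin [50,100)

    def test_minus_read_uses_its_own_5prime_end(self):
        # minus-strand 5' end is end-1 = 100 -> bin [100,150)
        df = pd.DataFrame([("c1", 75, 101, "r", 60, "-")],
                          columns=["chrom", "start", "end", "name", "mapq", "strand"])
        col, _ = rp.count_reads_per_bin(rp.ReadSet(df=df), self._bins(), "-")
        assert col[2] == 1 and col.sum() == 1

    def test_strand_separation(self):
        df = pd.DataFrame([("c1", 10, 36, "a", 60, "+"), ("c1", 10, 36, "b", 60, "-")],
                          columns=["chrom", "start", "end", "name", "mapq", "strand"])
        plus, _ = rp.count_reads_per_bin(rp.ReadSet(df=df), self._bins(), "+")
        assert plus.sum() == 1

    def test_conservation(self, small_reads, small_genome):
        rs = small_reads["1min_rep1"]
        bins = rp.make_bins(small_genome.sizes, 50)
        plus, sk_p = rp.count_reads_per_bin(rs, bins, "+")
        minus, sk_m = rp.count_reads_per_bin(rs, bins, "-")
        assert plus.sum() + minus.sum() + sk_p + sk_m == len(rs)

    def test_unknown_chromosome_tally_not_exception(self):
        df = pd.DataFrame([("cX", 10, 36, "a", 60, "+")],
                          columns=["chrom", "start", "end", "name", "mapq", "strand"])
        col, skipped = rp.count_reads_per_bin(rp.ReadSet(df=df), self._bins(), "+")
        assert skipped == 1 and col.sum() == 0


class TestBlacklist:
    def test_one_bp_overlap_masks_bin(self):
        bins = rp.make_bins({"c1": 1000}, 50)
        bl = pd.DataFrame([("c1", 60, 70)], columns=["chrom", "start", "end"])
        masked = rp.apply_blacklist(bins, bl)
        assert masked.masked[1] and not masked.masked[0]
        assert not bins.masked.any()  # original untouched

    def test_empty_blacklist(self):
        bins = rp.make_bins({"c1": 1000}, 50)
        out = rp.apply_blacklist(bins, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert not out.masked.any()

    def test_interval_spanning_bins_masks_all_overlapped(self):
        bins = rp.make_bins({"c1": 1000}, 50)
        bl = pd.DataFrame([("c1", 95, 140)], columns=["chrom", "start", "end"])
        out = rp.apply_blacklist(bins, bl)
        # brute-force overlap oracle
        expect = np.array([max(s, 95) < min(e, 140) for s, e in zip(bins.starts, bins.ends)])
        assert np.array_equal(out.masked, expect)


def _matrix(Y, early=("e1", "e2"), late=("l1", "l2"), masked=None):
    nb = Y.shape[0]
    bins = rp.make_bins({"c1": nb * 50}, 50)
    if masked is not None:
        bins.masked[:] = masked
    samples = pd.DataFrame({"sample_id": list(early) + list(late),
                            "time_point": ["1min"] * len(early) + ["4h"] * len(late),
                            "replicate": ["rep1", "rep2"] * 2})
    return rp.BinCountMatrix(Y=Y, strand="+", bins=bins, samples=samples,
                             N=np.full(Y.shape[1], 1000.0))


class TestCallSpots:
    def test_boundary_counts_inclusive(self):
        Y = np.array([[15, 15, 5, 5],     # hotspot: boundaries inclusive
                      [15, 14, 5, 5],     # fails: "both replicates"
                      [15, 15, 6, 5],     # fails: late cap exceeded
                      [2, 2, 10, 10],     # coldspot
                      [2, 3, 10, 10]])    # fails early coldspot cap
        out = rp.call_spots(_matrix(Y), rp.ThresholdRule(early=["e1", "e2"], late=["l1", "l2"]))
        hot = out[out["category"] == "hotspot"]
        cold = out[out["category"] == "coldspot"]
        assert list(hot["bin_index"]) == [0]
        assert list(cold["bin_index"]) == [3]

    def test_blacklisted_bin_never_called(self):
        Y = np.tile([50, 50, 0, 0], (3, 1))
        masked = np.array([False, True, False])
        out = rp.call_spots(_matrix(Y, masked=masked),
                            rp.ThresholdRule(early=["e1", "e2"], late=["l1", "l2"]))
        assert set(out["bin_index"]) == {0, 2}

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        rule = rp.ThresholdRule(early=["e1", "e2"], late=["l1", "l2"])
        for _ in range(5):
            Y = rng.poisson(3.0, size=(1000, 4))
            masked = rng.random(1000) < 0.05
            out = rp.call_spots(_matrix(Y, masked=masked), rule)
            called_hot = set(out.loc[out["category"] == "hotspot", "bin_index"])
            called_cold = set(out.loc[out["category"] == "coldspot", "bin_index"])
            # independent per-bin predicate evaluation
            exp_hot, exp_cold = set(), set()
            for i in range(1000):
                if masked[i]:
                    continue
                if Y[i, 0] >= 15 and Y[i, 1] >= 15 and Y[i, 2] <= 5 and Y[i, 3] <= 5:
                    exp_hot.add(i)
                if Y[i, 0] <= 2 and Y[i, 1] <= 2 and Y[i, 2] >= 10 and Y[i, 3] >= 10:
                    exp_cold.add(i)
            assert called_hot == exp_hot and called_cold == exp_cold

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        Y = rng.poisson(6.0, size=(500, 4))
        m = _matrix(Y)
        base = set(rp.call_spots(m, rp.ThresholdRule(["e1", "e2"], ["l1", "l2"],
                                                     hot_min_early=8, hot_max_late=6),
                                 categories=["hotspot"])["bin_index"])
        stricter = set(rp.call_spots(m, rp.ThresholdRule(["e1", "e2"], ["l1", "l2"],
                                                         hot_min_early=10, hot_max_late=6),
                                     categories=["hotspot"])["bin_index"])
        looser_late = set(rp.call_spots(m, rp.ThresholdRule(["e1", "e2"], ["l1", "l2"],
                                                            hot_min_early=8, hot_max_late=8),
                                        categories=["hotspot"])["bin_index"])
        assert stricter <= base <= looser_late

    def test_cpd_coldspots_refused(self):
        Y = np.zeros((150, 4), dtype=int)
        with pytest.raises(ValueError, match="CPD coldspot"):
            rp.call_spots(_matrix(Y), rp.ThresholdRule(["e1", "e2"], ["l1", "l2"]),
                          damage_type="CPD")
        # hotspot-only CPD calling is fine, as is forcing
        rp.call_spots(_matrix(Y), rp.ThresholdRule(["e1", "e2"], ["l1", "l2"]),
                      categories=["hotspot"], damage_type="CPD")
        rp.call_spots(_matrix(Y), rp.ThresholdRule(["e1", "e2"], ["l1", "l2"]),
                      damage_type="CPD", force=True)

    def test_unknown_samples_error(self):
        Y = np.zeros((150, 4), dtype=int)
        with pytest.raises(ValueError, match="unknown samples"):
            rp.call_spots(_matrix(Y), rp.ThresholdRule(early=["nope"], late=["l1"]))
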