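"""Annotation overlap enrichment with the bootstrap genome null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import repairspot as rp

SIZES = {"c1": 100_000, "c2": 100_000}


def _ann(rows, name="ann"):
    return rp.AnnotationSet(name=name, df=pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestOverlapProportion:
    def test_extremes(self):
        spots = pd.DataFrame({"chrom": "c1", "start": [100, 300], "end": [150, 350]})
        assert rp.overlap_proportion(spots, _ann([("c1", 0, 1000)])) == 1.0
        assert rp.overlap_proportion(spots, _ann([("c2", 0, 1000)])) == 0.0
        with pytest.raises(ValueError, match="empty"):
            rp.overlap_proportion(spots.iloc[:0], _ann([("c1", 0, 1000)]))

    def test_constructed_fraction(self):
        # 200 disjoint grid spots, annotation touching exactly the first 47
        rows = [("c1" if i < 100 else "c2", (i % 100) * 1000, (i % 100) * 1000 + 50)
                for i in range(200)]
        spots = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        ann_rows = [(r.chrom, r.start - 10, r.start + 10) for r in spots.head(47).itertuples()]
        ann_rows += [("c1", (i % 100) * 1000 + 200, (i % 100) * 1000 + 300)
                     for i in range(60, 70)]  # decoys in inter-spot gaps
        assert rp.overlap_proportion(spots, _ann(ann_rows)) == pytest.approx(47 / 200)

    def test_invariant_under_split_and_order(self):
        rng = np.random.default_rng(2)
        spots = rp.sample_random_spots(50, 50, SIZES, seed=rng)
        rows = [("c1", 1000, 3000), ("c2", 5000, 9000), ("c1", 40_000, 45_000)]
        base = rp.overlap_proportion(spots, _ann(rows))
        shuffled = rp.overlap_proportion(spots, _ann(rows[::-1]))
        split = rp.overlap_proportion(spots, _ann(
            [("c1", 1000, 2000), ("c1", 2000, 3000), ("c2", 5000, 9000),
             ("c1", 40_000, 45_000)]))
        assert base == shuffled == split


class TestSampleRandomSpots:
    def test_forced_single_slot(self):
        sizes = {"c1": 1000}
        excl = pd.DataFrame({"chrom": "c1", "start": [0, 450], "end": [400, 1000]})
        out = rp.sample_random_spots(1, 50, sizes, exclusions=excl, seed=0)
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (400, 450)

    def test_uniform_over_eligible_space(self):
        sizes = {"c1": 2000}
        excl = pd.DataFrame({"chrom": "c1", "start": [500], "end": [700]})
        rng = np.random.default_rng(3)
        out = rp.sample_random_spots(100_000, 10, sizes, exclusions=excl, seed=rng)
        starts = out["start"].to_numpy()
        assert ((starts + 10 <= 500) | (starts >= 700)).all()
        # chi-square uniformity over the legal start positions
        legal = np.concatenate([np.arange(0, 491), np.arange(700, 1991)])
        counts = pd.Series(starts).value_counts().reindex(legal, fill_value=0)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=len(legal) - 1) > 0.01

    def test_seed_reproducible_and_infeasible(self):
        a = rp.sample_random_spots(20, 50, SIZES, seed=11)
        b = rp.sample_random_spots(20, 50, SIZES, seed=11)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError, match="eligible space"):
            rp.sample_random_spots(1, 200_001, SIZES)


class TestBootstrapEnrichment:
    def _spots(self, seed=5, n=50):
        s = rp.sample_random_spots(n, 50, SIZES, seed=seed)
        return s

    def test_full_colocation_gives_minimum_p(self):
        cfg = rp.SimConfig(seed=1, chrom_lengths=SIZES,
                           samples=[rp.SampleSpec("s", "1min", "r", 100)])
        spots = self._spots()
        ann = rp.simulate_annotations(cfg, spots, 1.0, n_intervals=60, width=1000)
        res = rp.bootstrap_enrichment(spots, ann, SIZES, B=200, seed=2)
        assert res.observed == 1.0
        assert res.p_enrichment == pytest.approx(1 / 201)

    def test_null_mean_matches_placement_oracle(self):
        cfg = rp.SimConfig(seed=4, chrom_lengths=SIZES,
                           samples=[rp.SampleSpec("s", "1min", "r", 100)])
        spots = self._spots(seed=6)
        ann = rp.simulate_annotations(cfg, spots, 0.0, n_intervals=40, width=1000)
        res = rp.bootstrap_enrichment(spots, ann, SIZES, B=5000, seed=7)
        # oracle: exact per-chromosome probability that a random legal 50-bp
        # placement (outside exclusions) touches the annotation
        probs = []
        excl = spots
        for chrom, size in SIZES.items():
            legal = np.ones(size - 50 + 1, dtype=bool)
            for r in excl[excl["chrom"] == chrom].itertuples():
                legal[max(0, r.start - 49) : r.end] = False
            hit = np.zeros(size - 50 + 1, dtype=bool)
            for r in ann.df[ann.df["chrom"] == chrom].itertuples():
                hit[max(0, r.start - 49) : r.end] = True
            probs.append((chrom, (hit & legal).sum() / legal.sum(),
                          (excl["chrom"] == chrom).sum()))
        expect = sum(p * n for _, p, n in probs) / sum(n for _, _, n in probs)
        se = res.null.std() / np.sqrt(len(res.null))
        assert abs(res.null_mean - expect) < 3 * se + 1e-4
        assert res.p_enrichment > 0  # add-one formula can never hit 0

    def test_empirical_p_uniform_under_null(self):
        ps = []
        for seed in range(120):
            cfg = rp.SimConfig(seed=seed, chrom_lengths=SIZES,
                               samples=[rp.SampleSpec("s", "1min", "r", 100)])
            spots = rp.sample_random_spots(100, 50, SIZES, seed=seed + 4000)
            ann = rp.simulate_annotations(cfg, spots, 0.0, n_intervals=60, width=1000)
            res = rp.bootstrap_enrichment(spots, ann, SIZES, B=200, seed=seed + 8000)
            ps.append(res.p_enrichment)
        assert stats.kstest(np.array(ps), "uniform").pvalue > 0.01

    def test_b_floor(self):
        spots = self._spots()
        with pytest.raises(ValueError, match="B must be"):
            rp.bootstrap_enrichment(spots, _ann([("c1", 0, 100)]), SIZES, B=10)


class TestInteractions:
    def test_anchor_overlap_counting(self):
        spots = pd.DataFrame({"chrom": ["c1"], "start": [1000], "end": [1050]})
        inter = pd.DataFrame({
            "chrom1": ["c1", "c1", "c1", "c2"], "start1": [900, 900, 5000, 900],
            "end1": [1100, 1100, 5200, 1100],
            "chrom2": ["c2", "c1", "c1", "c2"], "start2": [0, 980, 900, 0],
            "end2": [200, 1200, 1100, 200],
        })
        counts = rp.count_interactions_per_spot(spots, inter)
        # rows 0 and 1 via anchor1; row 1 also matches anchor2 but counts once...
        # row 2 matches via anchor2 only; row 3 is on another chromosome
        assert counts[0] == 4  # anchor-level overlap events (1: both anchors)

    def test_excess_at_spots_detected(self):
        detected = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = rp.SimConfig(seed=seed, chrom_lengths=SIZES,
                               samples=[rp.SampleSpec("s", "1min", "r", 100)])
            spots = rp.sample_random_spots(30, 50, SIZES, seed=seed + 100)
            inter = rp.simulate_interactions(cfg, spots, n_background=60, per_spot=5,
                                             anchor_width=1000)
            rnd = rp.sample_random_spots(30, 50, SIZES, exclusions=spots, seed=seed + 200)
            sc = rp.count_interactions_per_spot(spots, inter)
            rc = rp.count_interactions_per_spot(rnd, inter)
            _, p = rp.interaction_excess_test(sc, rc)
            detected += p < 0.01
        assert detected >= n_seeds - 1

    def test_no_interactions_all_zero(self):
        spots = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [50]})
        inter = pd.DataFrame(columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])
        assert rp.count_interactions_per_spot(spots, inter)[0] == 0


class TestSignalAndComposition:
    def test_constant_track(self):
        track = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100_000],
                              "value": [3.5]})
        spots = pd.DataFrame({"chrom": "c1", "start": [10, 500], "end": [60, 550]})
        np.testing.assert_allclose(rp.aggregate_signal(spots, track, SIZES), 3.5)

    def test_elevated_track_detected(self):
        rng = np.random.default_rng(12)
        hot = rp.sample_random_spots(25, 50, SIZES, seed=rng)
        rnd = rp.sample_random_spots(25, 50, SIZES, exclusions=hot, seed=rng)
        rows = [("c1", 0, 100_000, 1.0), ("c2", 0, 100_000, 1.0)]
        rows += [(r.chrom, r.start, r.end, 10.0) for r in hot.itertuples()]
        track = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        sig_hot = rp.aggregate_signal(hot, track, SIZES)
        sig_rnd = rp.aggregate_signal(rnd, track, SIZES)
        stat, p = stats.mannwhitneyu(sig_hot, sig_rnd, alternative="greater")
        assert p < 0.01

    def test_empty_track_all_zero(self):
        track = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        spots = pd.DataFrame({"chrom": "c1", "start": [10], "end": [60]})
        assert rp.aggregate_signal(spots, track, SIZES)[0] == 0.0

    def test_category_composition_rules(self):
        states = rp.AnnotationSet(name="states", df=pd.DataFrame({
            "chrom": ["c1", "c1"], "start": [0, 130], "end": [130, 100_000],
            "label": ["promoter", "quiescent"]}))
        spots = pd.DataFrame({"chrom": "c1", "start": [100, 500, 60_000],
                              "end": [150, 550, 60_050]})
        frac = rp.category_composition(spots, states)
        # first spot: 30 bp promoter vs 20 bp quiescent -> promoter
        assert frac["promoter"] == pytest.approx(1 / 3)
        assert frac["quiescent"] == pytest.approx(2 / 3)
        assert frac.sum() <= 1.0

    def test_single_label_covering_genome(self):
        states = rp.AnnotationSet(name="states", df=pd.DataFrame({
            "chrom": ["c1"], "start": [0], "end": [100_000], "label": ["all"]}))
        spots = pd.DataFrame({"chrom": "c1", "start": [10, 20], "end": [60, 70]})
        assert rp.category_composition(spots, states)["all"] == 1.0
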