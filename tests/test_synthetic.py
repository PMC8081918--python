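"""Synthetic-data generator: determinism, planted structure, count model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import repairspot as rp
from repairspot.synthetic import CANONICAL_MOTIFS, simulate_count_matrix


def _one_spot_config(damage_type="64PP", seed=7, **kw):
    return rp.SimConfig(
        seed=seed,
        chrom_lengths={"chrS1": 10_000},
        samples=[rp.SampleSpec("s1", "1min", "rep1", 5000)],
        planted_hotspots=[rp.PlantedSpot("chrS1", 500, 550, "+", 50.0, 1.0)],
        damage_type=damage_type,
        **kw,
    )


class TestSimulateGenome:
    def test_motif_planted_inside_interval(self):
        g = rp.simulate_genome(_one_spot_config())
        assert len(g.sequences["chrS1"]) == 10_000
        assert "CTCA" in g.sequences["chrS1"][500:550]

    def test_cpd_motif_is_tt(self):
        cfg = _one_spot_config(damage_type="CPD")
        g = rp.simulate_genome(cfg)
        for anchor in rp.planted_anchors(rp.PlantedSpot("chrS1", 500, 550, "+"), cfg):
            assert g.sequences["chrS1"][anchor : anchor + 2] == "TT"
        assert CANONICAL_MOTIFS == {"64PP": "CTCA", "CPD": "TT"}

    def test_minus_strand_motif_on_planted_strand(self):
        cfg = rp.SimConfig(seed=3, chrom_lengths={"chrS1": 10_000},
                           samples=[rp.SampleSpec("s1", "1min", "rep1", 5000)],
                           planted_hotspots=[rp.PlantedSpot("chrS1", 500, 550, "-", 50.0, 1.0)])
        g = rp.simulate_genome(cfg)
        minus = rp.revcomp(g.sequences["chrS1"][500:550])
        assert "CTCA" in minus

    def test_deterministic(self):
        a = rp.simulate_genome(_one_spot_config())
        b = rp.simulate_genome(_one_spot_config())
        assert a.sequences == b.sequences

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="outside chromosome bounds"):
            rp.SimConfig(seed=0, chrom_lengths={"chrS1": 1000},
                         samples=[rp.SampleSpec("s", "1min", "r", 10)],
                         planted_hotspots=[rp.PlantedSpot("chrS1", 900, 1100)])

    def test_hotspot_coldspot_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            rp.SimConfig(seed=0, chrom_lengths={"chrS1": 10_000},
                         samples=[rp.SampleSpec("s", "1min", "r", 10)],
                         planted_hotspots=[rp.PlantedSpot("chrS1", 500, 550)],
                         planted_coldspots=[rp.PlantedSpot("chrS1", 540, 590)])


class TestXrseqReads:
    def test_homogeneous_null_mean(self):
        # no planting, no biases: per-bin counts i.i.d. Poisson(N / bins-per-strand)
        cfg = rp.SimConfig(seed=5, chrom_lengths={"chrS1": 100_000},
                           samples=[rp.SampleSpec("s1", "1min", "rep1", 20_000)],
                           beta_dispersion=0.0, tc_bias_strength=0.0)
        g = rp.simulate_genome(cfg)
        reads = rp.simulate_xrseq_reads(cfg, g)["s1"]
        bins = rp.make_bins(g.sizes, 50)
        col, _ = rp.count_reads_per_bin(reads, bins, "+", assign="5prime")
        mean_expected = 20_000 / bins.n_bins
        se = np.sqrt(mean_expected / bins.n_bins)
        assert abs(col.mean() - mean_expected) < 3 * se

    def test_planted_hotspot_exceeds_null_quantile(self):
        # early-enriched bin beats the 99.9th percentile of non-planted bins
        exceed = 0
        n_seeds = 15
        for seed in range(n_seeds):
            cfg = rp.SimConfig(
                seed=seed, chrom_lengths={"chrS1": 100_000},
                samples=[rp.SampleSpec("e", "1min", "rep1", 2000),
                         rp.SampleSpec("l", "4h", "rep1", 2000)],
                planted_hotspots=[rp.PlantedSpot("chrS1", 50_000, 50_050, "+", 50.0, 0.1)],
            )
            g = rp.simulate_genome(cfg)
            Y = simulate_count_matrix(cfg, g, "+")
            planted_bin = 1000
            others = np.delete(Y.Y[:, 0], planted_bin)
            if Y.Y[planted_bin, 0] > np.quantile(others, 0.999):
                exceed += 1
        assert exceed >= n_seeds - 1

    def test_doubling_library_size_doubles_total(self):
        base, doubled = [], []
        for lib, sink in ((1_000_000, base), (2_000_000, doubled)):
            cfg = rp.SimConfig(seed=9, chrom_lengths={"chrS1": 500_000},
                               samples=[rp.SampleSpec("s1", "1min", "rep1", lib)])
            g = rp.simulate_genome(cfg)
            sink.append(len(rp.simulate_xrseq_reads(cfg, g)["s1"]))
        assert abs(doubled[0] / base[0] - 2.0) < 0.02

    def test_determinism_and_bounds(self, small_config, small_genome, small_reads):
        again = rp.simulate_xrseq_reads(small_config, small_genome)
        for sid, rs in small_reads.items():
            pd.testing.assert_frame_equal(rs.df, again[sid].df)
            sizes = rs.df["chrom"].map(small_genome.sizes)
            assert (rs.df["start"] >= 0).all() and (rs.df["end"] <= sizes).all()

    def test_excessive_folds_rejected(self):
        cfg = _one_spot_config()
        cfg.planted_hotspots[0].fold_early = 1e6
        g = rp.simulate_genome(cfg)
        with pytest.raises(ValueError, match="exceed 10x"):
            rp.simulate_xrseq_reads(cfg, g)

    def test_goodness_of_fit_against_model(self):
        # binned GOF of null counts against Poisson(N*beta*f): stratum sums
        # are Poisson, so the standardized chi-square has ~50 df
        fails = 0
        n_seeds = 12
        for seed in range(n_seeds):
            samples = [rp.SampleSpec("s1", "1min", "rep1", 10_000)]
            cfg = rp.SimConfig(seed=100 + seed, chrom_lengths={"chrS1": 100_000},
                               samples=samples)
            g = rp.simulate_genome(cfg)
            lam = rp.expected_bin_means(cfg, g)["+"]["lambda"][:, 0]
            Y = simulate_count_matrix(cfg, g, "+").Y[:, 0]
            order = np.argsort(lam)
            strata = np.array_split(order, 50)
            chi2 = sum((Y[s].sum() - lam[s].sum()) ** 2 / lam[s].sum() for s in strata)
            p = stats.chi2.sf(chi2, df=50)
            fails += p < 0.01
        assert fails <= max(1, int(0.05 * n_seeds))


class TestDamageReads:
    def test_uniform_low_intensity_never_reaches_threshold(self):
        # Poisson tail bound: P(X >= 10 | mu=0.01) ~ 2.6e-24 per position
        cfg = rp.SimConfig(seed=2, chrom_lengths={"chrS1": 100_000},
                           samples=[rp.SampleSpec("d", "0", "r", 100)])
        g = rp.simulate_genome(cfg)
        prof = {("chrS1", "+"): np.full(100_000, 0.01)}
        reads = rp.simulate_damage_reads(cfg, g, prof)
        pile, _ = rp.infer_damage_positions(reads, g.sizes)
        assert (pile["count"] < 10).all()

    def test_high_intensity_position_called(self):
        cfg = rp.SimConfig(seed=4, chrom_lengths={"chrS1": 10_000},
                           samples=[rp.SampleSpec("d", "0", "r", 100)])
        g = rp.simulate_genome(cfg)
        prof = {("chrS1", "+"): np.zeros(10_000)}
        prof[("chrS1", "+")][5000] = 50.0
        # P(X >= 10 | mu=50) > 0.999 by the Poisson CDF
        assert stats.poisson.sf(9, 50) > 0.999
        reads = rp.simulate_damage_reads(cfg, g, prof)
        pile, _ = rp.infer_damage_positions(reads, g.sizes)
        hot = rp.call_damage_hotspots(pile, 10)
        assert list(hot["pos"]) == [5000]

    def test_empty_profile_empty_reads(self):
        cfg = rp.SimConfig(seed=4, chrom_lengths={"chrS1": 1000},
                           samples=[rp.SampleSpec("d", "0", "r", 100)])
        g = rp.simulate_genome(cfg)
        reads = rp.simulate_damage_reads(cfg, g, {("chrS1", "+"): np.zeros(1000)})
        assert len(reads) == 0


class TestAnnotations:
    def _spots(self, cfg, n=20):
        rng = np.random.default_rng(123)
        s = rp.sample_random_spots(n, 50, cfg.chrom_lengths, seed=rng)
        s["strand"] = "+"
        return s

    def test_colocation_zero_matches_coverage(self):
        # uniform placement: spot overlap proportion ~ dilated coverage
        props, expected = [], []
        for seed in range(15):
            cfg = rp.SimConfig(seed=seed, chrom_lengths={"chrS1": 200_000},
                               samples=[rp.SampleSpec("s", "1min", "r", 100)])
            spots = self._spots(cfg, 40)
            ann = rp.simulate_annotations(cfg, spots, 0.0, n_intervals=30, width=1000)
            props.append(rp.overlap_proportion(spots, ann))
            # oracle: fraction of legal 50-bp placements hitting the annotation
            hit = np.zeros(200_000 - 50 + 1, dtype=bool)
            for r in ann.df.itertuples():
                hit[max(0, r.start - 49) : r.end] = True
            expected.append(hit.mean())
        diff = np.mean(props) - np.mean(expected)
        se = np.std(props) / np.sqrt(len(props))
        assert abs(diff) < 3 * max(se, 1e-3)

    def test_colocation_one_covers_every_spot(self):
        cfg = rp.SimConfig(seed=3, chrom_lengths={"chrS1": 200_000},
                           samples=[rp.SampleSpec("s", "1min", "r", 100)])
        spots = self._spots(cfg)
        ann = rp.simulate_annotations(cfg, spots, 1.0, n_intervals=40, width=1000)
        assert rp.overlap_proportion(spots, ann) == 1.0

    def test_colocation_half_exact_count(self):
        cfg = rp.SimConfig(seed=8, chrom_lengths={"chrS1": 500_000},
                           samples=[rp.SampleSpec("s", "1min", "r", 100)])
        spots = self._spots(cfg, 30)
        ann = rp.simulate_annotations(cfg, spots, 0.5, n_intervals=200, width=500)
        overlapping = 0
        for r in ann.df.itertuples():
            sub = spots[spots["chrom"] == r.chrom]
            overlapping += int(((sub["start"] < r.end) & (r.start < sub["end"])).any())
        assert overlapping == 100

    def test_colocation_validation(self):
        cfg = rp.SimConfig(seed=1, chrom_lengths={"chrS1": 10_000},
                           samples=[rp.SampleSpec("s", "1min", "r", 100)])
        with pytest.raises(ValueError, match="co_location"):
            rp.simulate_annotations(cfg, self._spots(cfg, 2), 1.5)


class TestGeneSimulation:
    def _cfg(self, ts, seed=0):
        return rp.SimConfig(seed=seed, chrom_lengths={"chrS1": 200_000},
                            samples=[rp.SampleSpec("s1", "1min", "rep1", 1000)],
                            ts_fraction_per_gene=ts)

    def test_symmetric_ts_fraction_averages_half(self):
        cfg = self._cfg(0.5)
        g = rp.simulate_genome(cfg)
        genes, reads = rp.simulate_gene_annotation(cfg, g, n_genes=50,
                                                   reads_per_gene_mean=100)
        counts = rp.assign_reads_to_genes(reads["s1"], genes)
        ratio = counts["ts"] / (counts["ts"] + counts["nts"])
        se = ratio.std() / np.sqrt(len(ratio))
        assert abs(ratio.mean() - 0.5) < 3 * se

    def test_full_ts_fraction_all_transcribed(self):
        cfg = self._cfg(1.0)
        g = rp.simulate_genome(cfg)
        genes, reads = rp.simulate_gene_annotation(cfg, g, n_genes=20,
                                                   reads_per_gene_mean=50)
        counts = rp.assign_reads_to_genes(reads["s1"], genes)
        assert (counts["nts"] == 0).all()
        assert (counts["ts"] > 0).all()
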