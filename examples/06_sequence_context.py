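"""Damage-centered sequence context of hotspot reads.

Excision-product reads mapped to hotspots are centered on their damage
dinucleotide (located by scanning near the 3' end) and trimmed to 15 bp;
per-position nucleotide frequencies reveal the canonical CTCA core of
(6-4)PP lesions and the planted cytosine-rich flanks.
"""

import numpy as np
import pandas as pd

import repairspot as rp
from repairspot.pipeline import split_reads_by_spots

cfg = rp.SimConfig(
    seed=16, chrom_lengths={"chrS1": 200_000},
    samples=[rp.SampleSpec("early", "1min", "rep1", 4000)],
    planted_hotspots=[rp.PlantedSpot("chrS1", s, s + 50, "+", 200.0, 1.0)
                      for s in np.linspace(10_000, 190_000, 60).astype(int)],
    flank_c_fraction=0.5,
)
genome = rp.simulate_genome(cfg)
reads = rp.simulate_xrseq_reads(cfg, genome)["early"]
spots = pd.DataFrame([(s.chrom, s.start, s.end, s.strand)
                      for s in cfg.planted_hotspots],
                     columns=["chrom", "start", "end", "strand"])

spot_reads, random_reads = split_reads_by_spots(reads.df, spots,
                                                np.random.default_rng(3))
spot_m = rp.pool_matrices(rp.nucleotide_frequency(
    rp.ReadSet(df=spot_reads, damage_type="64PP"), genome=genome))
rand_m = rp.pool_matrices(rp.nucleotide_frequency(
    rp.ReadSet(df=random_reads, damage_type="64PP"), genome=genome))

print(f"{spot_m.n_reads} hotspot reads, {rand_m.n_reads} random reads")
print("\nhotspot frequencies around the damage site (positions -2..+2):")
print(spot_m.to_frame().loc[-2:2].round(2).to_string())

cmp = rp.compare_c_enrichment(spot_m, rand_m)
print(f"\nmean flank cytosine excess over random reads: "
      f"{cmp.attrs['mean_delta']:+.3f}")
print(f"flank positions significant after BH correction: "
      f"{int(cmp['significant'].sum())}/{cmp['significant'].notna().sum()}")
print("\nThe core shows T at 0 and C at +1 (the TC of the CTCA photoproduct);")
print("flanks are cytosine-enriched relative to reads drawn off-hotspot.")
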