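"""Simulate a miniature XR-seq time course and call repair super hotspots.

Builds the canonical synthetic study (eight samples, 20 planted hotspots,
10 planted coldspots on two 100-kb chromosomes), runs read QC, depth
equalization, 50-bp binning, and the replicate-wise threshold rule
(>= 15 reads in both 1-min replicates, <= 5 in both 4-h replicates for
hotspots), then compares the calls with the planted truth.
"""

import pandas as pd

import repairspot as rp

cfg = rp.fixture_config(seed=1, scale="small")
genome = rp.simulate_genome(cfg)
reads = rp.simulate_xrseq_reads(cfg, genome)

bins = rp.make_bins(genome.sizes, cfg.bin_width)
readsets = [rp.filter_reads(rp.deduplicate_reads(reads[s.sample_id]))
            for s in cfg.samples]
depth = min(len(r) for r in readsets)
rule = rp.ThresholdRule(
    early=[s.sample_id for s in cfg.samples if s.time_point == "1min"],
    late=[s.sample_id for s in cfg.samples if s.time_point == "4h"],
)

calls = []
for strand in "+-":
    Y = rp.build_count_matrix(readsets, bins, strand, depth=depth, seed=1)
    calls.append(rp.call_spots(Y, rule))
spots = pd.concat(calls, ignore_index=True)

hot = spots[spots["category"] == "hotspot"]
planted = {(s.chrom, s.start, s.strand) for s in cfg.planted_hotspots}
called = set(zip(hot["chrom"], hot["start"], hot["strand"]))

print(f"samples downsampled to {depth} reads each")
print(f"hotspots called: {len(hot)}  (planted: {len(planted)})")
print(f"recovered planted hotspots: {len(called & planted)}")
print(f"false calls: {len(called - planted)}")
print("\nEach called hotspot is a 50-bp bin repaired almost completely within")
print("one minute; a perfect run recovers all 20 planted bins with no extras.")
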