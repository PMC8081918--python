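"""Single-nucleotide damage mapping and regional damage quantification.

Damage-seq reads start immediately 3' of the lesion, so read 5' ends pin
lesions exactly. We plant a uniform lesion field plus a few intense sites,
recover them, and show that damage counts over repair hotspot / coldspot /
random regions are statistically indistinguishable when damage is uniform.
"""

import numpy as np
import pandas as pd

import repairspot as rp

cfg = rp.SimConfig(seed=7, chrom_lengths={"chrS1": 100_000},
                   samples=[rp.SampleSpec("damage", "0h", "r", 100)])
genome = rp.simulate_genome(cfg)

profile = {("chrS1", "+"): np.full(100_000, 0.02),
           ("chrS1", "-"): np.full(100_000, 0.02)}
intense = [10_000, 40_000, 70_000]
for pos in intense:
    profile[("chrS1", "+")][pos] = 30.0

reads = rp.simulate_damage_reads(cfg, genome, profile)
pileup, skipped = rp.infer_damage_positions(reads, genome.sizes)
hot = rp.call_damage_hotspots(pileup, min_reads=10, genome=genome)
print(f"{len(reads)} damage reads -> {len(pileup)} lesion positions "
      f"({skipped} out of bounds)")
print(f"damage hotspots (>= 10 reads): {list(hot['pos'])}  planted: {intense}")

rng = np.random.default_rng(1)
cats = []
for name in ("hotspot", "coldspot", "random"):
    r = rp.sample_random_spots(20, 50, genome.sizes, seed=rng)
    r["category"] = name
    cats.append(r)
background = pileup[~pileup["pos"].isin(intense)]
table = rp.quantify_damage_in_regions(background, pd.concat(cats), genome.sizes,
                                      extensions=(0, 20, 500))
kw = rp.compare_damage_by_category(table)
print("\nKruskal-Wallis across categories (uniform background damage):")
print(kw.round(3).to_string(index=False))
print("\np-values well above 0.01 at every flank extension: regions that")
print("differ in repair speed carry the same amount of initial damage.")
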