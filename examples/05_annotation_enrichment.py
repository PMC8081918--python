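"""Bootstrap overlap enrichment of hotspots with FIRE-like annotations.

The observed fraction of spots overlapping an annotation is compared with
a bootstrap null: width- and chromosome-matched random regions drawn from
the unmasked genome. Here 30% of the annotation intervals are planted on
the spots, so the observed proportion clears the null by a wide margin.
"""

import numpy as np

import repairspot as rp

sizes = {"chrS1": 100_000, "chrS2": 100_000}
cfg = rp.SimConfig(seed=3, chrom_lengths=sizes,
                   samples=[rp.SampleSpec("s", "1min", "r", 100)])
spots = rp.sample_random_spots(40, 50, sizes, seed=11)
spots["strand"] = "+"

fire = rp.simulate_annotations(cfg, spots, co_location=0.3, n_intervals=60,
                               width=2000, name="FIRE-like")
res = rp.bootstrap_enrichment(spots, fire, sizes, B=1000, seed=12)

print(f"observed overlap proportion: {100 * res.observed:.1f}%")
print(f"bootstrap null mean (genome average): {100 * res.null_mean:.1f}%")
print(f"annotation coverage of assembly: {100 * res.coverage_fraction:.1f}%")
print(f"empirical enrichment p-value: {res.p_enrichment:.4g}  (B = {len(res.null)})")

inter = rp.simulate_interactions(cfg, spots, n_background=80, per_spot=5,
                                 anchor_width=2000)
rnd = rp.sample_random_spots(40, 50, sizes, exclusions=spots, seed=13)
sc = rp.count_interactions_per_spot(spots, inter)
rc = rp.count_interactions_per_spot(rnd, inter)
stat, p = rp.interaction_excess_test(sc, rc)
print(f"\nmean chromatin interactions per spot: {sc.mean():.1f} "
      f"vs {rc.mean():.1f} at matched random regions (rank-sum p = {p:.2g})")
print("\nHotspots overlap the annotation far above the genome average and")
print("anchor significantly more chromatin interactions than random regions.")
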