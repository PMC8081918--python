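# repairspot

Super hotspots and super coldspots of nucleotide excision repair from
time-course XR-seq data.

XR-seq sequences the ~21–31-nt oligonucleotides that nucleotide excision
repair cuts out around a UV lesion, so each read marks a repair event at
near-nucleotide resolution. Given a time course of such samples (e.g.
1 min → 4 h after UV), `repairspot` identifies the genomic sites repaired
earliest (**super hotspots**) and latest (**super coldspots**), verifies
that they are features of repair rather than of damage formation, and
characterizes their chromatin and sequence context. It is written for
computational biologists analysing excision-repair or damage-map
sequencing data, and every stage is testable end to end on built-in
synthetic data with planted ground truth.

The pipeline:

* **Read QC** — deduplication on shared 5′/3′ ends; MAPQ > 20; lengths
  21–31 nt.
* **Spot calling** — 50-bp bins per strand, depth equalization by
  downsampling (7.7 M default), then a replicate-wise threshold: a hotspot
  bin has ≥ 15 reads in both 1-min replicates and ≤ 5 in both 4-h
  replicates (coldspots mirrored and relaxed: ≤ 2 early, ≥ 10 late);
  blacklist bins masked.
* **Normalization and testing** — the cross-sample Poisson log-linear null
  `Y_ij ~ Poisson(N_j β_i f_j(TC_i))` with a robust iterative
  maximum-likelihood fit; exact Poisson tail tests of spot enrichment with
  BH-FDR.
* **Gene-level repair** — TS/NTS separation by gene annotation, RPKM,
  the TS/(TS+NTS) transcription-coupled-repair ratio, and a PCA repair
  trajectory over the top 2000 variable genes.
* **Damage analysis** — single-nucleotide lesion maps from
  Damage-seq-style reads (read 5′ ends pin lesions), hotspots at ≥ 10
  reads, and regional damage quantification with 0/20/500-bp flank
  extensions.
* **Enrichment** — spot overlap with FIREs, superenhancers, chromatin
  states, signal tracks and Hi-C interactions against a bootstrap genome
  null of width- and chromosome-matched random regions.
* **Sequence context** — 15-bp damage-centered nucleotide frequencies of
  spot-mapped reads (CTCA core for (6-4)PP, TT for CPD) and flanking
  cytosine enrichment.

See `docs/methods.md` for models, estimators and design decisions.

## Worked example

```bash
python examples/01_simulate_and_call_spots.py
```

simulates the canonical synthetic study — eight samples (1 min ×2, 5 min,
20 min, 1 h, 2 h, 4 h ×2) on two 100-kb chromosomes with 20 planted
hotspots and 10 coldspots — and calls spots through the full QC + binning
+ threshold path:

```
samples downsampled to 7983 reads each
hotspots called: 19  (planted: 20)
recovered planted hotspots: 19
false calls: 0

Each called hotspot is a 50-bp bin repaired almost completely within
one minute; a perfect run recovers all 20 planted bins with no extras.
```

The other examples each exercise one capability: `02` fits the Poisson
null and shows a planted bin's observed 1-min count (2049) against its
null expectation (7.3, upper-tail p ≈ 0); `03` computes TS/(TS+NTS)
(≈ 0.5 on strand-symmetric data) and a PCA trajectory whose PC1 orders
samples by time (Spearman ρ = 0.99); `04` recovers planted damage hotspots
exactly and shows repair categories carry indistinguishable damage; `05`
measures annotation overlap against the bootstrap null; `06` recovers the
planted CTCA core and cytosine-rich flanks.

A thin CLI wraps the same library:

```bash
repairspot make-fixture --outdir study --seed 1
repairspot run --fixture study --outdir results --seed 1
repairspot filter-reads study/reads_1min_rep1.bed filtered.bed
```

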