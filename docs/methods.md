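# Methods

`repairspot` analyses time-course nucleotide excision repair as measured by
XR-seq — sequencing of the ~21–31-nt oligonucleotides that the repair
machinery excises around a UV lesion — together with Damage-seq-style maps
of the lesions themselves. This note records the models, the estimators,
the synthetic-data generator that stands in for sequencing data in all
tests, and the numerical and design choices a maintainer would want to
know.

## Spot calling

The genome is segmented into consecutive 50-bp bins per chromosome (the
final partial bin is kept and flagged). Reads pass post-alignment QC first:
duplicates sharing both end coordinates (and strand) collapse to the first
occurrence, then reads are kept only with mapping quality strictly above 20
and length 21–31 nt inclusive. Samples are equalized to a common depth by
uniform subsampling without replacement (the production default is 7.7
million reads per sample; synthetic studies equalize to the smallest
sample). Each read increments exactly one bin — the bin containing its 5′
end (strand-aware; configurable to midpoint) — and plus- and minus-strand
reads are binned and analysed separately.

A **repair super hotspot** is an unmasked bin with at least
`hot_min_early = 15` reads in *every* designated early replicate (the two
1-min samples for (6-4)PP) and at most `hot_max_late = 5` reads in every
late replicate (the two 4-h samples). A **super coldspot** uses the relaxed
mirror rule: at most `cold_max_early = 2` early and at least
`cold_min_late = 10` late. The coldspot thresholds are package defaults —
there is no established constant for how far to relax the rule — and they
are echoed in every output header. CPD studies call hotspots
only, from the 12-min samples, because transcription-coupled repair
dominates late CPD time points; coldspot calling for CPD raises unless
forced. Bins overlapping a blacklist interval (segmental duplications,
assembly gaps, repeats) by one or more bp are masked from calling and from
all null resampling. Adjacent qualifying bins are reported as separate
50-bp spots; an optional merge flag exists but is off by default.

## The Poisson log-linear null

Counts under no biologically relevant enrichment are modelled as

    Y_ij ~ Poisson(λ_ij),   λ_ij = N_j · β_i · f_j(TC_i)

where `N_j` is sample j's total mapped reads (fixed after depth
equalization), `β_i` a bin propensity absorbing library-preparation and
sequencing bias (Σβ = 1 per strand over unmasked bins), and `f_j` a smooth
per-sample function of the bin's T+C (pyrimidine) content fraction,
normalized to β-weighted mean one. TC content is computed on the bin's own
strand (T+C on the minus strand equals A+G on the forward sequence); Ns are
excluded from numerator and denominator and all-N bins are masked.

### Fitting

The fit is an alternating scheme with residual-based robustness:

1. **Initialization.** β from the across-sample median of `Y_ij/N_j`
   (floored and normalized). A median start matters: a bin enriched in a
   subset of time points would be absorbed into a row-sum initialization
   and never look like an outlier.
2. **Iteration 1 (untrimmed).** Closed-form β update
   `β_i ← Σ_j Y_ij / Σ_j N_j f_j(TC_i)`, then f re-estimated (below), using
   all bins — residuals from the rough initialization are not yet
   trustworthy.
3. **Trim once, then freeze.** Bins whose standardized Pearson residual
   exceeds `resid_cut = 3` in any sample are excluded from all further
   updates but retained for testing; their β is imputed as the median β of
   kept bins in the same TC stratum. The trim set is frozen after this
   pass: re-trimming every iteration lets the fit drift along the
   near-degenerate direction in which a common TC-shaped component migrates
   between β and f.
4. **Refinement.** Alternating β and f updates on the frozen kept set until
   the relative change of the Poisson log-likelihood falls below
   `tol = 1e-6` (max 50 iterations), with a safeguard that stops and
   reverts if an update fails to improve the likelihood, so the recorded
   trace is non-decreasing.

**f estimator.** Kept bins are stratified into 20 TC-content quantile
strata; each stratum's value for sample j is the symmetric 10%-trimmed mean
of `Y_ij/(N_j β_i)` (robust to residual enriched bins, far less noisy than
a median of heavily quantized ratios), smoothed across adjacent strata with
a size-weighted 3-point window — justified because f is smooth in TC by
model assumption — then linearly interpolated between stratum mean-TC
points and renormalized to weighted mean one.

**Scale.** The constraints Σβ = 1, weighted-mean f = 1, and fixed N are
jointly over-determined: reads on masked bins are counted in N but carried
by no row. A single fitted scale factor `c = ΣY/Σ(NβF)` over kept bins
absorbs this mass, so expected counts are `Λ_ij = c·N_j·β_i·f_j(TC_i)`.
Multiplying all library sizes by a constant leaves β̂ unchanged and is
absorbed entirely by `c`.

### Enrichment testing

For a spot set and a sample group sharing a time point (default: the early
replicates), counts and expectations are summed over the group (Poisson
additivity) and tested against the exact Poisson tail — upper for hotspots,
lower (depletion at early times) for coldspots — with Benjamini–Hochberg
FDR across tested bins. The reported p-value is the deterministic exact
tail, which is conservative for discrete counts. For calibration studies
the function can instead emit randomized (uniform tie-split) p-values,
`P(X > y) + U·P(X = y)`, which are exactly Uniform(0,1) under the null;
calibration is checked against the generator's true expected counts,
because any p-value computed from a model fitted on the same counts
inherits estimation noise that a large-sample uniformity test will detect
regardless of the estimator's quality.

## Gene-level repair and the trajectory

Reads overlapping a gene are assigned to the transcribed strand (TS) when
antisense to the gene's annotated strand — the orientation of excision
products relative to the template — and to the nontranscribed strand (NTS)
otherwise (`ts_convention` flag to flip; reads in overlapping genes count
once per gene by default). Gene QC keeps genes with at least 10 TT or TC
dinucleotides on either strand, length strictly below 300 kb, and at least
10 reads total across samples. RPKM normalizes within sample;
TS/(TS+NTS) ∈ [0,1] cancels strand-shared biases and quantifies the
transcription-coupled contribution. The trajectory ranks genes by variance
of log2(RPKM+1) across samples, keeps the top 2000 (or all, with a
warning), and projects samples onto the first two principal components
(full SVD); PC1's sign is fixed to increase with time-point rank when ranks
are supplied.

## Damage analysis

Damage-seq chemistry stalls a high-fidelity polymerase immediately 3′ of a
lesion, so a read's 5′ end pins the lesion: a plus-strand read starting at
s implies a lesion dinucleotide at [s−2, s); a minus-strand read ending at
e implies [e, e+2). Pileups are keyed by the leftmost base of the
dinucleotide per strand; this coordinate convention is the package's
concrete reading of the chemistry and is configurable. Damage hotspots are
single positions with at least 10 supporting reads, reported per strand.
Regional damage is quantified as the lesion-weighted count within each
region extended by 0, 20, and 500 bp on both ends (clipped to the
chromosome), strand-combined by default, and compared across repair
categories (hotspot / coldspot / random) by Kruskal–Wallis.

## Annotation enrichment

The observed statistic is the fraction of spots overlapping an annotation
by ≥ 1 bp. The null is a bootstrap over the genome: B = 1000 replicates
(configurable) each place |spots| regions, matched per chromosome and per
width, uniformly over eligible space — everything outside the blacklist and
the spots themselves — and recompute the proportion. The empirical p-value
uses the add-one formula `(1 + #{null ≥ obs})/(B + 1)` (never zero), with
the depletion tail mirrored and two-sided as twice the smaller tail. The
null mean estimates the "genome average" overlap; note this equals the
annotation's coverage *dilated by the spot width minus one* over eligible
placements, slightly above raw base coverage, and both numbers are
reported. Interactions (BEDPE) are counted per spot as records with at
least one anchor overlapping the spot (spots can be expanded to a
containing coarse anchor bin, e.g. 40 kb, to match contact-map resolution)
and compared against matched random regions by one-sided rank-sum.
Per-base signal tracks are averaged over spots via prefix integrals of the
piecewise-constant track, missing positions counting as zero. Labelled
state annotations assign each spot to its largest-overlap label
(alphabetical tie-break).

## Sequence context

Reads mapped to a spot set are centred on the 5′ base of their damage
dinucleotide and trimmed/extended to 15 bases (7 flanks each side; genome
fill where the window leaves the read). The anchor is located by scanning a
window 9 to 4 nt from the read's 3′ end for the canonical dipyrimidine (TT
or TC for CPD; TC, preferring a CTCA context, for (6-4)PP), choosing the
candidate closest to 6 nt from the 3′ end with ties resolved 3′-ward, and
falling back (flagged) to exactly 6 nt when none is found. Both the window
and the 6-nt offset reflect the known excision geometry of the assay and
are configurable; the synthetic generator uses the same offset, making the
pair an exact inverse on synthetic reads. Per-position strand-specific
A/C/G/T frequencies are tallied; cytosine enrichment of spot reads over a
reference matrix is the per-flank-position frequency difference with a
two-proportion z-test per position (BH-corrected), the damage dinucleotide
positions (0, +1) excluded.

## The synthetic-data generator

The generator emulates exactly the structure the analysis assumes, so every
stage can be verified with planted truth.

* **Genome.** I.i.d. background bases (default uniform) on chromosomes
  named `chrS1…` (never colliding with real assemblies). Every planted
  hotspot/coldspot carries the canonical damage motif (CTCA for (6-4)PP, TT
  for CPD) with 6-bp cytosine-weighted flanks (default C fraction 0.4) on
  the planted strand. Each bin of a planted interval holds **three** motif
  anchors per strand, at offsets chosen so reads generated there keep their
  5′ ends inside the bin: a repair hotspot is a cluster of excision
  products at several nearby lesions, and a single shared endpoint would be
  annihilated by deduplication.
* **XR-seq reads.** Per strand, `β` is drawn log-normal (σ =
  `beta_dispersion`) and normalized; `f_j = exp(b_j·(TC−TC̄))` with
  `b_j ~ N(0, tc_bias_strength)`, normalized to weighted mean one; bin
  counts are Poisson with mean `N_j·β_i·f_j·e_ij`, where the planted fold
  `e_ij` applies at early/late time points of planted spots and is one
  elsewhere (`library_size` is the per-strand expected total). Reads place
  the lesion 6 nt from their 3′ end (configurable), uniform length 21–31,
  MAPQ 60; reads at planted bins anchor on a planted motif. A configuration
  whose expected totals exceed 10× the library size is rejected.
  `simulate_count_matrix` short-circuits the read layer and draws bin
  counts directly from the same seeded model — the exact null for
  estimator-recovery and calibration studies, free of the ±1-bin smoothing
  that 5′-end assignment of 21–31-nt reads introduces.
* **Damage reads** start immediately 3′ of lesions drawn Poisson from a
  per-position intensity profile; the read↔lesion mapping is an exact
  inverse of `infer_damage_positions` (boundary reads that would leave the
  chromosome are dropped and tallied rather than shifted, to keep the
  round-trip exact).
* **Annotations.** `round(co_location·n)` intervals are centred on spots
  (cycling, so full co-location covers every spot); the remainder is
  uniform — avoiding spots entirely when co_location > 0 so forced counts
  are exact, and purely uniform at co_location = 0 so chance overlap
  matches coverage. Interactions add a configurable per-spot anchor excess
  over a uniform background.
* **Genes.** Non-overlapping genes with reads assigned to the transcribed
  strand with probability `ts_fraction_per_gene`; an optional per-gene
  log-linear time trend (`time_trend_sd`) produces the monotone structure
  used by trajectory tests.
* **Randomness.** One seeded generator stream per operation
  (`(seed, operation-id)`); identical configurations reproduce
  byte-identical outputs.

**Defaults.** `beta_dispersion = 0.5` and `tc_bias_strength = 0.5` as
package defaults (real-data magnitudes of these biases are not established;
the values give clearly visible but not overwhelming structure). The
canonical study (`fixture_config`) uses dispersion 0.3 and TC strength 0.3
with 20 hotspots (fold 50 early, 0.05 late) and 10 coldspots (0.02 early,
30 late) at baseline one read per bin per strand across eight samples
(1 min ×2, 5 min, 20 min, 1 h, 2 h, 4 h ×2): modest dispersion keeps a
fold-50 planting reliably above the 15-read threshold at that depth.
Estimator-recovery studies instead use dispersion 0.7, where propensity
spread rather than Poisson noise dominates, which is the regime a
correlation-based recovery measure is about. Problem sizes in the test
suite (2×100-kb chromosomes for calling studies; 10,000 bins × 6 samples at
mean depth 5 for model recovery; B = 200–5000 bootstrap replicates; 20–200
seeds per multi-seed property) were chosen so the full suite completes in
well under a minute of compute per module while leaving the measured
quantities' standard errors far inside the asserted tolerances.

### What the generator does not emulate

Mappability structure, adapter/sequencing errors, fragment GC bias beyond
the single TC covariate, overdispersion (the model and generator are
exactly Poisson), correlated replicates, copy-number variation, and real
blacklist geometry. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not robustness to every artifact of
real libraries; the robust trimming and blacklist machinery are exercised
against planted analogues of those artifacts only.

## Degenerate inputs and numerical notes

Empty read sets and empty profiles flow through (empty outputs); an empty
spot set makes an overlap proportion undefined and raises; a sample with
zero unmasked counts, a constant expression matrix, fewer than two samples,
or fewer than 100 unmasked bins are errors. Reads on unknown chromosomes or
with out-of-bounds assignment points are tallied and skipped, never raised.
β is floored at `0.1/n_bins`-scale quantities only after normalization so
the fit is invariant to rescaling all library sizes. Bootstrap placements
may overlap each other (resampling) but never the exclusions. All
coordinates are 0-based half-open; minus-strand sequence operations use the
reverse complement consistently, and frequency matrices satisfy exact
strand symmetry under reverse-complementing the data.

## Known limitations

Coldspot thresholds are a package default, not an established constant.
The lesion-position offset inside excision products (6 nt from the 3′ end)
is an assumption shared between generator and locator; real libraries show
a distribution of offsets. The Poisson model has no overdispersion
extension. Interaction counting treats anchors as plain intervals and does
not model contact-matrix normalization. The CLI covers simulation, read QC,
spot calling and the full run; the finer-grained stages are exposed through
the Python API and `examples/`.
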