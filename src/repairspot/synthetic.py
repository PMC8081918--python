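"""Synthetic miniature genomes, XR-seq / Damage-seq read sets, and annotations.

The generator reproduces the statistical structure the downstream analysis
assumes, so every stage can be exercised with known ground truth:

* per-bin XR-seq counts follow the Poisson log-linear null
  Y_ij ~ Poisson(N_j * beta_i * f_j(TC_i) * e_ij), with beta_i drawn
  log-normal and normalized per strand, f_j = exp(b_j * (TC_i - mean TC))
  normalized to weighted mean 1, and e_ij the planted enrichment fold
  (1 outside planted spots);
* planted hotspots/coldspots carry a canonical damage motif (CTCA for
  (6-4)PP, TT for CPD) with cytosine-weighted 6-bp flanks on the planted
  strand, elsewhere bases are i.i.d. background;
* Damage-seq-style reads start immediately 3' of a lesion whose position is
  drawn from a per-base intensity profile;
* annotation sets (FIRE-like, superenhancer-like, BEDPE interactions) with
  controllable co-location with spots; gene annotations with controllable
  TS/NTS read asymmetry.

Randomness: each operation draws from its own generator seeded by
(config.seed, operation id), so operations are individually reproducible
and the draw order within each operation is documented in its docstring.

Chromosomes are named "chrS1", "chrS2", ... to avoid collision with real
assemblies. ``library_size`` is the expected read total per strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnnotationSet, ReadSet, ReferenceGenome, revcomp
from .null_model import compute_tc_content
from .spots import BinIndex, make_bins

# per-operation seed-stream ids
_OP_GENOME, _OP_XRSEQ, _OP_DAMAGE, _OP_ANNOT, _OP_GENES, _OP_INTERACT = range(1, 7)

CANONICAL_MOTIFS = {"64PP": "CTCA", "CPD": "TT"}
# index of the lesion dinucleotide's 5' base within the canonical motif
_MOTIF_LESION_INDEX = {"64PP": 1, "CPD": 0}


@dataclass
class SampleSpec:
    """One simulated XR-seq sample (time point x replicate)."""

    sample_id: str
    time_point: str
    replicate: str = "rep1"
    library_size: int = 100_000


@dataclass
class PlantedSpot:
    """A planted enrichment interval with early/late multiplicative folds."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    fold_early: float = 1.0
    fold_late: float = 1.0


@dataclass
class SimConfig:
    """Full description of one synthetic study.

    ``beta_dispersion`` is the log-normal sigma of per-bin propensities;
    ``tc_bias_strength`` the standard deviation of the per-sample slope b_j
    in f_j = exp(b_j * (TC - mean TC)); ``lesion_offset`` the distance (nt)
    of the lesion dinucleotide's 5' base from a read's 3' end.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chrS1": 100_000})
    samples: list[SampleSpec] = field(default_factory=list)
    bin_width: int = 50
    planted_hotspots: list[PlantedSpot] = field(default_factory=list)
    planted_coldspots: list[PlantedSpot] = field(default_factory=list)
    beta_dispersion: float = 0.5
    tc_bias_strength: float = 0.5
    read_length_range: tuple[int, int] = (21, 31)
    damage_type: str = "64PP"
    ts_fraction_per_gene: float = 0.5
    early_timepoints: tuple[str, ...] = ("1min",)
    late_timepoints: tuple[str, ...] = ("4h",)
    flank_c_fraction: float = 0.4
    background_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lesion_offset: int = 6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0 or length % self.bin_width:
                raise ValueError(
                    f"chromosome {chrom!r} length {length} must be a positive "
                    f"multiple of bin_width={self.bin_width}"
                )
        for s in self.samples:
            if s.library_size <= 0:
                raise ValueError(f"sample {s.sample_id!r} has non-positive library size")
        if self.damage_type not in CANONICAL_MOTIFS:
            raise ValueError(f"damage_type must be one of {sorted(CANONICAL_MOTIFS)}")
        if self.beta_dispersion < 0:
            raise ValueError("beta_dispersion must be >= 0")
        lo, hi = self.read_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid read_length_range")
        if not 0.0 <= self.ts_fraction_per_gene <= 1.0:
            raise ValueError("ts_fraction_per_gene must lie in [0, 1]")
        for spot in self.planted_hotspots + self.planted_coldspots:
            if spot.chrom not in self.chrom_lengths:
                raise ValueError(f"planted interval on unknown chromosome {spot.chrom!r}")
            if not (0 <= spot.start < spot.end <= self.chrom_lengths[spot.chrom]):
                raise ValueError(
                    f"planted interval {spot.chrom}:{spot.start}-{spot.end} "
                    "outside chromosome bounds"
                )
        # hotspot and coldspot intervals must be mutually disjoint
        for h in self.planted_hotspots:
            for c in self.planted_coldspots:
                if h.chrom == c.chrom and h.start < c.end and c.start < h.end:
                    raise ValueError(
                        f"planted hotspot {h.chrom}:{h.start}-{h.end} overlaps "
                        f"coldspot {c.chrom}:{c.start}-{c.end}"
                    )

    @property
    def all_planted(self) -> list[PlantedSpot]:
        return list(self.planted_hotspots) + list(self.planted_coldspots)

    def time_ranks(self) -> dict[str, int]:
        """Rank of each time-point label in first-appearance order."""
        order: dict[str, int] = {}
        for s in self.samples:
            order.setdefault(s.time_point, len(order))
        return order


def _anchor_offsets(config: SimConfig, strand: str, n_anchors: int = 3) -> np.ndarray:
    """Within-bin offsets of planted lesion positions for one strand.

    A repair hotspot is a cluster of excision products at several nearby
    lesion sites, not a single endpoint — several anchors per bin keep read
    endpoints diverse enough to survive endpoint deduplication. Offsets are
    chosen so the 5' ends of reads generated at each anchor stay inside the
    anchor's bin under the configured read geometry.
    """
    lmax = config.read_length_range[1]
    off = config.lesion_offset
    w = config.bin_width
    if strand == "+":
        lo, hi = min(lmax - off, w - 4), w - 1
    else:
        lo, hi = 2, max(2, w - 2 - lmax + off)
    if hi < lo:
        lo = hi
    return np.unique(np.linspace(lo, hi, n_anchors).astype(np.int64))


def planted_anchors(spot: PlantedSpot, config: SimConfig) -> np.ndarray:
    """Genome positions (leftmost base) of the planted lesion dinucleotides.

    Anchors tile every bin the interval overlaps; positions falling outside
    the interval's chromosome are the caller's responsibility (validated by
    the config).
    """
    offsets = _anchor_offsets(config, spot.strand)
    first_bin = (spot.start // config.bin_width) * config.bin_width
    last_bin = ((spot.end - 1) // config.bin_width) * config.bin_width
    bins = np.arange(first_bin, last_bin + 1, config.bin_width)
    return (bins[:, None] + offsets[None, :]).ravel()


def simulate_genome(config: SimConfig) -> ReferenceGenome:
    """Background i.i.d. genome with canonical damage motifs at planted spots.

    Draw order: per-chromosome background bases (in chrom_lengths order),
    then per planted spot (hotspots then coldspots, in listed order) the two
    cytosine-weighted 6-bp flanks.
    """
    rng = np.random.default_rng([config.seed, _OP_GENOME])
    bases = np.array(list("ACGT"))
    seqs = {}
    for chrom, length in config.chrom_lengths.items():
        seqs[chrom] = rng.choice(bases, size=length, p=config.background_base_probs)

    motif = CANONICAL_MOTIFS[config.damage_type]
    q = _MOTIF_LESION_INDEX[config.damage_type]
    cf = config.flank_c_fraction
    flank_probs = np.array([(1 - cf) / 3, cf, (1 - cf) / 3, (1 - cf) / 3])
    for spot in config.all_planted:
        for anchor in planted_anchors(spot, config):
            flanks = rng.choice(bases, size=12, p=flank_probs)
            ctx = "".join(flanks[:6]) + motif + "".join(flanks[6:])
            w = 6 + q  # index of lesion 5' base within ctx
            if spot.strand == "+":
                g0 = anchor - w
                written = ctx
            else:
                g0 = (anchor + 1) + w - len(ctx) + 1
                written = revcomp(ctx)
            if g0 < 0 or g0 + len(ctx) > config.chrom_lengths[spot.chrom]:
                raise ValueError(
                    f"planted interval {spot.chrom}:{spot.start}-{spot.end} too close "
                    "to a chromosome end to hold its motif context"
                )
            seqs[spot.chrom][g0 : g0 + len(ctx)] = list(written)
    return ReferenceGenome(sequences={c: "".join(s) for c, s in seqs.items()})


def expected_bin_means(
    config: SimConfig, genome: ReferenceGenome
) -> dict[str, dict[str, np.ndarray]]:
    """True per-bin expected counts per strand and sample (the generator's lambda).

    Returns {strand: {"lambda": (bins x samples), "beta": ..., "f": ...}}.
    Uses the same seeded stream as :func:`simulate_xrseq_reads`, so the
    parameters here are exactly those the read simulator uses.
    """
    rng = np.random.default_rng([config.seed, _OP_XRSEQ])
    return _draw_model(config, genome, rng)


def _draw_model(config, genome, rng):
    bins = make_bins(genome.sizes, config.bin_width)
    nb = bins.n_bins
    N = np.array([s.library_size for s in config.samples], dtype=float)
    slopes = rng.normal(0.0, config.tc_bias_strength, size=len(config.samples))
    out = {}
    for strand in ("+", "-"):
        beta = rng.lognormal(0.0, config.beta_dispersion, size=nb) if config.beta_dispersion > 0 \
            else np.ones(nb)
        beta /= beta.sum()
        tc = compute_tc_content(bins, genome, strand)
        tc_bar = float(np.sum(beta * tc))
        F = np.exp(slopes[None, :] * (tc[:, None] - tc_bar))
        F /= (beta[:, None] * F).sum(axis=0)[None, :]
        fold = np.ones((nb, len(config.samples)))
        offsets = _anchor_offsets(config, strand)
        anchors: dict[int, np.ndarray] = {}
        for spot in config.all_planted:
            if spot.strand != strand:
                continue
            idx = bins.bins_overlapping(spot.chrom, spot.start, spot.end)
            for j, s in enumerate(config.samples):
                if s.time_point in config.early_timepoints:
                    fold[idx, j] = spot.fold_early
                elif s.time_point in config.late_timepoints:
                    fold[idx, j] = spot.fold_late
            for b in idx:
                anchors[int(b)] = bins.starts[b] + offsets
        lam = N[None, :] * beta[:, None] * F * fold
        out[strand] = {"lambda": lam, "beta": beta, "f": F, "tc": tc,
                       "anchors": anchors, "bins": bins}
    return out


def simulate_count_matrix(config: SimConfig, genome: ReferenceGenome, strand: str = "+"):
    """Bin counts drawn directly from the planted Poisson model (no reads).

    Returns a :class:`~repairspot.spots.BinCountMatrix` whose counts are
    Y_ij ~ Poisson(N_j beta_i f_j(TC_i) e_ij) with the same seeded model
    parameters that :func:`simulate_xrseq_reads` uses — the exact null for
    estimator-recovery and calibration studies, free of read-geometry
    smoothing.
    """
    from .spots import BinCountMatrix

    rng = np.random.default_rng([config.seed, _OP_XRSEQ])
    model = _draw_model(config, genome, rng)
    m = model[strand]
    Y = rng.poisson(m["lambda"])
    samples = pd.DataFrame(
        [(s.sample_id, s.time_point, s.replicate) for s in config.samples],
        columns=["sample_id", "time_point", "replicate"],
    )
    N = np.array([s.library_size for s in config.samples], dtype=float)
    return BinCountMatrix(Y=Y, strand=strand, bins=m["bins"], samples=samples,
                          N=N, tc=m["tc"])


def simulate_xrseq_reads(config: SimConfig, genome: ReferenceGenome) -> dict[str, ReadSet]:
    """Per-sample XR-seq read sets drawn from the planted Poisson model.

    Draw order: per-sample TC-bias slopes; then per strand (+ before -) the
    per-bin propensities; then per sample x strand the per-bin Poisson
    counts, per-read offsets within bins, and per-read lengths. Reads place
    the lesion dinucleotide ``lesion_offset`` nt from their 3' end; reads at
    planted bins anchor at the planted motif. Reads falling off a chromosome
    end are shifted inside, so every realized Poisson count yields a read.
    """
    rng = np.random.default_rng([config.seed, _OP_XRSEQ])
    model = _draw_model(config, genome, rng)
    lo, hi = config.read_length_range
    off = config.lesion_offset
    results: dict[str, ReadSet] = {}
    for j, sample in enumerate(config.samples):
        lam_tot = sum(model[s]["lambda"][:, j].sum() for s in ("+", "-"))
        if lam_tot > 10 * 2 * sample.library_size:
            raise ValueError(
                f"sample {sample.sample_id!r}: expected total reads {lam_tot:.0f} "
                f"exceed 10x the requested library size; reduce enrichment folds"
            )
        frames = []
        for strand in ("+", "-"):
            m = model[strand]
            bins: BinIndex = m["bins"]
            counts = rng.poisson(m["lambda"][:, j])
            total = int(counts.sum())
            if total == 0:
                continue
            bin_idx = np.repeat(np.arange(bins.n_bins), counts)
            widths = (bins.ends - bins.starts)[bin_idx]
            anchors = bins.starts[bin_idx] + (rng.random(total) * widths).astype(np.int64)
            if m["anchors"]:
                planted_bins = np.array(sorted(m["anchors"]))
                planted_pos = np.vstack([m["anchors"][b] for b in planted_bins])
                loc = np.searchsorted(planted_bins, bin_idx)
                hit = (loc < len(planted_bins)) & (planted_bins[np.minimum(loc, len(planted_bins) - 1)] == bin_idx)
                pick = rng.integers(0, planted_pos.shape[1], size=int(hit.sum()))
                anchors[hit] = planted_pos[loc[hit], pick]
            lengths = rng.integers(lo, hi + 1, size=total)
            if strand == "+":
                ends = anchors + off
                starts = ends - lengths
            else:
                starts = anchors + 2 - off
                ends = starts + lengths
            chrom_arr = np.array(bins.chroms, dtype=object)[bins.chrom_codes[bin_idx]]
            sizes_arr = np.array([bins.chrom_sizes[c] for c in bins.chroms])[bins.chrom_codes[bin_idx]]
            shift = np.maximum(0, -starts) - np.maximum(0, ends - sizes_arr)
            starts = starts + shift
            ends = ends + shift
            frames.append(pd.DataFrame({
                "chrom": chrom_arr, "start": starts, "end": ends,
                "name": "", "mapq": 60, "strand": strand,
            }))
        if frames:
            df = pd.concat(frames, ignore_index=True)
        else:
            df = ReadSet.empty().df
        df["name"] = [f"{sample.sample_id}_r{i}" for i in range(len(df))]
        results[sample.sample_id] = ReadSet(
            df=df, sample_id=sample.sample_id, time_point=sample.time_point,
            replicate=sample.replicate, damage_type=config.damage_type,
        )
    return results


DamageProfile = Mapping[tuple[str, str], np.ndarray]


def simulate_damage_reads(
    config: SimConfig, genome: ReferenceGenome, damage_profile: DamageProfile,
    sample_id: str = "damage",
) -> ReadSet:
    """Damage-seq-style reads: each read starts immediately 3' of its lesion.

    ``damage_profile`` maps (chrom, strand) to a per-position intensity array
    (position = leftmost base of the lesion dinucleotide); lesion counts are
    Poisson with that intensity. Reads that would extend beyond a chromosome
    end are dropped (tallied in the log), keeping the read-to-lesion
    round-trip exact.
    """
    rng = np.random.default_rng([config.seed, _OP_DAMAGE])
    lo, hi = config.read_length_range
    rows = []
    for (chrom, strand), intensity in damage_profile.items():
        intensity = np.asarray(intensity, dtype=float)
        if (intensity < 0).any():
            raise ValueError("damage intensity must be non-negative")
        if chrom not in genome:
            raise ValueError(f"profile references unknown chromosome {chrom!r}")
        size = genome.sizes[chrom]
        if len(intensity) != size:
            raise ValueError(f"profile length {len(intensity)} != chromosome {chrom} size {size}")
        counts = rng.poisson(intensity)
        pos = np.repeat(np.arange(size), counts)
        if len(pos) == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=len(pos))
        if strand == "+":
            starts = pos + 2
            ends = starts + lengths
        else:
            ends = pos
            starts = ends - lengths
        ok = (starts >= 0) & (ends <= size)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts[ok], "end": ends[ok],
            "name": "", "mapq": 60, "strand": strand,
        }))
    df = pd.concat(rows, ignore_index=True) if rows else ReadSet.empty().df
    df["name"] = [f"{sample_id}_r{i}" for i in range(len(df))]
    return ReadSet(df=df, sample_id=sample_id, time_point="0h",
                   damage_type=config.damage_type)


def simulate_annotations(
    config: SimConfig,
    spots: pd.DataFrame,
    co_location: float,
    n_intervals: int = 200,
    width: int = 1000,
    name: str = "annotation",
) -> AnnotationSet:
    """Interval set with a controlled fraction of intervals placed on spots.

    round(co_location * n) intervals are centered on spots (cycling through
    the spot list, so with co_location=1 and n >= |spots| every spot is
    covered); the remainder is placed uniformly over the genome — avoiding
    spots entirely when co_location > 0 (so forced overlap counts are exact),
    and purely uniformly when co_location == 0.
    """
    if not 0.0 <= co_location <= 1.0:
        raise ValueError(f"co_location must lie in [0, 1], got {co_location}")
    rng = np.random.default_rng([config.seed, _OP_ANNOT])
    sizes = config.chrom_lengths
    chrom_names = list(sizes)
    chrom_tot = np.array([sizes[c] - width for c in chrom_names], dtype=float).clip(min=0)
    n_on = int(round(co_location * n_intervals))
    rows = []
    spot_rows = spots.reset_index(drop=True)
    for k in range(n_on):
        s = spot_rows.iloc[k % len(spot_rows)]
        mid = (int(s["start"]) + int(s["end"])) // 2
        start = max(0, min(mid - width // 2, sizes[s["chrom"]] - width))
        rows.append((s["chrom"], start, start + width))
    n_off = n_intervals - n_on
    attempts = 0
    while n_off > 0 and attempts < 100_000:
        attempts += 1
        ci = rng.choice(len(chrom_names), p=chrom_tot / chrom_tot.sum())
        start = int(rng.integers(0, chrom_tot[ci] + 1))
        chrom = chrom_names[ci]
        if co_location > 0:
            sub = spot_rows[spot_rows["chrom"] == chrom]
            if ((start < sub["end"].to_numpy()) & (sub["start"].to_numpy() < start + width)).any():
                continue
        rows.append((chrom, start, start + width))
        n_off -= 1
    if n_off > 0:
        raise ValueError("could not place annotation intervals away from spots")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    return AnnotationSet(name=name, df=df, source="synthetic")


def simulate_interactions(
    config: SimConfig,
    spots: pd.DataFrame,
    n_background: int = 100,
    per_spot: int = 0,
    anchor_width: int = 2000,
) -> pd.DataFrame:
    """BEDPE interaction list with an optional excess anchored at spots.

    Each spot receives ``per_spot`` interactions whose first anchor covers
    the spot; ``n_background`` interactions have both anchors uniform.
    """
    rng = np.random.default_rng([config.seed, _OP_INTERACT])
    sizes = config.chrom_lengths
    chroms = list(sizes)
    rows = []

    def _rand_anchor():
        c = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(0, max(1, sizes[c] - anchor_width)))
        return c, s, s + anchor_width

    for s in spots.itertuples():
        mid = (s.start + s.end) // 2
        a_start = max(0, min(mid - anchor_width // 2, sizes[s.chrom] - anchor_width))
        for _ in range(per_spot):
            c2, s2, e2 = _rand_anchor()
            rows.append((s.chrom, a_start, a_start + anchor_width, c2, s2, e2))
    for _ in range(n_background):
        c1, s1, e1 = _rand_anchor()
        c2, s2, e2 = _rand_anchor()
        rows.append((c1, s1, e1, c2, s2, e2))
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])


def simulate_gene_annotation(
    config: SimConfig,
    genome: ReferenceGenome,
    n_genes: int = 50,
    gene_length: int = 2000,
    gap: int = 500,
    reads_per_gene_mean: float = 50.0,
    time_trend_sd: float = 0.0,
    genes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, ReadSet]]:
    """Non-overlapping genes plus per-sample reads with planted TS fraction.

    Each gene's read count per sample is Poisson(reads_per_gene_mean *
    exp(slope_g * centered time rank)) with slope_g ~ N(0, time_trend_sd),
    giving a monotone per-gene time trend when time_trend_sd > 0. Each read
    lands on the transcribed strand (antisense to the gene) with probability
    ``ts_fraction_per_gene``. Pass an explicit ``genes`` frame (chrom, start,
    end, id, strand) to exercise specific QC branches.
    """
    rng = np.random.default_rng([config.seed, _OP_GENES])
    if genes is None:
        rows = []
        gid = 0
        for chrom, size in config.chrom_lengths.items():
            pos = gap
            while pos + gene_length + gap <= size and gid < n_genes:
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((chrom, pos, pos + gene_length, f"gene{gid}", strand))
                gid += 1
                pos += gene_length + gap
        genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "strand"])
    genes = genes.reset_index(drop=True)

    ranks = config.time_ranks()
    rank_arr = np.array([ranks[s.time_point] for s in config.samples], dtype=float)
    rank_arr -= rank_arr.mean()
    slopes = rng.normal(0.0, time_trend_sd, size=len(genes)) if time_trend_sd > 0 else np.zeros(len(genes))

    lo, hi = config.read_length_range
    out: dict[str, ReadSet] = {}
    for j, sample in enumerate(config.samples):
        frames = []
        for g_i, g in enumerate(genes.itertuples()):
            n = rng.poisson(reads_per_gene_mean * np.exp(slopes[g_i] * rank_arr[j]))
            if n == 0:
                continue
            starts = rng.integers(g.start, max(g.start + 1, g.end - hi), size=n)
            lengths = rng.integers(lo, hi + 1, size=n)
            is_ts = rng.random(n) < config.ts_fraction_per_gene
            ts_strand = "-" if g.strand == "+" else "+"
            frames.append(pd.DataFrame({
                "chrom": g.chrom, "start": starts, "end": starts + lengths,
                "name": "", "mapq": 60,
                "strand": np.where(is_ts, ts_strand, g.strand),
            }))
        df = pd.concat(frames, ignore_index=True) if frames else ReadSet.empty().df
        df["name"] = [f"{sample.sample_id}_g{i}" for i in range(len(df))]
        out[sample.sample_id] = ReadSet(
            df=df, sample_id=sample.sample_id, time_point=sample.time_point,
            replicate=sample.replicate, damage_type=config.damage_type,
        )
    return genes, out
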