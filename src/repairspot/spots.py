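"""Genome binning, depth equalization, and super hotspot / coldspot calling.

The calling rule is a replicate-wise count threshold on fixed-width bins:
a bin is a repair super hotspot when every designated early-time replicate
carries at least ``hot_min_early`` reads and every late replicate at most
``hot_max_late`` (defaults 15 and 5, applied to depth-equalized samples);
super coldspots use the relaxed mirrored rule. Plus and minus strands are
analyzed separately, and blacklisted bins are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ReadSet, merge_intervals

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 50
DEFAULT_DOWNSAMPLE_DEPTH = 7_700_000


@dataclass
class BinIndex:
    """Consecutive fixed-width bins tiling every chromosome.

    The final bin of each chromosome may be shorter than ``bin_width``; it is
    retained and flagged partial.
    """

    bin_width: int
    chroms: list[str]
    chrom_sizes: dict[str, int]
    starts: np.ndarray          # per-bin start
    ends: np.ndarray            # per-bin end (clipped at chromosome length)
    chrom_codes: np.ndarray     # per-bin index into `chroms`
    masked: np.ndarray          # per-bin blacklist flag
    partial: np.ndarray         # per-bin partial-width flag
    offsets: dict[str, int]     # chrom -> index of its first bin

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def bin_of(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Global bin index for positions on one chromosome (no bounds check)."""
        return self.offsets[chrom] + np.asarray(positions) // self.bin_width

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of bins overlapping [start, end) by >= 1 bp."""
        first = start // self.bin_width
        last = (end - 1) // self.bin_width
        n_chrom = -(-self.chrom_sizes[chrom] // self.bin_width)
        first = max(first, 0)
        last = min(last, n_chrom - 1)
        if last < first:
            return np.empty(0, dtype=np.int64)
        return self.offsets[chrom] + np.arange(first, last + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": np.array(self.chroms, dtype=object)[self.chrom_codes],
                "start": self.starts,
                "end": self.ends,
                "masked": self.masked,
                "partial": self.partial,
            }
        )


def make_bins(sizes: Mapping[str, int], width: int = DEFAULT_BIN_WIDTH) -> BinIndex:
    """Tile each chromosome with consecutive ``width``-bp bins."""
    if width < 1:
        raise ValueError(f"bin width must be >= 1, got {width}")
    chroms, starts, ends, codes, partial = [], [], [], [], []
    offsets: dict[str, int] = {}
    total = 0
    for code, (chrom, size) in enumerate(sizes.items()):
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        n = -(-size // width)  # ceil
        s = np.arange(n, dtype=np.int64) * width
        e = np.minimum(s + width, size)
        chroms.append(chrom)
        starts.append(s)
        ends.append(e)
        codes.append(np.full(n, code, dtype=np.int64))
        partial.append(e - s < width)
        offsets[chrom] = total
        total += n
    starts = np.concatenate(starts)
    return BinIndex(
        bin_width=width,
        chroms=chroms,
        chrom_sizes=dict(sizes),
        starts=starts,
        ends=np.concatenate(ends),
        chrom_codes=np.concatenate(codes),
        masked=np.zeros(total, dtype=bool),
        partial=np.concatenate(partial),
        offsets=offsets,
    )


def downsample_reads(
    reads: ReadSet,
    n: int = DEFAULT_DOWNSAMPLE_DEPTH,
    seed: int | np.random.Generator = 0,
    allow_short: bool = False,
) -> ReadSet:
    """Uniform subsample of exactly ``n`` reads without replacement.

    Both strands of the sample are pooled before subsampling. Input order of
    the surviving reads is preserved, so the result is reproducible from the
    seed alone.
    """
    if n < 0:
        raise ValueError("downsampling depth must be >= 0")
    if len(reads) < n:
        if not allow_short:
            raise ValueError(
                f"sample {reads.sample_id!r} has {len(reads)} reads, fewer than the "
                f"requested depth {n}; pass allow_short=True to keep all reads"
            )
        logger.warning(
            "sample %s has %d < %d reads; keeping all", reads.sample_id, len(reads), n
        )
        return reads
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(reads), size=n, replace=False))
    return reads.with_df(reads.df.iloc[keep])


def count_reads_per_bin(
    reads: ReadSet,
    bins: BinIndex,
    strand: str,
    assign: str = "5prime",
) -> tuple[np.ndarray, int]:
    """One strand's per-bin read counts: each read increments exactly one bin.

    The assignment point is the read's 5' end by default (start for "+",
    end - 1 for "-"), or the midpoint with ``assign="midpoint"``. Reads on the
    other strand are ignored; reads on unknown chromosomes or with
    out-of-bounds assignment points are tallied as skipped, not raised.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    skipped = 0
    df = reads.df
    on_strand = df[df["strand"] == strand]
    for chrom, sub in on_strand.groupby("chrom", sort=False):
        if chrom not in bins.offsets:
            skipped += len(sub)
            continue
        if assign == "5prime":
            pts = np.where(
                sub["strand"].to_numpy() == "+",
                sub["start"].to_numpy(),
                sub["end"].to_numpy() - 1,
            )
        elif assign == "midpoint":
            pts = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        else:
            raise ValueError(f"unknown assignment mode {assign!r}")
        ok = (pts >= 0) & (pts < bins.chrom_sizes[chrom])
        skipped += int((~ok).sum())
        idx = bins.bin_of(chrom, pts[ok])
        np.add.at(counts, idx, 1)
    if skipped:
        logger.info("count_reads_per_bin: skipped %d reads (unknown chrom / out of bounds)", skipped)
    return counts, skipped


def apply_blacklist(bins: BinIndex, blacklist: pd.DataFrame) -> BinIndex:
    """Mask every bin overlapping a blacklist interval by >= 1 bp."""
    masked = bins.masked.copy()
    if len(blacklist):
        for chrom, sub in blacklist.groupby("chrom"):
            if chrom not in bins.offsets:
                continue
            for s, e in merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy()):
                idx = bins.bins_overlapping(chrom, int(s), int(e))
                masked[idx] = True
    return replace(bins, masked=masked)


@dataclass
class BinCountMatrix:
    """Strand-specific bin x sample read counts with the null-model covariates.

    ``N`` holds the per-sample total mapped reads after depth equalization
    (the null model's library sizes), ``tc`` the per-bin T+C content fraction
    on this strand.
    """

    Y: np.ndarray                  # (n_bins, n_samples) integer counts
    strand: str
    bins: BinIndex
    samples: pd.DataFrame          # sample_id, time_point, replicate
    N: np.ndarray                  # per-sample library size
    tc: np.ndarray | None = None   # per-bin TC fraction (NaN where unknown)

    def __post_init__(self) -> None:
        if self.Y.shape != (self.bins.n_bins, len(self.samples)):
            raise ValueError("count matrix shape does not match bins x samples")
        if (self.Y < 0).any():
            raise ValueError("negative counts")
        if (np.asarray(self.N) <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        ids = list(self.samples["sample_id"])
        missing = [s for s in sample_ids if s not in ids]
        if missing:
            raise ValueError(f"unknown samples in rule: {missing}")
        return np.array([ids.index(s) for s in sample_ids], dtype=int)


def build_count_matrix(
    readsets: Sequence[ReadSet],
    bins: BinIndex,
    strand: str,
    depth: int | None = None,
    seed: int = 0,
    allow_short: bool = True,
    assign: str = "5prime",
) -> BinCountMatrix:
    """Downsample each sample to a common depth and bin one strand's reads."""
    cols, Ns, meta = [], [], []
    for k, rs in enumerate(readsets):
        if depth is not None:
            rs = downsample_reads(rs, depth, seed=seed + k, allow_short=allow_short)
        col, _ = count_reads_per_bin(rs, bins, strand, assign=assign)
        cols.append(col)
        Ns.append(len(rs))
        meta.append((rs.sample_id, rs.time_point, rs.replicate))
    samples = pd.DataFrame(meta, columns=["sample_id", "time_point", "replicate"])
    return BinCountMatrix(
        Y=np.column_stack(cols), strand=strand, bins=bins,
        samples=samples, N=np.asarray(Ns, dtype=float),
    )


@dataclass
class ThresholdRule:
    """Replicate-wise early/late count thresholds for spot calling.

    Hotspot: count >= ``hot_min_early`` in EVERY early sample and
    count <= ``hot_max_late`` in EVERY late sample. Coldspot (relaxed,
    mirrored): count <= ``cold_max_early`` in every early sample and
    count >= ``cold_min_late`` in every late sample. ``late`` may be empty
    (e.g. CPD hotspots from the 12-min samples alone), in which case the late
    condition is vacuous.
    """

    early: Sequence[str]
    late: Sequence[str] = ()
    hot_min_early: int = 15
    hot_max_late: int = 5
    cold_max_early: int = 2
    cold_min_late: int = 10

    def describe(self) -> str:
        return (
            f"early={list(self.early)} late={list(self.late)} "
            f"hotspot(min_early={self.hot_min_early}, max_late={self.hot_max_late}) "
            f"coldspot(max_early={self.cold_max_early}, min_late={self.cold_min_late})"
        )


def call_spots(
    Y: BinCountMatrix,
    rule: ThresholdRule,
    categories: Sequence[str] = ("hotspot", "coldspot"),
    damage_type: str | None = None,
    force: bool = False,
    merge_adjacent: bool = False,
) -> pd.DataFrame:
    """Call super hotspots and coldspots on one strand's count matrix.

    Returns a BED-like frame (chrom, start, end, strand, category, bin index,
    per-sample counts) sorted by chrom, start. CPD coldspots are refused
    unless ``force=True``: late-time CPD repair is dominated by
    transcription-coupled repair, which confounds the rule.
    """
    if not len(rule.early):
        raise ValueError("rule must designate at least one early sample")
    if damage_type == "CPD" and "coldspot" in categories and not force:
        raise ValueError(
            "CPD coldspot calling is disabled (transcription-coupled repair "
            "confounds late CPD time points); pass force=True to override"
        )
    early = Y.sample_index(rule.early)
    late = Y.sample_index(rule.late) if len(rule.late) else np.empty(0, dtype=int)

    unmasked = ~Y.bins.masked
    frames = []
    for category in categories:
        if category == "hotspot":
            ok = (Y.Y[:, early] >= rule.hot_min_early).all(axis=1)
            if len(late):
                ok &= (Y.Y[:, late] <= rule.hot_max_late).all(axis=1)
        elif category == "coldspot":
            ok = (Y.Y[:, early] <= rule.cold_max_early).all(axis=1)
            if len(late):
                ok &= (Y.Y[:, late] >= rule.cold_min_late).all(axis=1)
            else:
                raise ValueError("coldspot calling requires designated late samples")
        else:
            raise ValueError(f"unknown category {category!r}")
        idx = np.flatnonzero(ok & unmasked)
        sub = pd.DataFrame(
            {
                "chrom": np.array(Y.bins.chroms, dtype=object)[Y.bins.chrom_codes[idx]],
                "start": Y.bins.starts[idx],
                "end": Y.bins.ends[idx],
                "strand": Y.strand,
                "category": category,
                "bin_index": idx,
            }
        )
        for k, sid in enumerate(Y.samples["sample_id"]):
            sub[f"count_{sid}"] = Y.Y[idx, k]
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(drop=True)
    if merge_adjacent:
        out = _merge_adjacent_spots(out)
    logger.info(
        "call_spots strand=%s: %s (%s)",
        Y.strand,
        {c: int((out["category"] == c).sum()) for c in categories},
        rule.describe(),
    )
    return out


def _merge_adjacent_spots(spots: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (chrom, strand, cat), sub in spots.groupby(["chrom", "strand", "category"]):
        sub = sub.sort_values("start")
        cur = None
        for r in sub.itertuples():
            if cur is not None and r.start == cur[2]:
                cur[2] = r.end
            else:
                if cur is not None:
                    rows.append(cur)
                cur = [chrom, r.start, r.end, strand, cat]
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "category"])
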