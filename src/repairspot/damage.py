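"""Single-nucleotide damage mapping from Damage-seq-style reads.

The library chemistry stalls a high-fidelity polymerase one base 3' of the
lesion, so a read's 5' end marks the damage site exactly: for a plus-strand
read starting at s the lesion dinucleotide occupies [s-2, s); for a
minus-strand read ending at e it occupies [e, e+2). Pileups are keyed by
the leftmost base of the dinucleotide, per strand.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ReadSet, ReferenceGenome

logger = logging.getLogger(__name__)

DEFAULT_MIN_HOTSPOT_READS = 10
DEFAULT_EXTENSIONS = (0, 20, 500)


def infer_damage_positions(
    reads: ReadSet, sizes: Mapping[str, int]
) -> tuple[pd.DataFrame, int]:
    """Lesion pileup (chrom, pos, strand, count) from read 5' ends.

    ``pos`` is the leftmost base of the inferred lesion dinucleotide. Reads
    whose inferred lesion falls outside its chromosome are tallied and
    skipped, not raised.
    """
    df = reads.df
    pos = np.where(df["strand"] == "+", df["start"] - 2, df["end"])
    chrom_size = df["chrom"].map(sizes).to_numpy()
    ok = (pos >= 0) & (pos + 2 <= chrom_size)
    skipped = int((~ok).sum())
    if skipped:
        logger.info("infer_damage_positions: %d reads with out-of-bounds lesions skipped", skipped)
    pile = (
        pd.DataFrame({"chrom": df["chrom"][ok], "pos": pos[ok], "strand": df["strand"][ok]})
        .groupby(["chrom", "pos", "strand"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return pile, skipped


def call_damage_hotspots(
    pileup: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_HOTSPOT_READS,
    genome: ReferenceGenome | None = None,
) -> pd.DataFrame:
    """Positions supported by at least ``min_reads`` reads, per strand.

    Output is sorted by chrom, pos, strand; when a genome is supplied the
    lesion dinucleotide context (on the lesion strand) is attached.
    """
    hot = pileup[pileup["count"] >= min_reads].copy()
    hot = hot.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
    if genome is not None:
        hot["context"] = [
            genome.fetch(r.chrom, r.pos, r.pos + 2, r.strand) for r in hot.itertuples()
        ]
    return hot


def quantify_damage_in_regions(
    pileup: pd.DataFrame,
    regions: pd.DataFrame,
    sizes: Mapping[str, int],
    extensions: Sequence[int] = DEFAULT_EXTENSIONS,
    split_strands: bool = False,
) -> pd.DataFrame:
    """Lesion counts per region at each flank extension.

    For extension e, counts pileup entries (weighted by read support) whose
    key lies in [start - e, end + e) clipped to the chromosome. Strands are
    combined unless ``split_strands``. ``regions`` needs chrom/start/end and
    optionally a ``category`` column, carried through for group comparisons.
    """
    by_chrom: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    keys = ["chrom", "strand"] if split_strands else ["chrom"]
    for key, sub in pileup.groupby(keys):
        if not isinstance(key, tuple):
            key = (key,)
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(sub["count"].to_numpy())])
        by_chrom[key] = (pos, cum)

    rows = []
    strands = ("+", "-") if split_strands else (None,)
    for r_i, r in enumerate(regions.itertuples()):
        size = sizes[r.chrom]
        cat = getattr(r, "category", "region")
        for e in extensions:
            lo = max(0, r.start - e)
            hi = min(size, r.end + e)
            for strand in strands:
                key = (r.chrom, strand) if split_strands else (r.chrom,)
                if key not in by_chrom:
                    count = 0
                else:
                    pos, cum = by_chrom[key]
                    count = int(cum[np.searchsorted(pos, hi, "left")] - cum[np.searchsorted(pos, lo, "left")])
                rows.append((r_i, r.chrom, r.start, r.end, cat, e, strand or "both", count))
    return pd.DataFrame(
        rows,
        columns=["region", "chrom", "start", "end", "category", "extension", "strand", "count"],
    )


def compare_damage_by_category(table: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis comparison of damage counts across repair categories,
    one test per flank extension."""
    rows = []
    for ext, sub in table.groupby("extension"):
        groups = [g["count"].to_numpy() for _, g in sub.groupby("category")]
        if len(groups) < 2:
            continue
        try:
            stat, p = stats.kruskal(*groups)
        except ValueError:  # all values identical
            stat, p = 0.0, 1.0
        rows.append((ext, stat, p))
    return pd.DataFrame(rows, columns=["extension", "statistic", "pvalue"])


def overlap_spot_sets(
    a: pd.DataFrame, b: pd.DataFrame, slack: int = 0
) -> tuple[int, pd.DataFrame]:
    """Count of intervals in ``a`` overlapping (within ``slack`` bp) any in ``b``.

    Point sets (e.g. damage hotspots with a ``pos`` column) are treated as
    2-bp dinucleotide intervals. Returns the count and the overlapping pairs.
    """

    def _intervals(df: pd.DataFrame) -> pd.DataFrame:
        if "start" in df.columns:
            return df[["chrom", "start", "end"]].copy()
        out = df[["chrom"]].copy()
        out["start"] = df["pos"]
        out["end"] = df["pos"] + 2
        return out

    ia = _intervals(a).reset_index(drop=True)
    ib = _intervals(b).reset_index(drop=True)
    pairs = []
    for chrom, sub_a in ia.groupby("chrom"):
        sub_b = ib[ib["chrom"] == chrom]
        if sub_b.empty:
            continue
        bs = sub_b["start"].to_numpy() - slack
        be = sub_b["end"].to_numpy() + slack
        order = np.argsort(bs)
        bs, be = bs[order], be[order]
        b_idx = sub_b.index.to_numpy()[order]
        for ai, a_s, a_e in zip(sub_a.index, sub_a["start"], sub_a["end"]):
            hits = np.flatnonzero((bs < a_e) & (be > a_s))
            for h in hits:
                pairs.append((ai, int(b_idx[h])))
    pairs_df = pd.DataFrame(pairs, columns=["index_a", "index_b"])
    n_overlapping = pairs_df["index_a"].nunique() if len(pairs_df) else 0
    return n_overlapping, pairs_df
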