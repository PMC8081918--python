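"""Post-alignment read quality control.

Duplicates sharing both end coordinates are collapsed to one read, then
reads are kept only if mapping quality exceeds 20 and length lies in
21-31 nt — the excision-product size range. Multi-mapper removal is assumed
done upstream by the aligner.
"""

from __future__ import annotations

import logging

from .core import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 21
DEFAULT_LEN_RANGE = (21, 31)


def deduplicate_reads(reads: ReadSet, use_strand: bool = True) -> ReadSet:
    """Keep one read per shared (chrom, start, end[, strand]) key.

    The first-encountered read of each duplicate group is kept and input
    order is otherwise preserved. Strand participates in the key by default:
    two reads on opposite strands have different 5'/3' ends even when their
    intervals coincide.
    """
    key = ["chrom", "start", "end"] + (["strand"] if use_strand else [])
    out = reads.df.drop_duplicates(subset=key, keep="first")
    n_dup = len(reads.df) - len(out)
    if n_dup:
        logger.info("deduplicate_reads[%s]: removed %d duplicates", reads.sample_id, n_dup)
    return reads.with_df(out)


def filter_reads(
    reads: ReadSet,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
) -> ReadSet:
    """Keep reads with mapq >= ``min_mapq`` and length within ``len_range``.

    Defaults implement "mapping quality greater than 20" (strict) and
    lengths 21-31 inclusive. Per-filter rejection counts are logged.
    """
    lengths = reads.df["end"] - reads.df["start"]
    if (lengths <= 0).any():
        raise ValueError("reads with non-positive length")
    ok_mapq = reads.df["mapq"] >= min_mapq
    ok_len = (lengths >= len_range[0]) & (lengths <= len_range[1])
    logger.info(
        "filter_reads[%s]: rejected %d by mapq<%d, %d by length outside %s",
        reads.sample_id, int((~ok_mapq).sum()), min_mapq, int((~ok_len).sum()), len_range,
    )
    return reads.with_df(reads.df[ok_mapq & ok_len])
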