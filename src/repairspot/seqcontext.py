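"""Damage-centered nucleotide-frequency analysis of spot-mapped reads.

Reads are trimmed/extended to 15 bases centered on the 5' base of the
damage dinucleotide (7 flanking bases each side) and strand-specific
per-position nucleotide frequencies tallied — the readout behind the
cytosine-enrichment signature flanking UV damage sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .core import ReadSet, ReferenceGenome

logger = logging.getLogger(__name__)

CONTEXT_HALF_WIDTH = 7
# search window for the lesion: 5' base between 9 and 4 nt from the 3' end
LESION_SEARCH_WINDOW = (4, 9)
DEFAULT_LESION_OFFSET = 6

_DIPYRIMIDINES = {"CPD": ("TT", "TC"), "64PP": ("TC",)}


def locate_damage_in_read(
    seq: str,
    damage_type: str,
    lesion_offset: int = DEFAULT_LESION_OFFSET,
    window: tuple[int, int] = LESION_SEARCH_WINDOW,
) -> tuple[int, bool]:
    """Offset (from the read 5' end) of the damage dinucleotide's 5' base.

    Scans a window ``window[0]`` to ``window[1]`` nt from the 3' end for the
    canonical dipyrimidine (TT or TC for CPD; TC — preferring a CTCA
    context — for (6-4)PP), picks the candidate whose 5' base lies closest
    to ``lesion_offset`` nt from the 3' end, ties resolved 3'-ward. Returns
    (offset, fallback_flag); with no candidate the fallback is the position
    exactly ``lesion_offset`` nt from the 3' end, flagged True.
    """
    if not seq:
        raise ValueError("read sequence missing")
    L = len(seq)
    seq = seq.upper()
    dinucs = _DIPYRIMIDINES[damage_type]
    lo, hi = window
    candidates = []  # (distance d from 3' end, is_ctca)
    for d in range(lo, hi + 1):
        i = L - d
        if i < 0 or i + 2 > L:
            continue
        if seq[i : i + 2] in dinucs:
            is_ctca = damage_type == "64PP" and seq[max(0, i - 1) : i + 3] == "CTCA"
            candidates.append((d, is_ctca))
    if not candidates:
        return L - lesion_offset, True
    if damage_type == "64PP" and any(c[1] for c in candidates):
        candidates = [c for c in candidates if c[1]]
    # closest to the expected offset; ties go to the 3'-ward (smaller d)
    d_best = min(candidates, key=lambda c: (abs(c[0] - lesion_offset), c[0]))[0]
    return L - d_best, False


@dataclass
class FrequencyMatrix:
    """Per-position A/C/G/T frequencies around the damage-site anchor.

    ``freq`` is 15 x 4 (positions -7..+7 by A,C,G,T); ``counts`` holds the
    raw tallies, whose row sums give the per-position denominators.
    """

    counts: np.ndarray
    strand: str
    n_reads: int
    n_fallback: int = 0

    positions = np.arange(-CONTEXT_HALF_WIDTH, CONTEXT_HALF_WIDTH + 1)
    alphabet = "ACGT"

    @property
    def freq(self) -> np.ndarray:
        denom = self.counts.sum(axis=1, keepdims=True)
        return np.divide(self.counts, denom, out=np.full_like(self.counts, np.nan, dtype=float),
                         where=denom > 0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, index=self.positions, columns=list(self.alphabet))
        df.index.name = "position"
        return df


def _read_window_base(row, k: int, genome: ReferenceGenome | None) -> str:
    """Base at read-coordinate k (5'->3' on read strand), genome-filled."""
    L = row.end - row.start
    seq = getattr(row, "seq", None)
    if seq and 0 <= k < L:
        return seq[k].upper()
    if genome is None or row.chrom not in genome:
        return "N"
    g = row.start + k if row.strand == "+" else row.end - 1 - k
    return genome.fetch(row.chrom, g, g + 1, row.strand)


def nucleotide_frequency(
    reads: ReadSet,
    damage_type: str | None = None,
    genome: ReferenceGenome | None = None,
    lesion_offset: int = DEFAULT_LESION_OFFSET,
) -> dict[str, FrequencyMatrix]:
    """Strand-specific 15-bp damage-centered frequency matrices.

    The anchor within each read comes from :func:`locate_damage_in_read`
    (falling back to the fixed offset when the read has no sequence and a
    genome is available to reconstruct it). Window positions beyond the read
    are filled from the genome when given, else excluded from that
    position's denominator.
    """
    damage_type = damage_type or reads.damage_type or "64PP"
    out = {}
    has_seq_col = "seq" in reads.df.columns
    for strand in ("+", "-"):
        sub = reads.df[reads.df["strand"] == strand]
        counts = np.zeros((2 * CONTEXT_HALF_WIDTH + 1, 4))
        n_used = 0
        n_fb = 0
        for row in sub.itertuples():
            seq = getattr(row, "seq", None) if has_seq_col else None
            if (not seq or not isinstance(seq, str)) and genome is not None and row.chrom in genome:
                seq = genome.fetch(row.chrom, row.start, row.end, strand)
            if not seq or not isinstance(seq, str):
                n_fb += 1
                continue
            anchor, fb = locate_damage_in_read(seq, damage_type, lesion_offset)
            n_fb += int(fb)
            L = row.end - row.start
            for p in range(-CONTEXT_HALF_WIDTH, CONTEXT_HALF_WIDTH + 1):
                k = anchor + p
                if 0 <= k < L:
                    base = seq[k].upper()
                elif genome is not None and row.chrom in genome:
                    g = row.start + k if strand == "+" else row.end - 1 - k
                    base = genome.fetch(row.chrom, g, g + 1, strand)
                else:
                    continue
                bi = "ACGT".find(base)
                if bi >= 0:
                    counts[p + CONTEXT_HALF_WIDTH, bi] += 1
            n_used += 1
        out[strand] = FrequencyMatrix(counts=counts, strand=strand, n_reads=n_used,
                                      n_fallback=n_fb)
        if n_fb:
            logger.info("nucleotide_frequency strand %s: %d reads without canonical dipyrimidine "
                        "(fallback anchor) or sequence", strand, n_fb)
    return out


def pool_matrices(mats: dict[str, FrequencyMatrix]) -> FrequencyMatrix:
    """Strand-pooled frequency matrix (counts added in strand space)."""
    counts = sum(m.counts for m in mats.values())
    return FrequencyMatrix(
        counts=counts, strand="both",
        n_reads=sum(m.n_reads for m in mats.values()),
        n_fallback=sum(m.n_fallback for m in mats.values()),
    )


def compare_c_enrichment(
    spot_matrix: FrequencyMatrix,
    reference_matrix: FrequencyMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-flank-position cytosine frequency differences, spots vs reference.

    The damage dinucleotide positions (0 and +1) are excluded. Each flank
    position gets a two-proportion z-test (BH-corrected); the mean C
    difference over flanks is attached as a summary attribute ``mean_delta``.
    """
    if spot_matrix.counts.shape != reference_matrix.counts.shape:
        raise ValueError("frequency matrices are on different position grids")
    ci = "ACGT".find("C")
    rows = []
    for k, pos in enumerate(FrequencyMatrix.positions):
        if pos in (0, 1):
            continue
        n1 = spot_matrix.counts[k].sum()
        n2 = reference_matrix.counts[k].sum()
        c1 = spot_matrix.counts[k, ci]
        c2 = reference_matrix.counts[k, ci]
        if n1 == 0 or n2 == 0:
            rows.append((pos, np.nan, np.nan))
            continue
        delta = c1 / n1 - c2 / n2
        if c1 + c2 in (0, n1 + n2):
            p = 1.0
        else:
            _, p = proportions_ztest([c1, c2], [n1, n2])
        rows.append((pos, delta, p))
    out = pd.DataFrame(rows, columns=["position", "delta_c", "pvalue"])
    ok = out["pvalue"].notna()
    out["qvalue"] = np.nan
    if ok.any():
        out.loc[ok, "qvalue"] = multipletests(out.loc[ok, "pvalue"], method="fdr_bh")[1]
    out["significant"] = out["qvalue"] < alpha
    out.attrs["mean_delta"] = float(np.nanmean(out["delta_c"]))
    return out
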