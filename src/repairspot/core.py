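"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open throughout, matching BED conventions.
Strands are "+" and "-". Read sets are thin wrappers around a pandas
DataFrame with BED6-like columns plus an optional ``seq`` column holding the
read sequence in read orientation (5'->3' on the read's strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

READ_COLUMNS = ["chrom", "start", "end", "name", "mapq", "strand"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """A reference genome held fully in memory.

    Suitable for the miniature synthetic assemblies this package analyses;
    real assemblies should be accessed through :func:`repairspot.io.read_fasta`
    chromosome by chromosome.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the requested strand.

        Positions outside the chromosome are filled with "N" so that callers
        asking for flanks near an edge get a fixed-width answer.
        """
        seq = self.sequences[chrom]
        size = len(seq)
        left_pad = max(0, -start)
        right_pad = max(0, end - size)
        core = seq[max(0, start) : min(end, size)]
        out = "N" * left_pad + core + "N" * right_pad
        return out if strand == "+" else revcomp(out)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class ReadSet:
    """One sample's aligned reads with its experimental labels.

    ``df`` columns: chrom, start, end, name, mapq, strand (+ optional seq).
    """

    df: pd.DataFrame
    sample_id: str = "sample"
    time_point: str | None = None
    replicate: str | None = None
    damage_type: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in READ_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"read table missing columns {missing}")
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            raise ValueError("reads with start >= end present")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def with_df(self, df: pd.DataFrame) -> "ReadSet":
        return replace(self, df=df.reset_index(drop=True))

    @classmethod
    def empty(cls, **labels) -> "ReadSet":
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            READ_COLUMNS, [str, np.int64, np.int64, str, np.int64, str])})
        return cls(df=df, **labels)


@dataclass
class AnnotationSet:
    """A named genomic interval set (FIREs, superenhancers, states, ...).

    ``df`` columns: chrom, start, end and optionally label.
    """

    name: str
    df: pd.DataFrame
    source: str = ""

    def __len__(self) -> int:
        return len(self.df)

    def coverage_fraction(self, sizes: Mapping[str, int]) -> float:
        """Fraction of the assembly covered by the (merged) intervals."""
        total = sum(sizes.values())
        covered = 0
        for chrom, sub in self.df.groupby("chrom"):
            if chrom not in sizes:
                continue
            merged = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            covered += int(np.sum(merged[:, 1] - merged[:, 0]))
        return covered / total if total else 0.0


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Merge possibly overlapping intervals; returns array of [start, end) rows."""
    if len(starts) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    starts = np.asarray(starts, dtype=np.int64)[order]
    ends = np.asarray(ends, dtype=np.int64)[order]
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.column_stack([out_s, out_e]).astype(np.int64)


def intervals_overlap_any(
    query_starts: np.ndarray,
    query_ends: np.ndarray,
    ref_starts: np.ndarray,
    ref_ends: np.ndarray,
) -> np.ndarray:
    """Boolean per query: does [qs, qe) overlap any reference interval by >= 1 bp?

    References must be merged (non-overlapping, sorted); the test is then a
    pair of binary searches per query.
    """
    if len(ref_starts) == 0:
        return np.zeros(len(query_starts), dtype=bool)
    # first reference whose end is > query start
    idx = np.searchsorted(ref_ends, np.asarray(query_starts), side="right")
    hit = idx < len(ref_starts)
    out = np.zeros(len(query_starts), dtype=bool)
    out[hit] = ref_starts[idx[hit]] < np.asarray(query_ends)[hit]
    return out
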