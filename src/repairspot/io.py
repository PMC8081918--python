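"""Readers and writers for the plain-text genomics formats the pipeline uses.

FASTA goes through Biopython, BAM through pysam; the tabular formats
(BED3/6/12, BEDPE, bedGraph, chrom.sizes, TSV) through pandas. All
coordinates are 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AnnotationSet, ReadSet, ReferenceGenome

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
    "strand1", "strand2",
]


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: ReferenceGenome, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> ReferenceGenome:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    return ReferenceGenome(sequences=seqs)


# ---------------------------------------------------------------- chrom.sizes

def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


# ---------------------------------------------------------------- reads (BED6 / BAM)

def write_reads_bed(reads: ReadSet, path: str) -> None:
    """BED6 with MAPQ in the score column."""
    out = reads.df[["chrom", "start", "end", "name", "mapq", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str, **labels) -> ReadSet:
    df = pd.read_csv(
        path, sep="\t", header=None, names=BED6_COLS,
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    df = df.rename(columns={"score": "mapq"})
    df["mapq"] = df["mapq"].astype(int)
    return ReadSet(df=df, **labels)


def read_reads_bam(path: str, **labels) -> ReadSet:
    """Aligned reads from BAM/SAM via pysam; sequences retained."""
    import pysam

    rows = []
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            seq = aln.query_sequence or ""
            if strand == "-" and seq:
                # pysam returns the forward-genome sequence; store read-strand
                from .core import revcomp
                seq = revcomp(seq)
            rows.append(
                (aln.reference_name, aln.reference_start, aln.reference_end,
                 aln.query_name, aln.mapping_quality, strand, seq)
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "mapq", "strand", "seq"])
    return ReadSet(df=df, **labels)


# ---------------------------------------------------------------- intervals

def write_bed(df: pd.DataFrame, path: str, header_lines: Iterable[str] = ()) -> None:
    """Write BED3/BED6-style intervals; extra columns appended after strand."""
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path: str, name: str | None = None) -> AnnotationSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    names = ["chrom", "start", "end", "label", "score", "strand"][:ncol]
    df.columns = names + [f"extra{i}" for i in range(ncol - len(names))]
    df["chrom"] = df["chrom"].astype(str)
    return AnnotationSet(name=name or os.path.basename(path), df=df, source=path)


def write_genes_bed12(genes: pd.DataFrame, path: str) -> None:
    """Single-exon BED12 (one block spanning the gene)."""
    with open(path, "w") as fh:
        for g in genes.itertuples():
            length = g.end - g.start
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{length},\t0,\n"
            )


def read_genes_bed12(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = df.iloc[:, :6].copy()
    genes.columns = ["chrom", "start", "end", "id", "score", "strand"]
    genes["chrom"] = genes["chrom"].astype(str)
    return genes.drop(columns=["score"])


def read_genes_gtf(path: str) -> pd.DataFrame:
    """Gene records from a GTF; one row per feature of type 'gene'."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1) for kv in f[8].rstrip(";").split(";") if kv.strip()
            )
            gid = attrs.get("gene_id", "gene").strip('"')
            rows.append((f[0], int(f[3]) - 1, int(f[4]), gid, f[6]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "strand"])


# ---------------------------------------------------------------- BEDPE / bedGraph

def write_bedpe(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BEDPE_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BEDPE row has {len(f)} fields (need >= 6)")
            try:
                rows.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BEDPE coordinates") from exc
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])


def write_bedgraph(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )
    df["chrom"] = df["chrom"].astype(str)
    return df
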