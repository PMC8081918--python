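"""Gene-level strand-resolved repair quantification.

Excision-product reads are split by gene annotation into transcribed-strand
(TS) and nontranscribed-strand (NTS) counts — a read antisense to the gene
reports repair of the transcribed strand. RPKM normalizes within sample;
the TS/(TS+NTS) ratio cancels biases shared by the two strands (library
size, gene length, pull-down efficiency) and quantifies the
transcription-coupled repair contribution, bounded in [0, 1].
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .core import ReadSet, ReferenceGenome

logger = logging.getLogger(__name__)

MAX_GENE_LENGTH = 300_000
MIN_DINUCLEOTIDES = 10
MIN_TOTAL_READS = 10


def assign_reads_to_genes(
    reads: ReadSet,
    genes: pd.DataFrame,
    convention: str = "antisense",
    unique: bool = False,
) -> pd.DataFrame:
    """Per-gene TS/NTS read counts for one sample.

    A read overlapping a gene by >= 1 bp is TS when its strand is opposite
    the gene's annotated strand (``convention="antisense"``, the XR-seq read
    orientation) or when equal (``"sense"``). Reads overlapping several genes
    count once per gene unless ``unique=True`` (first gene by coordinate).
    Reads outside every gene are ignored.
    """
    if convention not in ("antisense", "sense"):
        raise ValueError(f"unknown TS convention {convention!r}")
    trees: dict[str, IntervalTree] = {}
    for idx, g in genes.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(g["start"], g["end"], idx)
    ts = np.zeros(len(genes), dtype=np.int64)
    nts = np.zeros(len(genes), dtype=np.int64)
    gene_strand = genes["strand"].to_numpy()
    for chrom, sub in reads.df.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for start, end, strand in zip(sub["start"], sub["end"], sub["strand"]):
            hits = tree.overlap(start, end)
            if not hits:
                continue
            if unique:
                hits = [min(hits, key=lambda iv: (iv.begin, iv.data))]
            for iv in hits:
                gi = iv.data
                antisense = strand != gene_strand[gi]
                is_ts = antisense if convention == "antisense" else not antisense
                if is_ts:
                    ts[gi] += 1
                else:
                    nts[gi] += 1
    return pd.DataFrame({"id": genes["id"], "ts": ts, "nts": nts})


def count_tt_tc_dinucleotides(genes: pd.DataFrame, genome: ReferenceGenome) -> pd.DataFrame:
    """TT+TC dinucleotide counts on each strand of each gene.

    The counts on the minus strand of the gene body equal the AA+GA
    (reverse-complement) occurrences on the forward sequence.
    """
    plus, minus = [], []
    for g in genes.itertuples():
        seq = genome.fetch(g.chrom, g.start, g.end, "+")
        plus.append(sum(seq.count(d) for d in ("TT", "TC")))
        minus.append(sum(seq.count(d) for d in ("AA", "GA")))
    return pd.DataFrame({"id": genes["id"].to_numpy(), "dinuc_plus": plus, "dinuc_minus": minus})


def filter_genes(
    genes: pd.DataFrame,
    dinucs: pd.DataFrame,
    total_reads: np.ndarray,
    max_length: int = MAX_GENE_LENGTH,
    min_dinucs: int = MIN_DINUCLEOTIDES,
    min_reads: int = MIN_TOTAL_READS,
) -> pd.DataFrame:
    """Gene QC: keep genes with >= ``min_dinucs`` TT/TC dinucleotides on
    either strand, length strictly below ``max_length``, and at least
    ``min_reads`` reads summed across all samples."""
    lengths = (genes["end"] - genes["start"]).to_numpy()
    d = dinucs.set_index("id").loc[genes["id"]]
    ok_dinuc = (d["dinuc_plus"].to_numpy() >= min_dinucs) | (d["dinuc_minus"].to_numpy() >= min_dinucs)
    ok_len = lengths < max_length
    ok_reads = np.asarray(total_reads) >= min_reads
    logger.info(
        "filter_genes: rejected %d by dinucleotides, %d by length, %d by read total",
        int((~ok_dinuc).sum()), int((~ok_len).sum()), int((~ok_reads).sum()),
    )
    return genes[ok_dinuc & ok_len & ok_reads].reset_index(drop=True)


def rpkm(counts: np.ndarray, gene_lengths: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """Reads per kilobase per million mapped reads.

    ``counts`` is genes x samples; ``library_sizes`` per-sample mapped totals.
    """
    gene_lengths = np.asarray(gene_lengths, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (gene_lengths <= 0).any():
        raise ValueError("zero-length gene")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return np.asarray(counts, dtype=float) / (
        (gene_lengths[:, None] / 1e3) * (library_sizes[None, :] / 1e6)
    )


def build_gene_repair_table(
    genes: pd.DataFrame,
    per_sample_counts: dict[str, pd.DataFrame],
    library_sizes: dict[str, int],
) -> pd.DataFrame:
    """Long-format gene x sample table of TS/NTS counts, RPKM, and the ratio."""
    rows = []
    lengths = (genes["end"] - genes["start"]).to_numpy()
    for sid, cnt in per_sample_counts.items():
        ts = cnt["ts"].to_numpy()
        nts = cnt["nts"].to_numpy()
        lib = library_sizes[sid]
        ts_rpkm = rpkm(ts[:, None], lengths, np.array([lib]))[:, 0]
        nts_rpkm = rpkm(nts[:, None], lengths, np.array([lib]))[:, 0]
        tot = ts + nts
        ratio = np.where(tot > 0, ts / np.maximum(tot, 1), np.nan)
        rows.append(pd.DataFrame({
            "id": genes["id"], "sample_id": sid, "ts": ts, "nts": nts,
            "ts_rpkm": ts_rpkm, "nts_rpkm": nts_rpkm, "ratio": ratio,
        }))
    return pd.concat(rows, ignore_index=True)


def pca_trajectory(
    rpkm_matrix: np.ndarray,
    sample_ids: Sequence[str],
    top_n: int = 2000,
    time_ranks: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Low-dimensional repair trajectory across the time course.

    Rows of ``rpkm_matrix`` are genes, columns samples. Genes are ranked by
    the variance of log2(RPKM + 1) across samples, the ``top_n`` most
    variable are kept, and sample scores on the first two principal
    components are returned together with explained-variance fractions. When
    ``time_ranks`` is given, PC1's sign is fixed to increase with time.
    """
    X = np.log2(np.asarray(rpkm_matrix, dtype=float) + 1.0)
    if X.shape[1] < 3:
        raise ValueError("PCA trajectory needs >= 3 samples")
    var = X.var(axis=0)
    if np.allclose(X.var(axis=1).sum(), 0):
        raise ValueError("constant expression matrix; variance ranking degenerate")
    gene_var = X.var(axis=1)
    if top_n < X.shape[0]:
        keep = np.argsort(gene_var)[::-1][:top_n]
    else:
        if top_n > X.shape[0]:
            logger.warning("only %d genes available (< top_n=%d); using all", X.shape[0], top_n)
        keep = np.arange(X.shape[0])
    Xs = X[keep].T  # samples x genes
    n_comp = min(2, Xs.shape[0] - 1, Xs.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Xs)
    if time_ranks is not None:
        rho = spearmanr(scores[:, 0], np.asarray(time_ranks)).statistic
        if rho < 0:
            scores[:, 0] *= -1
    out = pd.DataFrame({"sample_id": list(sample_ids)})
    for k in range(n_comp):
        out[f"PC{k + 1}"] = scores[:, k]
    for k in range(n_comp):
        out[f"explained_var_PC{k + 1}"] = pca.explained_variance_ratio_[k]
    return out
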