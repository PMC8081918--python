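"""End-to-end orchestration: filter -> bin -> mask -> call -> model -> annotate.

`make_fixture` writes a self-contained synthetic study (genome, per-sample
reads, genes, blacklist, annotations, interactions, signal track, YAML
config); `run_pipeline` executes every stage on such a study directory and
writes the result bundle. All stage outputs carry a header recording the
package version, a hash of the configuration, and the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .core import AnnotationSet, ReadSet, ReferenceGenome
from .damage import (call_damage_hotspots, compare_damage_by_category,
                     infer_damage_positions, quantify_damage_in_regions)
from .enrich import (bootstrap_enrichment, count_interactions_per_spot,
                     interaction_excess_test, aggregate_signal, sample_random_spots)
from .filters import deduplicate_reads, filter_reads
from .genes import (assign_reads_to_genes, build_gene_repair_table,
                    count_tt_tc_dinucleotides, filter_genes, pca_trajectory)
from .null_model import compute_tc_content, fit_null_model, test_enrichment
from .seqcontext import compare_c_enrichment, nucleotide_frequency, pool_matrices
from .spots import (ThresholdRule, apply_blacklist, build_count_matrix,
                    call_spots, make_bins)
from .synthetic import (PlantedSpot, SampleSpec, SimConfig, simulate_annotations,
                        simulate_damage_reads, simulate_gene_annotation,
                        simulate_genome, simulate_interactions, simulate_xrseq_reads)

logger = logging.getLogger(__name__)

FIXTURE_TIMEPOINTS = ["1min", "1min", "5min", "20min", "1h", "2h", "4h", "4h"]
FIXTURE_REPLICATES = ["rep1", "rep2", "rep1", "rep1", "rep1", "rep1", "rep1", "rep2"]


def fixture_config(seed: int = 0, scale: str = "small") -> SimConfig:
    """The canonical synthetic study: an eight-sample (6-4)PP time course
    with 20 planted hotspots and 10 planted coldspots.

    ``scale="small"`` uses 2 x 100-kb chromosomes at baseline one read per
    bin per strand (fast enough for multi-seed tests); ``"full"`` scales the
    same design to 2 x 1-Mb chromosomes.
    """
    if scale == "small":
        chrom_len, lib_factor = 100_000, 1
    elif scale == "full":
        chrom_len, lib_factor = 1_000_000, 1
    else:
        raise ValueError(f"unknown scale {scale!r}")
    n_bins_per_strand = 2 * chrom_len // 50
    samples = [
        SampleSpec(sample_id=f"{tp}_{rep}", time_point=tp, replicate=rep,
                   library_size=n_bins_per_strand * lib_factor)
        for tp, rep in zip(FIXTURE_TIMEPOINTS, FIXTURE_REPLICATES)
    ]
    step_h = chrom_len // 25
    hotspots = [
        PlantedSpot("chrS1", (i + 1) * step_h, (i + 1) * step_h + 50,
                    strand="+" if i % 2 == 0 else "-",
                    fold_early=50.0, fold_late=0.05)
        for i in range(20)
    ]
    step_c = (chrom_len // 12) // 50 * 50  # bin-aligned
    coldspots = [
        PlantedSpot("chrS2", (i + 1) * step_c, (i + 1) * step_c + 50,
                    strand="+" if i % 2 == 0 else "-",
                    fold_early=0.02, fold_late=30.0)
        for i in range(10)
    ]
    return SimConfig(
        seed=seed,
        chrom_lengths={"chrS1": chrom_len, "chrS2": chrom_len},
        samples=samples,
        planted_hotspots=hotspots,
        planted_coldspots=coldspots,
        beta_dispersion=0.3,
        tc_bias_strength=0.3,
        damage_type="64PP",
    )


def fixture_blacklist(config: SimConfig) -> pd.DataFrame:
    """Two blacklist intervals per chromosome, away from planted spots."""
    rows = []
    for chrom, size in config.chrom_lengths.items():
        rows.append((chrom, 0, 500))
        rows.append((chrom, size - 800, size - 300))
    bl = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    for s in config.all_planted:
        for r in bl.itertuples():
            if s.chrom == r.chrom and s.start < r.end and r.start < s.end:
                raise ValueError("fixture blacklist overlaps a planted spot")
    return bl


def make_fixture(outdir: str, seed: int = 0, scale: str = "small") -> dict:
    """Write the canonical fixture directory; returns the manifest."""
    os.makedirs(outdir, exist_ok=True)
    config = fixture_config(seed=seed, scale=scale)
    genome = simulate_genome(config)
    io.write_fasta(genome, os.path.join(outdir, "genome.fa"))
    io.write_chrom_sizes(genome.sizes, os.path.join(outdir, "chrom.sizes"))

    readsets = simulate_xrseq_reads(config, genome)
    sample_entries = []
    for s in config.samples:
        path = os.path.join(outdir, f"reads_{s.sample_id}.bed")
        io.write_reads_bed(readsets[s.sample_id], path)
        sample_entries.append({
            "sample_id": s.sample_id, "time_point": s.time_point,
            "replicate": s.replicate, "path": os.path.basename(path),
        })

    blacklist = fixture_blacklist(config)
    io.write_bed(blacklist, os.path.join(outdir, "blacklist.bed"))

    genes, gene_reads = simulate_gene_annotation(
        config, genome, n_genes=40, gene_length=2000, reads_per_gene_mean=30.0,
        time_trend_sd=0.4,
    )
    io.write_genes_bed12(genes, os.path.join(outdir, "genes.bed12"))
    for sid, rs in gene_reads.items():
        io.write_reads_bed(rs, os.path.join(outdir, f"gene_reads_{sid}.bed"))

    hot_df = pd.DataFrame(
        [(s.chrom, s.start, s.end, s.strand) for s in config.planted_hotspots],
        columns=["chrom", "start", "end", "strand"],
    )
    fire = simulate_annotations(config, hot_df, co_location=0.3, n_intervals=60,
                                width=2000, name="FIRE")
    se = simulate_annotations(config, hot_df, co_location=0.2, n_intervals=20,
                              width=5000, name="superenhancer")
    io.write_bed(fire.df, os.path.join(outdir, "fire.bed"))
    io.write_bed(se.df, os.path.join(outdir, "superenhancer.bed"))
    interactions = simulate_interactions(config, hot_df, n_background=80, per_spot=5)
    io.write_bedpe(interactions, os.path.join(outdir, "interactions.bedpe"))

    # uniform low-intensity damage: lesions are not clustered at repair spots
    profile = {(c, s): np.full(n, 0.002) for c, n in config.chrom_lengths.items()
               for s in ("+", "-")}
    damage_reads = simulate_damage_reads(config, genome, profile)
    io.write_reads_bed(damage_reads, os.path.join(outdir, "damage_reads.bed"))

    # accessibility-like track, mildly elevated at planted hotspots
    track_rows = [(c, 0, n, 1.0) for c, n in config.chrom_lengths.items()]
    track_rows += [(s.chrom, s.start, s.end, 10.0) for s in config.planted_hotspots]
    track = pd.DataFrame(track_rows, columns=["chrom", "start", "end", "value"])
    io.write_bedgraph(track, os.path.join(outdir, "accessibility.bedgraph"))

    manifest = {
        "seed": seed,
        "scale": scale,
        "genome": "genome.fa",
        "chrom_sizes": "chrom.sizes",
        "samples": sample_entries,
        "genes": "genes.bed12",
        "blacklist": "blacklist.bed",
        "annotations": [{"name": "FIRE", "path": "fire.bed"},
                        {"name": "superenhancer", "path": "superenhancer.bed"}],
        "interactions": "interactions.bedpe",
        "damage_reads": "damage_reads.bed",
        "track": "accessibility.bedgraph",
        "damage_type": "64PP",
        "early_timepoints": ["1min"],
        "late_timepoints": ["4h"],
    }
    with open(os.path.join(outdir, "fixture.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    All parameters default to the pipeline's standard settings: 50-bp bins,
    depth equalization, hotspot thresholds (15, 5), coldspot thresholds
    (2, 10), damage hotspot minimum 10 reads, flank extensions 0/20/500 bp,
    top 2000 variable genes, B = 1000 bootstrap replicates.
    """

    fixture_dir: str
    outdir: str
    seed: int = 0
    bin_width: int = 50
    downsample_depth: int | None = None   # None: equalize to smallest sample
    hot_min_early: int = 15
    hot_max_late: int = 5
    cold_max_early: int = 2
    cold_min_late: int = 10
    damage_min_reads: int = 10
    extensions: tuple[int, ...] = (0, 20, 500)
    top_n_genes: int = 2000
    bootstrap_B: int = 1000
    min_mapq: int = 21
    read_len_range: tuple[int, int] = (21, 31)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _header(cfg: PipelineConfig) -> list[str]:
    return [f"repairspot {__version__}", f"config_hash={cfg.config_hash()}", f"seed={cfg.seed}"]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage on a fixture directory; returns the summary dict."""
    os.makedirs(cfg.outdir, exist_ok=True)
    fdir = cfg.fixture_dir
    with open(os.path.join(fdir, "fixture.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    genome = io.read_fasta(os.path.join(fdir, manifest["genome"]))
    sizes = genome.sizes
    summary: dict = {"version": __version__, "config_hash": cfg.config_hash(),
                     "seed": cfg.seed, "stages": {}}

    # ---- read QC -------------------------------------------------------
    readsets = []
    for entry in manifest["samples"]:
        rs = io.read_reads_bed(os.path.join(fdir, entry["path"]),
                               sample_id=entry["sample_id"],
                               time_point=entry["time_point"],
                               replicate=entry["replicate"],
                               damage_type=manifest.get("damage_type"))
        n0 = len(rs)
        rs = filter_reads(deduplicate_reads(rs), cfg.min_mapq, cfg.read_len_range)
        readsets.append(rs)
        summary["stages"].setdefault("read_qc", {})[entry["sample_id"]] = {
            "input": n0, "kept": len(rs)}

    early = [r.sample_id for r in readsets if r.time_point in manifest["early_timepoints"]]
    late = [r.sample_id for r in readsets if r.time_point in manifest["late_timepoints"]]
    if not early or not late:
        raise ValueError(
            f"rule requires early {manifest['early_timepoints']} and late "
            f"{manifest['late_timepoints']} samples; found early={early}, late={late}"
        )

    # ---- binning, masking, calling ------------------------------------
    bins = make_bins(sizes, cfg.bin_width)
    blacklist = io.read_bed(os.path.join(fdir, manifest["blacklist"])).df
    bins = apply_blacklist(bins, blacklist)
    depth = cfg.downsample_depth or min(len(r) for r in readsets)
    rule = ThresholdRule(early=early, late=late,
                         hot_min_early=cfg.hot_min_early, hot_max_late=cfg.hot_max_late,
                         cold_max_early=cfg.cold_max_early, cold_min_late=cfg.cold_min_late)
    spot_frames = []
    matrices = {}
    fits = {}
    for strand in ("+", "-"):
        Y = build_count_matrix(readsets, bins, strand, depth=depth, seed=cfg.seed)
        Y.tc = compute_tc_content(bins, genome, strand)
        matrices[strand] = Y
        calls = call_spots(Y, rule, damage_type=manifest.get("damage_type"))
        fit = fit_null_model(Y)
        fits[strand] = fit
        calls = test_enrichment(Y, fit, calls, group=early)
        spot_frames.append(calls)
    spots = pd.concat(spot_frames, ignore_index=True).sort_values(
        ["chrom", "start", "strand"]).reset_index(drop=True)
    summary["stages"]["spots"] = {
        "depth": depth, "rule": rule.describe(),
        "hotspots": int((spots["category"] == "hotspot").sum()),
        "coldspots": int((spots["category"] == "coldspot").sum()),
    }
    for cat in ("hotspot", "coldspot"):
        sub = spots[spots["category"] == cat].copy()
        sub["name"] = cat
        with np.errstate(divide="ignore"):
            sub["score"] = np.minimum(1000, -10 * np.log10(np.maximum(sub["pvalue"], 1e-100))).astype(int)
        io.write_bed(sub[["chrom", "start", "end", "name", "score", "strand"]],
                     os.path.join(cfg.outdir, f"super_{cat}s.bed"), header_lines=_header(cfg))
    spots.to_csv(os.path.join(cfg.outdir, "spot_counts.tsv"), sep="\t", index=False)

    # ---- gene-level repair and trajectory ------------------------------
    genes = io.read_genes_bed12(os.path.join(fdir, manifest["genes"]))
    gene_reads = {
        e["sample_id"]: io.read_reads_bed(
            os.path.join(fdir, f"gene_reads_{e['sample_id']}.bed"),
            sample_id=e["sample_id"], time_point=e["time_point"])
        for e in manifest["samples"]
    }
    per_sample = {sid: assign_reads_to_genes(rs, genes) for sid, rs in gene_reads.items()}
    totals = sum((c["ts"] + c["nts"]).to_numpy() for c in per_sample.values())
    dinucs = count_tt_tc_dinucleotides(genes, genome)
    kept_genes = filter_genes(genes, dinucs, totals)
    keep_mask = genes["id"].isin(kept_genes["id"]).to_numpy()
    per_sample = {sid: c[keep_mask].reset_index(drop=True) for sid, c in per_sample.items()}
    lib = {sid: max(1, len(rs)) for sid, rs in gene_reads.items()}
    table = build_gene_repair_table(kept_genes, per_sample, lib)
    table.to_csv(os.path.join(cfg.outdir, "gene_repair.tsv"), sep="\t", index=False)
    tp_order = {tp: i for i, tp in enumerate(dict.fromkeys(
        e["time_point"] for e in manifest["samples"]))}
    sample_ids = [e["sample_id"] for e in manifest["samples"]]
    rpkm_tot = np.column_stack([
        (table[table["sample_id"] == sid]["ts_rpkm"] +
         table[table["sample_id"] == sid]["nts_rpkm"]).to_numpy()
        for sid in sample_ids
    ])
    ranks = [tp_order[e["time_point"]] for e in manifest["samples"]]
    pca = pca_trajectory(rpkm_tot, sample_ids, top_n=cfg.top_n_genes, time_ranks=ranks)
    pca.to_csv(os.path.join(cfg.outdir, "pca_trajectory.tsv"), sep="\t", index=False)
    summary["stages"]["genes"] = {
        "genes_kept": len(kept_genes),
        "mean_ts_ratio": float(np.nanmean(table["ratio"])),
    }

    # ---- damage analysis ----------------------------------------------
    rng = np.random.default_rng([cfg.seed, 101])
    damage = io.read_reads_bed(os.path.join(fdir, manifest["damage_reads"]),
                               sample_id="damage")
    pileup, _ = infer_damage_positions(damage, sizes)
    dhot = call_damage_hotspots(pileup, cfg.damage_min_reads, genome)
    io.write_bed(dhot.assign(start=dhot["pos"], end=dhot["pos"] + 2,
                             name="damage_hotspot", score=dhot["count"])
                 [["chrom", "start", "end", "name", "score", "strand"]]
                 if len(dhot) else pd.DataFrame(columns=["chrom", "start", "end"]),
                 os.path.join(cfg.outdir, "damage_hotspots.bed"), header_lines=_header(cfg))
    exclusions = pd.concat([blacklist[["chrom", "start", "end"]],
                            spots[["chrom", "start", "end"]]], ignore_index=True)
    random_spots = sample_random_spots(max(1, len(spots)), cfg.bin_width, sizes,
                                       exclusions, seed=rng)
    regions = pd.concat([
        spots[["chrom", "start", "end", "category"]],
        random_spots.assign(category="random"),
    ], ignore_index=True)
    dmg_table = quantify_damage_in_regions(pileup, regions, sizes, cfg.extensions)
    dmg_table.to_csv(os.path.join(cfg.outdir, "damage_by_region.tsv"), sep="\t", index=False)
    kw = compare_damage_by_category(dmg_table)
    summary["stages"]["damage"] = {
        "hotspots_plus": int((dhot["strand"] == "+").sum()) if len(dhot) else 0,
        "hotspots_minus": int((dhot["strand"] == "-").sum()) if len(dhot) else 0,
        "kruskal": {int(r.extension): float(r.pvalue) for r in kw.itertuples()},
    }

    # ---- annotation enrichment ----------------------------------------
    hot = spots[spots["category"] == "hotspot"]
    enr_rows = []
    for entry in manifest["annotations"]:
        ann = io.read_bed(os.path.join(fdir, entry["path"]), name=entry["name"])
        ann = AnnotationSet(name=entry["name"], df=ann.df)
        res = bootstrap_enrichment(hot, ann, sizes, blacklist, B=cfg.bootstrap_B,
                                   seed=rng, spot_set_name="hotspots")
        enr_rows.append(res.summary())
    interactions = io.read_bedpe(os.path.join(fdir, manifest["interactions"]))
    hot_counts = count_interactions_per_spot(hot, interactions)
    rnd_counts = count_interactions_per_spot(random_spots.head(len(hot)), interactions)
    _, p_int = interaction_excess_test(hot_counts, rnd_counts)
    track = io.read_bedgraph(os.path.join(fdir, manifest["track"]))
    sig_hot = aggregate_signal(hot, track, sizes)
    sig_rnd = aggregate_signal(random_spots, track, sizes)
    pd.DataFrame(enr_rows).to_csv(os.path.join(cfg.outdir, "enrichment.tsv"),
                                  sep="\t", index=False)
    summary["stages"]["enrichment"] = {
        "annotations": enr_rows,
        "interaction_excess_p": float(p_int),
        "mean_interactions_hotspot": float(np.mean(hot_counts)) if len(hot_counts) else 0.0,
        "mean_signal_hotspot": float(np.mean(sig_hot)) if len(sig_hot) else 0.0,
        "mean_signal_random": float(np.mean(sig_rnd)) if len(sig_rnd) else 0.0,
    }

    # ---- sequence context ---------------------------------------------
    pooled_early = pd.concat([r.df for r in readsets if r.sample_id in early],
                             ignore_index=True)
    spot_reads, random_reads = split_reads_by_spots(pooled_early, hot, rng)
    mats_spot = nucleotide_frequency(ReadSet(df=spot_reads, sample_id="spot_reads",
                                             damage_type=manifest.get("damage_type")),
                                     genome=genome)
    mats_rand = nucleotide_frequency(ReadSet(df=random_reads, sample_id="random_reads",
                                             damage_type=manifest.get("damage_type")),
                                     genome=genome)
    pooled_spot = pool_matrices(mats_spot)
    pooled_rand = pool_matrices(mats_rand)
    cmp = compare_c_enrichment(pooled_spot, pooled_rand) if pooled_spot.n_reads and pooled_rand.n_reads else pd.DataFrame()
    pooled_spot.to_frame().to_csv(os.path.join(cfg.outdir, "context_frequencies.tsv"), sep="\t")
    if len(cmp):
        cmp.to_csv(os.path.join(cfg.outdir, "context_c_enrichment.tsv"), sep="\t", index=False)
    summary["stages"]["seqcontext"] = {
        "spot_reads": int(pooled_spot.n_reads),
        "mean_delta_c": cmp.attrs.get("mean_delta") if len(cmp) else None,
    }

    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def split_reads_by_spots(
    reads_df: pd.DataFrame, spots: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reads overlapping a spot (strand-matched) vs an equally sized random
    draw from the remaining reads."""
    from .core import merge_intervals, intervals_overlap_any

    in_spot = np.zeros(len(reads_df), dtype=bool)
    reads_df = reads_df.reset_index(drop=True)
    for (chrom, strand), sub in spots.groupby(["chrom", "strand"]):
        merged = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        sel = (reads_df["chrom"] == chrom) & (reads_df["strand"] == strand)
        idx = np.flatnonzero(sel.to_numpy())
        if len(idx):
            in_spot[idx] = intervals_overlap_any(
                reads_df.loc[idx, "start"].to_numpy(),
                reads_df.loc[idx, "end"].to_numpy(),
                merged[:, 0], merged[:, 1])
    spot_reads = reads_df[in_spot]
    outside = reads_df[~in_spot]
    k = min(len(spot_reads), len(outside))
    pick = rng.choice(len(outside), size=k, replace=False) if k else np.empty(0, dtype=int)
    return spot_reads.reset_index(drop=True), outside.iloc[np.sort(pick)].reset_index(drop=True)
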