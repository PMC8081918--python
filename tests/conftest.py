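import numpy as np
import pandas as pd
import pytest

import repairspot as rp


@pytest.fixture(scope="session")
def small_config():
    return rp.fixture_config(seed=1, scale="small")


@pytest.fixture(scope="session")
def small_genome(small_config):
    return rp.simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_reads(small_config, small_genome):
    return rp.simulate_xrseq_reads(small_config, small_genome)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The canonical synthetic study, written once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    rp.make_fixture(str(outdir), seed=1, scale="small")
    return str(outdir)


def call_fixture_spots(seed: int):
    """Simulate the canonical study at one seed and run threshold calling.

    Returns (config, called spots frame). Shared by recovery tests and the
    acceptance checks.
    """
    cfg = rp.fixture_config(seed=seed, scale="small")
    genome = rp.simulate_genome(cfg)
    reads = rp.simulate_xrseq_reads(cfg, genome)
    bins = rp.make_bins(genome.sizes, cfg.bin_width)
    rsets = [reads[s.sample_id] for s in cfg.samples]
    depth = min(len(r) for r in rsets)
    rule = rp.ThresholdRule(
        early=[s.sample_id for s in cfg.samples if s.time_point == "1min"],
        late=[s.sample_id for s in cfg.samples if s.time_point == "4h"],
    )
    frames = []
    for strand in "+-":
        Y = rp.build_count_matrix(rsets, bins, strand, depth=depth, seed=seed)
        frames.append(rp.call_spots(Y, rule))
    return cfg, pd.concat(frames, ignore_index=True)


def planted_keys(cfg, category="hotspot"):
    spots = cfg.planted_hotspots if category == "hotspot" else cfg.planted_coldspots
    return {(s.chrom, s.start, s.strand) for s in spots}
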