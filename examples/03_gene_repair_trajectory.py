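"""Gene-level strand-resolved repair and the PCA repair trajectory.

Reads overlapping annotated genes are split into transcribed-strand (TS,
antisense to the gene) and nontranscribed-strand (NTS) counts; TS/(TS+NTS)
quantifies transcription-coupled repair. RPKM-normalized totals of the most
variable genes, projected on principal components, order the samples along
the repair time course.
"""

import numpy as np
from scipy import stats

import repairspot as rp

tps = ["1min", "1min", "5min", "20min", "1h", "2h", "4h", "4h"]
samples = [rp.SampleSpec(f"s{i}", tp, "r", 1000) for i, tp in enumerate(tps)]
cfg = rp.SimConfig(seed=10, chrom_lengths={"chrS1": 200_000}, samples=samples,
                   ts_fraction_per_gene=0.5)
genome = rp.simulate_genome(cfg)
genes, reads = rp.simulate_gene_annotation(cfg, genome, n_genes=60,
                                           reads_per_gene_mean=50,
                                           time_trend_sd=0.5)

counts = {s.sample_id: rp.assign_reads_to_genes(reads[s.sample_id], genes)
          for s in samples}
ratios = np.concatenate([
    (c["ts"] / (c["ts"] + c["nts"]))[(c["ts"] + c["nts"]) > 0]
    for c in counts.values()
])
print(f"mean TS/(TS+NTS) over {len(ratios)} gene-sample pairs: {ratios.mean():.3f}")
print("(the generator plants symmetric strands, so the ratio sits near 0.5 —")
print(" repair without a transcription-coupled component)")

cnt = np.column_stack([(counts[s.sample_id]["ts"] + counts[s.sample_id]["nts"])
                       .to_numpy() for s in samples])
lib = np.array([max(1, len(reads[s.sample_id])) for s in samples])
rpkm = rp.rpkm(cnt, (genes["end"] - genes["start"]).to_numpy(), lib)
ranks = [0, 0, 1, 2, 3, 4, 5, 5]
pca = rp.pca_trajectory(rpkm, [s.sample_id for s in samples], top_n=2000,
                        time_ranks=ranks)
rho = stats.spearmanr(pca["PC1"], ranks).statistic
print(f"\nPC1 vs time-point rank, Spearman rho = {rho:.3f}")
print(pca[["sample_id", "PC1", "PC2"]].round(2).to_string(index=False))
print("\nPC1 increases monotonically with time: the reconstructed repair")
print("trajectory lines up with the experimental time points.")
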