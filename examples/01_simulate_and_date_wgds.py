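"""Simulate a genome with three layered WGDs and date the duplication waves.

Builds a synthetic genome whose paralog families arose from whole-genome
duplications at corrected-4DTv depths 1.33 / 0.85 / 0.40, reconstructs the
families from protein similarity with Markov clustering, computes the
corrected 4DTv for every within-family pair, fits normal mixtures to the
resulting age distribution, and classifies the BIC-best components into
small-scale-duplication (SSD) vs WGD peaks.
"""

import wgdkit as wk

config = wk.WGDSimConfig(
    n_ancestral_genes=150,
    n_chromosomes=3,
    wgd_depths=(1.33, 0.85, 0.40),
    retention_prob=0.6,
    seed=7,
)
genome = wk.simulate_wgd_genome(config)
print(f"simulated genes: {len(genome.genes)} from {config.n_ancestral_genes} ancestors")

proteins = {g.gene_id: g.protein for g in genome.genes}
edges = wk.all_vs_all_similarity(proteins)           # exact SW + Karlin-Altschul E-values
families = wk.mcl_cluster(edges, inflation=6.0, nodes=proteins)
families = wk.filter_family_sizes(families, 2, 8)    # 2-8 members, as for real paralog sets
print(f"similarity edges: {len(edges)}; families of 2-8 members: {len(families)}")

records = wk.family_fourdtv(families, genome.genes, min_sites=30)
values = [r.fourdtv_corrected for r in records if r.passes_filter]
print(f"paralog pairs with >=30 4D sites and below saturation: {len(values)}")

model = wk.select_model_bic(values, seed=7)
report = wk.classify_wgd_peaks(model)
print(f"BIC selects k={model.k} ({model.variance_mode} variance), BIC={model.bic:.1f}")
print(f"WGD peaks reported: {report.n_wgd}")
for mean, sd, weight in report.wgd_peaks:
    print(f"  peak at corrected 4DTv {mean:.2f} +- {sd:.2f}  (weight {weight:.2f})")
print("truth: waves at 0.40, 0.85, 1.33; peaks beyond ~1.5 reflect the")
print("saturation tail of the deepest wave rather than additional WGDs")
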