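"""Summarise paralogons: collinear blocks of paralogous genes.

After one simulated WGD with full retention, every chromosome should pair
with exactly its duplicated copy; anchors are tandem-collapsed family
pairs, blocks are monotone chains of anchors, and the summary counts
anchor points per chromosome and per chromosome pair.
"""

import wgdkit as wk

genome = wk.simulate_wgd_genome(
    wk.WGDSimConfig(
        n_ancestral_genes=60, n_chromosomes=3, wgd_depths=(0.4,),
        retention_prob=1.0, cds_length_codons=150, intergenic_genes=10, seed=29,
    )
)
families = [
    wk.ParalogFamily(fid, set(members))
    for fid, members in genome.truth_families.items()
    if len(members) > 1
]
anchors = wk.build_anchor_pairs(families, genome.genes)
blocks = wk.chain_collinear_blocks(anchors, max_gap_genes=25, min_anchors=3)
print(f"{len(families)} duplicated families -> {len(anchors)} anchors -> {len(blocks)} blocks")
for b in blocks:
    print(f"  {b.chrom_a} ~ {b.chrom_b}: {b.n_anchors} anchors, {b.orientation}")

totals, matrix = wk.paralogon_summary(blocks)
print("anchor points per chromosome:", totals)
print("shared-anchor matrix:")
print(matrix.to_string())
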