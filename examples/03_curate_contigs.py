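"""Curate a contig set: drop redundant duplicates, join terminal overlaps.

Simulates a 20 kb genome cut into three fragments that share >3 kb exact
terminal overlaps, plus two near-identical duplicate contigs, then applies
the two curation rules: remove contigs with >=95% identity and >=80%
coverage against a larger contig, and join terminal overlaps >3 kb at
>=95% identity (thresholds scaled down from chromosome-scale defaults).
"""

from wgdkit import merge_terminal_overlaps, remove_duplicate_contigs, simulate_contig_set

contigs, truth = simulate_contig_set(
    genome_length=20_000, n_duplicates=2, overlap_lengths=[3200, 3600],
    identity_noise=0.02, seed=5, min_overlap=3000,
)
print("input contigs:", ", ".join(f"{c.contig_id} ({len(c):,} bp)" for c in contigs))

dedup = remove_duplicate_contigs(contigs, min_identity=0.95, min_coverage=0.80)
for removed, (kept, identity, coverage) in dedup.removed.items():
    print(f"removed {removed}: {100 * identity:.1f}% identical to {kept} "
          f"over {100 * coverage:.0f}% of its length")
print("expected removals matched truth:", set(dedup.removed) == truth.removed)

merged = merge_terminal_overlaps(dedup.contigs, min_overlap=3000, min_identity=0.95)
for left, right, overlap, identity, merged_id in merged.merges:
    print(f"joined {left} + {right}: {overlap:,} bp overlap at {100 * identity:.1f}% identity")
total = sum(len(c) for c in merged.contigs)
print(f"final: {len(merged.contigs)} contig(s), {total:,} bp "
      f"(truth: {truth.final_n_contigs} contig(s), {truth.final_total_length:,} bp)")
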