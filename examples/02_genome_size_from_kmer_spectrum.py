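"""Estimate genome size from a diploid k-mer copy-number spectrum.

Simulates the 31-mer spectrum of a 1 Mb diploid genome sequenced to 50x
with 0.8% heterozygosity and sequencing errors, detects the error minimum
and the heterozygous/homozygous modes, and applies the Lander-Waterman
conversion with error-k-mer subtraction.
"""

from wgdkit import simulate_kmer_histogram
from wgdkit.kmer_profile import detect_kcn_peaks, estimate_genome_size

GENOME_SIZE = 1_000_000
hist, truth = simulate_kmer_histogram(
    GENOME_SIZE, coverage=50, read_len=150, k=31,
    heterozygosity=0.008, error_rate=0.002, seed=11,
)
print(f"simulated: genome {GENOME_SIZE:,} bp, k-mer depth c = {truth['kmer_depth']:.1f}")

peaks = detect_kcn_peaks(hist)
print(f"error minimum at KCN {peaks.error_minimum}")
print(f"heterozygous mode at KCN {peaks.het_peak}, homozygous mode at KCN {peaks.hom_peak}")
print(f"hom/het ratio {peaks.hom_peak / peaks.het_peak:.2f} (expected ~2 for a diploid)")

est = estimate_genome_size(hist, peaks)
rel_err = abs(est.genome_size - GENOME_SIZE) / GENOME_SIZE
print(f"total k-mer instances {est.total_kmer_instances:,}; "
      f"error instances subtracted {est.error_kmer_instances:,}")
print(f"estimated genome size: {est.genome_size:,.0f} bp ({100 * rel_err:.2f}% off truth)")
print(f"read-coverage equivalent of the homozygous depth: "
      f"{est.read_depth_in_read_coverage(150, 31):.1f}x")
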