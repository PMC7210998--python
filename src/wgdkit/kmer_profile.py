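"""Genome-size estimation from a k-mer copy-number (KCN) spectrum.

The homozygous single-copy mode of the spectrum gives the k-mer read depth;
genome size follows by Lander-Waterman arithmetic: total k-mer instances,
minus the instances at or below the first minimum (sequencing errors),
divided by the homozygous depth.  Peak KCNs are reported in k-mer coverage
units; conversion to per-base read coverage multiplies by L/(L-k+1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .model import KmerHistogram


class PeakDetectionError(ValueError):
    """Raised when no usable mode exists in the spectrum."""


@dataclass(frozen=True)
class KcnPeaks:
    """Landmarks of a KCN spectrum.

    ``error_minimum`` is the KCN of the first local minimum separating the
    sequencing-error spike from the genomic modes (0 when the spectrum has
    no error spike); ``het_peak`` is absent for effectively haploid data.
    """

    error_minimum: int
    het_peak: Optional[int]
    hom_peak: int


@dataclass(frozen=True)
class GenomeSizeEstimate:
    read_depth: float  # homozygous-mode depth in k-mer coverage units
    total_kmer_instances: int
    error_kmer_instances: int
    genome_size: float

    def read_depth_in_read_coverage(self, read_len: int, k: int) -> float:
        """Convert the k-mer depth to per-base read coverage (informational)."""
        return self.read_depth * read_len / (read_len - k + 1)


_PARTNER_RATIO = (1.7, 2.3)  # acceptable hom/het KCN ratio
_PARTNER_MIN_HEIGHT = 0.2  # secondary mode must reach this fraction of the main mode


def detect_kcn_peaks(hist: KmerHistogram, smoothing_window: int = 5) -> KcnPeaks:
    """Locate the error minimum and the heterozygous/homozygous modes.

    Counts are smoothed with a centered moving average, the first KCN where
    the smoothed counts stop decreasing marks the error minimum, and modes
    are local maxima above it ranked by height.  Two modes whose KCN ratio
    is approximately 2 (within [1.7, 2.3]) are reported as the het/hom
    pair; otherwise the single highest mode is the homozygous peak.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    max_kcn = hist.kcn[-1]
    dense = np.zeros(max_kcn + 1, dtype=float)
    for kcn, count in hist.entries:
        dense[kcn] = count
    smoothed = uniform_filter1d(dense[1:], size=smoothing_window, mode="nearest")

    # first KCN (1-based) where the smoothed spectrum stops decreasing
    error_minimum = 0
    for i in range(len(smoothed) - 1):
        if smoothed[i + 1] >= smoothed[i]:
            error_minimum = i + 1 if i > 0 else 0
            break
    else:
        raise PeakDetectionError("spectrum decreases monotonically: no genomic mode")

    modes = []
    for i in range(1, len(smoothed) - 1):
        kcn = i + 1
        if kcn <= error_minimum:
            continue
        if smoothed[i] > smoothed[i - 1] and smoothed[i] >= smoothed[i + 1]:
            modes.append((smoothed[i], kcn))
    if not modes:
        raise PeakDetectionError("no local maximum above the error minimum")
    modes.sort(reverse=True)

    if len(modes) >= 2 and modes[1][0] >= _PARTNER_MIN_HEIGHT * modes[0][0]:
        kcn_pair = sorted((modes[0][1], modes[1][1]))
        ratio = kcn_pair[1] / kcn_pair[0]
        if _PARTNER_RATIO[0] <= ratio <= _PARTNER_RATIO[1]:
            return KcnPeaks(error_minimum=error_minimum, het_peak=kcn_pair[0], hom_peak=kcn_pair[1])
    return KcnPeaks(error_minimum=error_minimum, het_peak=None, hom_peak=modes[0][1])


def estimate_genome_size(hist: KmerHistogram, peaks: KcnPeaks) -> GenomeSizeEstimate:
    """Lander-Waterman genome size with error-k-mer subtraction.

    genome_size = (sum of kcn*count  -  sum over kcn <= error_minimum) / hom_peak.
    """
    if peaks.hom_peak <= 0:
        raise ValueError("homozygous peak depth must be positive")
    kcn = np.array(hist.kcn, dtype=np.int64)
    counts = np.array(hist.counts, dtype=np.int64)
    instances = kcn * counts
    total = int(instances.sum())
    error = int(instances[kcn <= peaks.error_minimum].sum())
    return GenomeSizeEstimate(
        read_depth=float(peaks.hom_peak),
        total_kmer_instances=total,
        error_kmer_instances=error,
        genome_size=(total - error) / peaks.hom_peak,
    )
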