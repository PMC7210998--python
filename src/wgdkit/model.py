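"""Shared domain types for the WGD-inference pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion
to and from 1-based inclusive conventions (GFF3, BLAST tabular) happens only
at format boundaries in :mod:`wgdkit.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GeneModel:
    """A positioned, named gene with optional protein and CDS sequence.

    ``rank`` is the 0-based ordinal of the gene along its chromosome, by
    start coordinate; it is dense and unique per chromosome and is the unit
    in which tandem gaps and synteny gaps are measured.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    rank: int = -1
    protein: str = ""
    cds: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.name:
            self.name = self.gene_id

    def validate_sequences(self) -> None:
        """Check CDS length and CDS/protein concordance when both present."""
        if self.cds:
            if len(self.cds) % 3 != 0:
                raise ValueError(
                    f"gene {self.gene_id}: CDS length {len(self.cds)} not divisible by 3"
                )
            if self.protein:
                translated = str(Seq(self.cds).translate())
                if translated.endswith("*"):
                    translated = translated[:-1]
                if "*" in translated:
                    raise ValueError(f"gene {self.gene_id}: internal stop codon in CDS")
                if translated != self.protein:
                    raise ValueError(
                        f"gene {self.gene_id}: CDS does not translate to protein"
                    )


@dataclass(frozen=True)
class Contig:
    """A named assembly contig."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimilarityEdge:
    """One pairwise protein similarity hit (best HSP of a pair)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_cov: float = float("nan")
    subject_cov: float = float("nan")

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError("self-hit edges are not allowed")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class KmerHistogram:
    """A k-mer copy-number (KCN) spectrum: count of distinct k-mers per KCN."""

    k: int
    entries: tuple  # of (kcn, count) pairs, kcn strictly increasing

    def __post_init__(self) -> None:
        kcns = [kcn for kcn, _ in self.entries]
        if not kcns:
            raise ValueError("empty histogram")
        if any(k2 <= k1 for k1, k2 in zip(kcns, kcns[1:])):
            raise ValueError("KCN values must be strictly increasing")
        if any(kcn <= 0 or count < 0 for kcn, count in self.entries):
            raise ValueError("KCN must be positive and counts nonnegative")
        if all(count == 0 for _, count in self.entries):
            raise ValueError("histogram has no nonzero entry")

    @property
    def kcn(self):
        return tuple(kcn for kcn, _ in self.entries)

    @property
    def counts(self):
        return tuple(count for _, count in self.entries)


@dataclass(frozen=True)
class FourDTvRecord:
    """A paralog pair's 4D-site tally and raw/corrected transversion distance."""

    id_a: str
    id_b: str
    n_4d_sites: int
    n_transversions: int
    fourdtv_raw: float
    fourdtv_corrected: Optional[float]  # None when saturated (raw >= 0.5)
    passes_filter: bool

    @property
    def saturated(self) -> bool:
        return self.fourdtv_corrected is None and self.n_4d_sites > 0


@dataclass
class TandemCluster:
    """A chromosome-local run of >=3 same-name, high-identity gene copies."""

    chromosome: str
    member_ids: list
    name: str
    span_bp: int
    n_genes: int
    confirmed: Optional[bool] = None
    best_reference: dict = field(default_factory=dict)


def assign_ranks(genes: Sequence[GeneModel]) -> None:
    """Assign dense per-chromosome ranks in place, ordering by start.

    Ties on start are broken by end then gene_id so ranks are deterministic.
    """
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(members):
            g.rank = rank
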