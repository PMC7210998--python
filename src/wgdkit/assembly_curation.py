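"""Contig-level curation: duplicate (heterozygous) contig removal and
joining of long, high-identity terminal overlaps.

Both operations measure identity as matches / aligned columns and coverage
as the aligned span of the smaller contig divided by its length, from an
exact affine-gap local alignment for small inputs or a seed-and-extend
engine reporting the same definitions at contig scale.  A shared-k-mer
prefilter only decides which pairs are worth aligning; it never produces
the reported numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._align import (
    LocalAlignment,
    local_align_nucleotide,
    reverse_complement,
    shared_kmer_count,
)
from .model import Contig

_PREFILTER_KMER = 21
_PREFILTER_MIN_SHARED = 20


@dataclass
class CurationReport:
    """Outcome of a curation operation.

    ``removed`` maps a removed contig id to (kept_id, identity, coverage);
    ``merges`` lists (id_a, id_b, overlap_len, identity, merged_id) with
    id_a contributing its bases inside the overlap.
    """

    removed: Dict[str, Tuple[str, float, float]] = field(default_factory=dict)
    merges: List[Tuple[str, str, int, float, str]] = field(default_factory=list)
    contigs: List[Contig] = field(default_factory=list)

    @property
    def surviving(self) -> List[str]:
        return [c.contig_id for c in self.contigs]


def _size_order_key(contig: Contig) -> Tuple[int, str]:
    # larger first; at equal length the lexicographically earlier id is kept
    return (-len(contig), contig.contig_id)


def remove_duplicate_contigs(
    contigs: Sequence[Contig],
    min_identity: float = 0.95,
    min_coverage: float = 0.80,
    engine: str = "auto",
) -> CurationReport:
    """Remove contigs that are near-identical copies of a larger survivor.

    A contig is removed when a local alignment against a larger (or
    equal-length, lexicographically earlier) surviving contig reaches
    ``min_identity`` over at least ``min_coverage`` of the smaller contig's
    length.  Removals cascade: a removed contig cannot justify removing
    anything else.
    """
    report = CurationReport()
    if not contigs:
        return report
    ids = [c.contig_id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("contig ids must be unique")

    survivors: List[Contig] = []
    # process largest first so every candidate is only compared to survivors
    for contig in sorted(contigs, key=_size_order_key):
        removed_by: Optional[Tuple[str, float, float]] = None
        for kept in survivors:
            if shared_kmer_count(kept.sequence, contig.sequence, _PREFILTER_KMER) < _PREFILTER_MIN_SHARED:
                continue
            best = None
            for target_seq in (kept.sequence, reverse_complement(kept.sequence)):
                aln = local_align_nucleotide(target_seq, contig.sequence, engine=engine)
                if aln and (best is None or aln.score > best.score):
                    best = aln
            if best is None:
                continue
            coverage = best.query_coverage(len(contig))
            if best.identity >= min_identity and coverage >= min_coverage:
                removed_by = (kept.contig_id, best.identity, coverage)
                break
        if removed_by is None:
            survivors.append(contig)
        else:
            report.removed[contig.contig_id] = removed_by
    # restore input order among survivors
    order = {c.contig_id: i for i, c in enumerate(contigs)}
    survivors.sort(key=lambda c: order[c.contig_id])
    report.contigs = survivors
    return report


@dataclass(frozen=True)
class _OverlapCandidate:
    left: Contig  # contributes its bases in the overlap
    right: Contig
    right_is_rc: bool
    overlap_len: int
    identity: float
    right_trim: int  # bases of (possibly reverse-complemented) right inside the overlap


def _terminal_overlap(
    a: Contig, b: Contig, min_overlap: int, min_identity: float, end_slack: int,
    engine: str = "auto",
) -> List[_OverlapCandidate]:
    """Find suffix/prefix overlaps between two contigs in both orientations."""
    out: List[_OverlapCandidate] = []
    for right_is_rc in (False, True):
        b_seq = reverse_complement(b.sequence) if right_is_rc else b.sequence
        if shared_kmer_count(a.sequence, b_seq, _PREFILTER_KMER) < _PREFILTER_MIN_SHARED:
            continue
        aln = local_align_nucleotide(a.sequence, b_seq, engine=engine)
        if aln is None or aln.columns <= min_overlap or aln.identity < min_identity:
            continue
        a_suffix = aln.target_end >= len(a) - end_slack
        b_prefix = aln.query_start <= end_slack
        b_suffix = aln.query_end >= len(b) - end_slack
        a_prefix = aln.target_start <= end_slack
        if a_suffix and b_prefix:
            out.append(
                _OverlapCandidate(a, b, right_is_rc, aln.columns, aln.identity, aln.query_end)
            )
        elif b_suffix and a_prefix:
            # b's suffix overlaps a's prefix: b is the left partner
            out.append(
                _OverlapCandidate(
                    b if not right_is_rc else Contig(b.contig_id, b_seq),
                    a,
                    False,
                    aln.columns,
                    aln.identity,
                    aln.target_end,
                )
            )
    return out


def merge_terminal_overlaps(
    contigs: Sequence[Contig],
    min_overlap: int = 30000,
    min_identity: float = 0.95,
    end_slack: int = 100,
    engine: str = "auto",
) -> CurationReport:
    """Join contigs whose terminal regions overlap by more than ``min_overlap``
    base pairs at ``min_identity`` or better.

    Within a pass, merges are applied greedily by decreasing overlap length
    and each contig participates in at most one merge; passes repeat until a
    fixed point so chains of overlapping contigs collapse fully.  The left
    contig's bases are kept inside the overlap.  Unresolvable (circular)
    overlaps are left unmerged with a warning.
    """
    current: List[Contig] = list(contigs)
    report = CurationReport()
    while True:
        candidates: List[_OverlapCandidate] = []
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                candidates.extend(
                    _terminal_overlap(
                        current[i], current[j], min_overlap, min_identity, end_slack, engine
                    )
                )
        candidates.sort(key=lambda c: (-c.overlap_len, c.left.contig_id, c.right.contig_id))
        used = set()
        merged_any = False
        merged_out: Dict[str, Contig] = {}
        consumed = set()
        for cand in candidates:
            if cand.left.contig_id in used or cand.right.contig_id in used:
                continue
            used.update((cand.left.contig_id, cand.right.contig_id))
            right_seq = (
                reverse_complement(cand.right.sequence) if cand.right_is_rc else cand.right.sequence
            )
            merged_id = f"{cand.left.contig_id}+{cand.right.contig_id}"
            merged = Contig(merged_id, cand.left.sequence + right_seq[cand.right_trim :])
            report.merges.append(
                (cand.left.contig_id, cand.right.contig_id, cand.overlap_len, cand.identity, merged_id)
            )
            merged_out[cand.left.contig_id] = merged
            consumed.add(cand.right.contig_id)
            merged_any = True
        if not merged_any:
            break
        nxt: List[Contig] = []
        for c in current:
            if c.contig_id in consumed:
                continue
            nxt.append(merged_out.get(c.contig_id, c))
        if len(nxt) == len(current):  # pragma: no cover - defensive
            warnings.warn("circular overlap chain left unmerged")
            break
        current = nxt
    report.contigs = current
    return report


def curate_contigs(
    contigs: Sequence[Contig],
    min_identity: float = 0.95,
    min_coverage: float = 0.80,
    min_overlap: int = 30000,
    engine: str = "auto",
) -> CurationReport:
    """Full curation: duplicate removal followed by terminal-overlap joining."""
    dedup = remove_duplicate_contigs(
        contigs, min_identity=min_identity, min_coverage=min_coverage, engine=engine
    )
    merged = merge_terminal_overlaps(
        dedup.contigs, min_overlap=min_overlap, min_identity=min_identity, engine=engine
    )
    return CurationReport(removed=dedup.removed, merges=merged.merges, contigs=merged.contigs)
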