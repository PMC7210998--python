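"""Pairwise alignment helpers shared by the curation, family and 4DTv stages.

Exact affine-gap dynamic programming (Bio.Align.PairwiseAligner) is the
reference engine for every identity/coverage computation.  For contig-scale
inputs a cheap shared-k-mer / edlib prefilter is used to skip pairs that
cannot reach the identity thresholds; the final numbers always come from the
exact alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
from Bio import Align
from Bio.Align import substitution_matrices

REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]


@lru_cache(maxsize=None)
def _protein_global_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@lru_cache(maxsize=None)
def _protein_local_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@lru_cache(maxsize=None)
def _nucleotide_local_aligner() -> Align.PairwiseAligner:
    # blastn-like scoring: match 2, mismatch -3, gap 5/2
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def align_protein_pair(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> Tuple[str, str]:
    """Global affine-gap protein alignment; returns the two gapped strings.

    Identical inputs take a direct gapless path.  Ties are broken
    deterministically by taking the aligner's first optimal traceback.
    """
    if not a or not b:
        raise ValueError("cannot align an empty protein sequence")
    if a == b:
        return a, b
    alignment = _protein_global_aligner(gap_open, gap_extend).align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def protein_alignment_identity(a: str, b: str, **kwargs) -> float:
    """Fraction of identical columns in the global protein alignment."""
    ga, gb = align_protein_pair(a, b, **kwargs)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / len(ga)


@lru_cache(maxsize=1)
def _blosum62_diagonal() -> dict:
    matrix = substitution_matrices.load("BLOSUM62")
    return {res: float(matrix[res, res]) for res in matrix.alphabet}


def protein_local_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman score under BLOSUM62 with BLAST-default gap costs."""
    if a == b:
        diag = _blosum62_diagonal()
        return sum(diag[res] for res in a)
    return float(_protein_local_aligner(gap_open, gap_extend).score(a, b))


@dataclass(frozen=True)
class LocalAlignment:
    """Summary of the best local nucleotide alignment of query against target."""

    score: float
    matches: int
    columns: int
    target_start: int
    target_end: int
    query_start: int
    query_end: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    def query_coverage(self, query_length: int) -> float:
        return (self.query_end - self.query_start) / query_length


_EXACT_CELL_LIMIT = 4_000_000  # above this, "auto" switches to seed-and-extend


def local_align_nucleotide(
    target: str, query: str, engine: str = "auto"
) -> Optional[LocalAlignment]:
    """Best local alignment of *query* against *target*.

    ``engine="exact"`` runs affine-gap Smith-Waterman; ``"seed"`` chains
    shared 21-mers on a common diagonal band and scores the implied region
    with edlib, reporting identity and coverage under the same definitions
    (matches / aligned columns; span of query covered).  ``"auto"`` uses
    the exact engine while len(target)*len(query) stays small.
    """
    if engine not in ("auto", "exact", "seed"):
        raise ValueError("engine must be 'auto', 'exact' or 'seed'")
    if engine == "auto":
        engine = "exact" if len(target) * len(query) <= _EXACT_CELL_LIMIT else "seed"
    if engine == "seed":
        return _seed_local_align(target, query)
    return _exact_local_align(target, query)


def _exact_local_align(target: str, query: str) -> Optional[LocalAlignment]:
    if query == target:
        n = len(query)
        return LocalAlignment(2.0 * n, n, n, 0, n, 0, n)
    aligner = _nucleotide_local_aligner()
    alignments = aligner.align(target, query)
    if len(alignments) == 0:
        return None
    alignment = alignments[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    coords = alignment.coordinates
    return LocalAlignment(
        score=float(alignment.score),
        matches=matches,
        columns=len(ga),
        target_start=int(coords[0][0]),
        target_end=int(coords[0][-1]),
        query_start=int(coords[1][0]),
        query_end=int(coords[1][-1]),
    )


def _seed_local_align(
    target: str, query: str, k: int = 21, band: int = 30, end_slack: int = 200
) -> Optional[LocalAlignment]:
    """Seed-and-extend local alignment for contig-scale sequences.

    Shared k-mers are grouped by diagonal; the widest consistent band
    defines candidate query/target spans, which are extended to the
    sequence ends when within ``end_slack`` and scored globally with edlib.
    Identity = matches / aligned columns as in the exact engine.
    """
    if query == target:
        n = len(query)
        return LocalAlignment(2.0 * n, n, n, 0, n, 0, n)
    positions = {}
    for i in range(len(target) - k + 1):
        positions.setdefault(target[i : i + k], []).append(i)
    hits = []  # (diagonal, query_pos, target_pos)
    for qp in range(len(query) - k + 1):
        for tp in positions.get(query[qp : qp + k], ()):
            hits.append((tp - qp, qp, tp))
    if not hits:
        return None
    # aggregate seeds per diagonal, then find the widest band of diagonals
    per_diag = {}
    for d, qp, tp in hits:
        if d in per_diag:
            qs0, qe0, ts0, te0 = per_diag[d]
            per_diag[d] = (min(qs0, qp), max(qe0, qp), min(ts0, tp), max(te0, tp))
        else:
            per_diag[d] = (qp, qp, tp, tp)
    diags = sorted(per_diag)
    best_span, best_spans = -1, None
    lo = 0
    for hi in range(len(diags)):
        while diags[hi] - diags[lo] > band:
            lo += 1
        window = [per_diag[d] for d in diags[lo : hi + 1]]
        qs = min(w[0] for w in window)
        qe = max(w[1] for w in window) + k
        ts = min(w[2] for w in window)
        te = max(w[3] for w in window) + k
        if qe - qs > best_span:
            best_span = qe - qs
            best_spans = (qs, qe, ts, te)
    qs, qe, ts, te = best_spans
    # extend to the sequence ends when the unseeded tail is short
    if qs <= end_slack and ts >= qs:
        ts -= qs
        qs = 0
    if len(query) - qe <= end_slack and len(target) - te >= len(query) - qe:
        te += len(query) - qe
        qe = len(query)
    result = edlib.align(query[qs:qe], target[ts:te], mode="NW", task="path")
    columns = sum(
        int(num) for num, op in _CIGAR_RE.findall(result["cigar"] or "")
    )
    matches = columns - result["editDistance"]
    return LocalAlignment(
        score=2.0 * matches,
        matches=matches,
        columns=columns,
        target_start=ts,
        target_end=te,
        query_start=qs,
        query_end=qe,
    )


def shared_kmer_count(a: str, b: str, k: int = 21) -> int:
    """Number of distinct k-mers shared by two sequences (seed prefilter)."""
    if len(a) < k or len(b) < k:
        return 0
    kmers_a = {a[i : i + k] for i in range(len(a) - k + 1)}
    kmers_b = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(kmers_a & kmers_b)


def edlib_identity_upper_bound(query: str, target: str) -> float:
    """Cheap upper bound on achievable local identity of query in target.

    Uses edlib infix edit distance: identity cannot exceed
    1 - distance / len(query) for any alignment covering the whole query,
    and longer partial alignments only do worse per column.
    """
    result = edlib.align(query, target, mode="HW", task="distance")
    dist = result["editDistance"]
    if dist < 0:
        return 1.0
    return max(0.0, 1.0 - dist / len(query))
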