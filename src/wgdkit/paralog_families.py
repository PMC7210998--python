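"""Paralogous gene families: all-vs-all protein similarity, Markov
clustering (MCL), family-size filtering and tandem collapsing.

The MCL implementation follows the classical algorithm: a column-stochastic
transition matrix with self-loops, alternating expansion (matrix squaring)
and inflation (entrywise power + column renormalisation) with pruning of
tiny entries, iterated to a doubly idempotent limit whose nonzero pattern
yields the clusters.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from ._align import protein_local_score
from .io_formats import read_similarity_tabular
from .model import GeneModel, SimilarityEdge

# Karlin-Altschul parameters for gapped BLOSUM62 with BLAST default gap costs
KA_LAMBDA = 0.267
KA_K = 0.041

MAX_EDGE_WEIGHT = 200.0  # cap on -log10(E-value)


@dataclass
class ParalogFamily:
    family_id: str
    members: Set[str]
    representatives: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a family must have at least one member")
        if not self.representatives:
            self.representatives = set(self.members)
        if not self.representatives <= self.members:
            raise ValueError("representatives must be a subset of members")

    @property
    def size(self) -> int:
        return len(self.members)


def karlin_altschul_evalue(score: float, query_len: int, db_len: int) -> float:
    """Gapped Karlin-Altschul E-value for a local alignment score."""
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


_SEED_KMER = 6
_SEED_MIN_SHARED = 8
_SEED_MAX_BUCKET = 50  # ignore k-mers present in more proteins (low complexity)
_SEED_SHORT_PROTEIN = 25  # proteins this short are always aligned


def _candidate_pairs(proteins: Mapping[str, str]) -> Set[Tuple[str, str]]:
    """Pairs worth aligning, from an inverted protein k-mer index.

    Identical sequences are grouped first (every within- and cross-group
    pair of matching groups is a candidate); one representative per group
    is indexed by its distinct 6-mers and representative pairs sharing at
    least ``_SEED_MIN_SHARED`` of them are expanded back to gene pairs.
    Pairs involving a very short protein are always candidates, so the
    prefilter never hides a scorable alignment at test scale.
    """
    groups: Dict[str, List[str]] = {}
    for pid in sorted(proteins):
        groups.setdefault(proteins[pid], []).append(pid)

    out: Set[Tuple[str, str]] = set()
    for members in groups.values():
        out.update(itertools.combinations(members, 2))

    reps = {members[0]: seq for seq, members in groups.items()}
    index: Dict[str, List[str]] = {}
    for rid in sorted(reps):
        seq = reps[rid]
        for kmer in {seq[i : i + _SEED_KMER] for i in range(len(seq) - _SEED_KMER + 1)}:
            index.setdefault(kmer, []).append(rid)
    shared: Dict[Tuple[str, str], int] = {}
    for bucket in index.values():
        if len(bucket) < 2 or len(bucket) > _SEED_MAX_BUCKET:
            continue
        for a, b in itertools.combinations(bucket, 2):
            shared[(a, b)] = shared.get((a, b), 0) + 1
    for (ra, rb), count in shared.items():
        if count < _SEED_MIN_SHARED:
            continue
        for a in groups[reps[ra]]:
            for b in groups[reps[rb]]:
                out.add((min(a, b), max(a, b)))
    short = [pid for pid in proteins if len(proteins[pid]) < _SEED_SHORT_PROTEIN]
    for pid in short:
        for other in proteins:
            if other != pid:
                out.add((min(pid, other), max(pid, other)))
    return out


def all_vs_all_similarity(
    proteins: Mapping[str, str],
    max_evalue: float = 1e-8,
    precomputed: Optional[Iterable[SimilarityEdge]] = None,
    tabular_path=None,
) -> List[SimilarityEdge]:
    """All-vs-all protein similarity edges at an E-value threshold.

    The primary path ingests precomputed BLAST tabular hits (``tabular_path``
    via :func:`wgdkit.io_formats.read_similarity_tabular`, or ``precomputed``
    edges).  Otherwise exact Smith-Waterman alignments (BLOSUM62, affine
    gaps 11/1) are computed for every pair passing the 6-mer seed index, and
    scores are converted to E-values with gapped Karlin-Altschul parameters
    against the total database length.  Symmetric duplicates are collapsed
    keeping the better E-value.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    if tabular_path is not None:
        lengths = {k: len(v) for k, v in proteins.items()}
        precomputed = read_similarity_tabular(tabular_path, lengths, lengths)
    if precomputed is not None:
        best: Dict[frozenset, SimilarityEdge] = {}
        for edge in precomputed:
            key = frozenset((edge.query_id, edge.subject_id))
            if key not in best or edge.evalue < best[key].evalue:
                best[key] = edge
        return sorted(
            (e for e in best.values() if e.evalue <= max_evalue),
            key=lambda e: (e.query_id, e.subject_id),
        )

    db_len = sum(len(s) for s in proteins.values())
    edges: List[SimilarityEdge] = []
    for qid, sid in sorted(_candidate_pairs(proteins)):
        a, b = proteins[qid], proteins[sid]
        score = protein_local_score(a, b)
        evalue = karlin_altschul_evalue(score, len(a), db_len)
        if evalue > max_evalue:
            continue
        bitscore = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)
        if a == b:
            identity, length = 100.0, len(a)
        else:
            from ._align import align_protein_pair

            ga, gb = align_protein_pair(a, b)
            matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
            identity, length = 100.0 * matches / len(ga), len(ga)
        edges.append(
            SimilarityEdge(
                query_id=qid,
                subject_id=sid,
                percent_identity=identity,
                alignment_length=length,
                evalue=evalue,
                bitscore=bitscore,
                query_cov=1.0,
                subject_cov=1.0,
            )
        )
    return edges


def edge_weight(edge: SimilarityEdge, scheme: str = "neg_log_evalue") -> float:
    if scheme == "neg_log_evalue":
        if edge.evalue <= 0:
            return MAX_EDGE_WEIGHT
        return min(-math.log10(edge.evalue), MAX_EDGE_WEIGHT)
    if scheme == "bitscore":
        return max(edge.bitscore, 1e-6)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def mcl_cluster(
    edges: Sequence[SimilarityEdge],
    inflation: float = 6.0,
    weight: str = "neg_log_evalue",
    max_iter: int = 200,
    tol: float = 1e-8,
    nodes: Optional[Iterable[str]] = None,
) -> List[ParalogFamily]:
    """Markov clustering of the similarity graph.

    Self-loops are set to each node's maximum incident weight (1.0 for
    isolated nodes); columns are normalised, then expansion (matrix square)
    alternates with inflation (entrywise power ``inflation`` followed by
    column renormalisation), pruning entries below ``tol``.  At convergence
    the connected components of the limit matrix's nonzero pattern are the
    clusters; nodes listed in ``nodes`` but absent from the graph come back
    as singletons.  Deterministic.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    node_set = set(nodes) if nodes is not None else set()
    for e in edges:
        node_set.update((e.query_id, e.subject_id))
    if not node_set:
        return []
    names = sorted(node_set)
    index = {n: i for i, n in enumerate(names)}
    n = len(names)

    rows, cols, vals = [], [], []
    max_incident = np.zeros(n)
    for e in edges:
        w = edge_weight(e, weight)
        if w <= 0:
            raise ValueError("edge weights must be positive")
        i, j = index[e.query_id], index[e.subject_id]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        max_incident[i] = max(max_incident[i], w)
        max_incident[j] = max(max_incident[j], w)
    loops = np.where(max_incident > 0, max_incident, 1.0)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loops)
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    matrix = _normalize_columns(matrix)

    for iteration in range(max_iter):
        previous = matrix.copy()
        matrix = matrix @ matrix  # expansion
        matrix.data = np.power(matrix.data, inflation)  # inflation
        matrix = _normalize_columns(matrix)
        matrix.data[matrix.data < tol] = 0.0
        matrix.eliminate_zeros()
        matrix = _normalize_columns(matrix)
        diff = abs(matrix - previous)
        if diff.nnz == 0 or diff.max() < math.sqrt(tol):
            break
    else:
        raise RuntimeError(f"MCL did not converge within {max_iter} iterations")

    pattern = matrix + matrix.T
    n_comp, labels = connected_components(pattern, directed=False)
    clusters: Dict[int, List[str]] = {}
    for name, label in zip(names, labels):
        clusters.setdefault(label, []).append(name)
    ordered = sorted(clusters.values(), key=lambda ms: min(ms))
    return [
        ParalogFamily(family_id=f"F{i:05d}", members=set(ms)) for i, ms in enumerate(ordered)
    ]


def _normalize_columns(matrix: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(matrix.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    scale = sp.diags(1.0 / sums)
    return (matrix @ scale).tocsr()


def filter_family_sizes(
    families: Iterable[ParalogFamily], min_size: int = 2, max_size: int = 8
) -> List[ParalogFamily]:
    """Keep families whose member count lies in [min_size, max_size]."""
    return [f for f in families if min_size <= f.size <= max_size]


def collapse_tandem_members(
    family: ParalogFamily,
    genes: Sequence[GeneModel],
    max_intervening: int = 5,
) -> ParalogFamily:
    """Collapse same-chromosome members separated by few intervening genes.

    Members on one chromosome whose rank gaps (intervening gene counts) are
    at most ``max_intervening`` are grouped transitively; each group keeps
    its longest-protein member (ties: smaller rank) as representative.
    """
    lookup = {g.gene_id: g for g in genes}
    by_chrom: Dict[str, List[GeneModel]] = {}
    missing = []
    for gid in family.members:
        gene = lookup.get(gid)
        if gene is None:
            missing.append(gid)
            continue
        by_chrom.setdefault(gene.chromosome, []).append(gene)
    if missing:
        warnings.warn(f"family {family.family_id}: members without gene models: {missing}")

    representatives: Set[str] = set(missing)
    for members in by_chrom.values():
        members.sort(key=lambda g: g.rank)
        group: List[GeneModel] = []
        groups: List[List[GeneModel]] = []
        for gene in members:
            if group and gene.rank - group[-1].rank - 1 > max_intervening:
                groups.append(group)
                group = []
            group.append(gene)
        groups.append(group)
        for grp in groups:
            best = max(grp, key=lambda g: (len(g.protein), -g.rank))
            representatives.add(best.gene_id)
    return ParalogFamily(
        family_id=family.family_id,
        members=set(family.members),
        representatives=representatives,
    )
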