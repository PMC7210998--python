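"""Tandem gene-cluster detection.

The rule, applied per chromosome and per gene name:

1. same-name genes are chained while consecutive occurrences are separated
   by at most ``max_intervening`` unrelated (differently named) genes;
2. within a chain, members are linked when their global protein-alignment
   identity reaches ``min_identity`` (single linkage), and each connected
   component of that relation is a candidate cluster;
3. components with at least ``min_size`` members are reported.

Dropped low-identity copies still carry the cluster's name, so they do not
count as "unrelated" genes and never break the chain around the survivors.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import networkx as nx

from ._align import protein_alignment_identity, protein_local_score
from .model import GeneModel, TandemCluster


def _chains(occurrences: Sequence[GeneModel], max_intervening: int) -> List[List[GeneModel]]:
    chains: List[List[GeneModel]] = []
    chain: List[GeneModel] = []
    for gene in occurrences:
        if chain and gene.rank - chain[-1].rank - 1 > max_intervening:
            chains.append(chain)
            chain = []
        chain.append(gene)
    if chain:
        chains.append(chain)
    return chains


def find_tandem_clusters(
    genes: Sequence[GeneModel],
    max_intervening: int = 5,
    min_identity: float = 0.70,
    min_size: int = 3,
) -> List[TandemCluster]:
    """Detect runs of >= min_size same-name, high-identity gene copies."""
    by_key: Dict[tuple, List[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.chromosome, g.name), []).append(g)

    clusters: List[TandemCluster] = []
    for (chromosome, name), occurrences in sorted(by_key.items()):
        if len(occurrences) < min_size:
            continue
        occurrences.sort(key=lambda g: g.rank)
        for chain in _chains(occurrences, max_intervening):
            if len(chain) < min_size:
                continue
            graph = nx.Graph()
            graph.add_nodes_from(g.gene_id for g in chain)
            for i in range(len(chain)):
                for j in range(i + 1, len(chain)):
                    a, b = chain[i], chain[j]
                    if not a.protein or not b.protein:
                        warnings.warn(
                            f"missing protein for {a.gene_id}/{b.gene_id}: identity check skipped"
                        )
                        continue
                    if protein_alignment_identity(a.protein, b.protein) >= min_identity:
                        graph.add_edge(a.gene_id, b.gene_id)
            lookup = {g.gene_id: g for g in chain}
            for component in nx.connected_components(graph):
                if len(component) < min_size:
                    continue
                members = sorted((lookup[gid] for gid in component), key=lambda g: g.rank)
                clusters.append(
                    TandemCluster(
                        chromosome=chromosome,
                        member_ids=[g.gene_id for g in members],
                        name=name,
                        span_bp=max(g.end for g in members) - min(g.start for g in members),
                        n_genes=len(members),
                    )
                )
    clusters.sort(key=lambda c: (c.chromosome, c.member_ids[0]))
    return clusters


def confirm_against_reference(
    clusters: Iterable[TandemCluster],
    member_proteins: Mapping[str, str],
    reference_proteins: Mapping[str, str],
) -> List[TandemCluster]:
    """Assign each cluster member its best-scoring reference protein.

    A cluster is flagged confirmed when a strict majority of members share
    one best reference (tandem copies typically match the same reference
    protein); members with no positive-scoring hit stay unassigned.
    """
    if not reference_proteins:
        raise ValueError("reference protein set is empty")
    out: List[TandemCluster] = []
    for cluster in clusters:
        best_ref: Dict[str, Optional[str]] = {}
        for gid in cluster.member_ids:
            protein = member_proteins.get(gid, "")
            if not protein:
                best_ref[gid] = None
                continue
            scored = [
                (protein_local_score(protein, ref_seq), ref_id)
                for ref_id, ref_seq in reference_proteins.items()
            ]
            score, ref_id = max(scored, key=lambda t: (t[0], t[1]))
            # deterministic tie-break: highest score, then lexicographically last id
            best_score = max(s for s, _ in scored)
            candidates = sorted(r for s, r in scored if s == best_score)
            best_ref[gid] = candidates[0] if best_score > 0 else None
        assigned = [r for r in best_ref.values() if r is not None]
        confirmed = False
        if assigned:
            top = max(set(assigned), key=lambda r: (assigned.count(r), r))
            confirmed = assigned.count(top) * 2 > len(cluster.member_ids)
        out.append(
            TandemCluster(
                chromosome=cluster.chromosome,
                member_ids=list(cluster.member_ids),
                name=cluster.name,
                span_bp=cluster.span_bp,
                n_genes=cluster.n_genes,
                confirmed=confirmed,
                best_reference=best_ref,
            )
        )
    return out
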