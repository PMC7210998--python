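"""Paralogons: collinear blocks of paralogous genes and their summaries.

Anchor pairs are the unordered pairs of tandem-collapsed family
representatives; collinear blocks are strictly monotone chains of anchors
(same or inverted orientation) with bounded rank gaps on both chromosomes,
extracted greedily by decreasing chain length.  This is a deliberately
simple rank-space chaining model of synteny: each anchor belongs to at
most one block, and per-chromosome anchor totals plus the shared-anchor
matrix summarise the duplication footprint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .model import GeneModel
from .paralog_families import ParalogFamily, collapse_tandem_members


@dataclass(frozen=True)
class AnchorPair:
    """Two same-family genes at distinct positions, stored in canonical order."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int

    def __post_init__(self) -> None:
        if (self.chrom_a, self.rank_a) >= (self.chrom_b, self.rank_b):
            raise ValueError("anchor sides must be in canonical (chrom, rank) order")


@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: Tuple[AnchorPair, ...]
    orientation: str  # "same" | "inverted"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def build_anchor_pairs(
    families: Iterable[ParalogFamily],
    genes: Sequence[GeneModel],
    max_intervening: int = 5,
) -> List[AnchorPair]:
    """All unordered representative pairs after tandem collapsing.

    Tandem runs within a family are first collapsed to single
    representatives, so adjacent duplicate copies contribute no anchors;
    intra-chromosomal pairs are kept.
    """
    lookup = {g.gene_id: g for g in genes}
    anchors: List[AnchorPair] = []
    for family in families:
        collapsed = collapse_tandem_members(family, genes, max_intervening)
        reps = sorted(r for r in collapsed.representatives if r in lookup)
        for ga, gb in itertools.combinations(reps, 2):
            a, b = lookup[ga], lookup[gb]
            if (a.chromosome, a.rank) > (b.chromosome, b.rank):
                a, b = b, a
            anchors.append(
                AnchorPair(
                    gene_a=a.gene_id, gene_b=b.gene_id,
                    chrom_a=a.chromosome, chrom_b=b.chromosome,
                    rank_a=a.rank, rank_b=b.rank,
                )
            )
    return anchors


def _longest_chain(
    anchors: List[AnchorPair], max_gap: int, inverted: bool
) -> List[int]:
    """Longest strictly monotone chain (indices into *anchors*) with bounded
    per-step rank gaps on both sides; O(n^2) DP, deterministic."""
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].rank_a, anchors[i].rank_b if not inverted else -anchors[i].rank_b),
    )
    best_len = [1] * len(order)
    parent = [-1] * len(order)
    for oi, i in enumerate(order):
        for oj in range(oi):
            j = order[oj]
            da = anchors[i].rank_a - anchors[j].rank_a
            db = anchors[i].rank_b - anchors[j].rank_b
            if inverted:
                db = -db
            if 0 < da <= max_gap and 0 < db <= max_gap:
                if best_len[oj] + 1 > best_len[oi]:
                    best_len[oi] = best_len[oj] + 1
                    parent[oi] = oj
    if not order:
        return []
    end = max(range(len(order)), key=lambda oi: (best_len[oi], -oi))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = parent[end]
    return chain[::-1]


def chain_collinear_blocks(
    anchors: Sequence[AnchorPair],
    max_gap_genes: int = 25,
    min_anchors: int = 3,
) -> List[CollinearBlock]:
    """Greedy extraction of collinear blocks from an anchor set.

    Per chromosome pair, the longest strictly monotone chain (either
    orientation) is repeatedly removed until none reaches ``min_anchors``.
    Intra-chromosomal anchors additionally require the two sides to be at
    least ``max_gap_genes`` ranks apart, preventing self-trivial blocks.
    """
    by_pair: Dict[Tuple[str, str], List[AnchorPair]] = {}
    for anchor in anchors:
        if anchor.chrom_a == anchor.chrom_b and anchor.rank_b - anchor.rank_a < max_gap_genes:
            continue
        by_pair.setdefault((anchor.chrom_a, anchor.chrom_b), []).append(anchor)

    blocks: List[CollinearBlock] = []
    for (ca, cb), pool in sorted(by_pair.items()):
        pool = list(pool)
        while True:
            candidates = []
            for inverted in (False, True):
                idx = _longest_chain(pool, max_gap_genes, inverted)
                candidates.append((len(idx), not inverted, idx, inverted))
            candidates.sort(reverse=True)  # longest first; 'same' wins ties
            length, _, idx, inverted = candidates[0]
            if length < min_anchors:
                break
            chosen = [pool[i] for i in idx]
            blocks.append(
                CollinearBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=tuple(sorted(chosen, key=lambda a: a.rank_a)),
                    orientation="inverted" if inverted else "same",
                )
            )
            used = set(idx)
            pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


def paralogon_summary(
    blocks: Iterable[CollinearBlock],
    chromosomes: Sequence[str] = (),
) -> Tuple[Dict[str, int], pd.DataFrame]:
    """Per-chromosome anchor totals and the symmetric shared-anchor matrix.

    A block between two chromosomes contributes its anchor count to both
    totals and to the off-diagonal matrix cell; intra-chromosomal blocks
    count once on the diagonal and once in the total.
    """
    chroms = set(chromosomes)
    block_list = list(blocks)
    for b in block_list:
        chroms.update((b.chrom_a, b.chrom_b))
    names = sorted(chroms)
    matrix = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for b in block_list:
        matrix.loc[b.chrom_a, b.chrom_b] += b.n_anchors
        if b.chrom_a != b.chrom_b:
            matrix.loc[b.chrom_b, b.chrom_a] += b.n_anchors
    totals = {
        c: int(matrix.loc[c].sum()) for c in names
    }
    return totals, matrix


def write_link_file(blocks: Iterable[CollinearBlock], genes: Sequence[GeneModel], path) -> None:
    """Circos-compatible link file: one line per block with bp spans."""
    lookup = {g.gene_id: g for g in genes}
    with open(path, "w") as fh:
        for b in blocks:
            first, last = b.anchors[0], b.anchors[-1]
            sa = lookup[first.gene_a].start
            ea = lookup[last.gene_a].end
            ranks_b = [a.rank_b for a in b.anchors]
            genes_b = [lookup[a.gene_b] for a in b.anchors]
            sb = min(g.start for g in genes_b)
            eb = max(g.end for g in genes_b)
            fh.write(f"{b.chrom_a} {sa} {ea} {b.chrom_b} {sb} {eb} anchors={b.n_anchors}\n")
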