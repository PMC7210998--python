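import itertools

import pytest

from wgdkit.model import GeneModel, assign_ranks
from wgdkit.paralog_families import ParalogFamily
from wgdkit.synteny_paralogons import (
    AnchorPair,
    build_anchor_pairs,
    chain_collinear_blocks,
    paralogon_summary,
)
from wgdkit.synthetic_data import WGDSimConfig, simulate_wgd_genome
from tests.conftest import make_genes


def anchor(ra, rb, ca="chr1", cb="chr2", tag=""):
    return AnchorPair(
        gene_a=f"a{tag}{ra}", gene_b=f"b{tag}{rb}", chrom_a=ca, chrom_b=cb,
        rank_a=ra, rank_b=rb,
    )


# ------------------------------------------------------------------ anchors


def test_cross_chromosome_family_yields_one_anchor():
    genes = make_genes(
        {"chr1": [("a", "x")], "chr2": [("b", "x")]},
        proteins={"a": "MKV", "b": "MKV"},
    )
    anchors = build_anchor_pairs([ParalogFamily("F0", {"a", "b"})], genes)
    assert len(anchors) == 1
    assert {anchors[0].chrom_a, anchors[0].chrom_b} == {"chr1", "chr2"}


def test_family_of_three_on_three_chromosomes_gives_three_anchors():
    genes = make_genes(
        {c: [(f"g{c}", "x")] for c in ("chr1", "chr2", "chr3")},
        proteins={f"g{c}": "MKV" for c in ("chr1", "chr2", "chr3")},
    )
    anchors = build_anchor_pairs(
        [ParalogFamily("F0", {"gchr1", "gchr2", "gchr3"})], genes
    )
    assert len(anchors) == 3


def test_adjacent_tandem_pair_collapses_to_zero_anchors():
    genes = make_genes(
        {"chr1": [("t1", "x"), ("t2", "x")]}, proteins={"t1": "MKVA", "t2": "MKV"}
    )
    anchors = build_anchor_pairs([ParalogFamily("F0", {"t1", "t2"})], genes)
    assert anchors == []


# ------------------------------------------------------------------- chains


def test_collinear_run_forms_one_block():
    anchors = [anchor(i, i) for i in range(5)]
    blocks = chain_collinear_blocks(anchors)
    assert len(blocks) == 1
    assert blocks[0].n_anchors == 5 and blocks[0].orientation == "same"


def test_reversed_run_is_inverted():
    anchors = [anchor(i, 4 - i) for i in range(5)]
    blocks = chain_collinear_blocks(anchors)
    assert len(blocks) == 1 and blocks[0].orientation == "inverted"


def test_large_gaps_prevent_chaining():
    anchors = [anchor(40 * i, 40 * i) for i in range(5)]
    assert chain_collinear_blocks(anchors, max_gap_genes=25) == []


def test_anchors_used_at_most_once_and_greedy_by_length():
    long_chain = [anchor(i, i) for i in range(6)]
    short_chain = [anchor(i + 100, i + 200) for i in range(3)]
    blocks = chain_collinear_blocks(long_chain + short_chain)
    assert sorted(b.n_anchors for b in blocks) == [3, 6]
    used = [a for b in blocks for a in b.anchors]
    assert len(used) == len(set(used))


def test_greedy_matches_exhaustive_search_on_disjoint_chains():
    """On anchor sets made of disjoint monotone chains, greedy extraction is
    provably optimal; compare the chained anchor count with brute force."""
    chains = [[(i, i) for i in range(4)],
              [(i + 50, 60 - i) for i in range(5)],
              [(i + 200, i + 300) for i in range(3)]]
    anchors = [anchor(ra, rb, tag=f"c{ci}") for ci, chain in enumerate(chains)
               for ra, rb in chain]

    def feasible(chain_subset):
        chain_subset = sorted(chain_subset, key=lambda a: a.rank_a)
        for direction in (1, -1):
            ok = True
            for u, v in zip(chain_subset, chain_subset[1:]):
                da = v.rank_a - u.rank_a
                db = (v.rank_b - u.rank_b) * direction
                if not (0 < da <= 25 and 0 < db <= 25):
                    ok = False
                    break
            if ok:
                return True
        return False

    best_cover = 0
    # exhaustive: pick up to 3 disjoint feasible chains of size >= 3
    feas = [s for r in range(3, len(anchors) + 1)
            for s in itertools.combinations(anchors, r) if feasible(s)]
    for combo_size in range(1, 4):
        for combo in itertools.combinations(feas, combo_size):
            used = list(itertools.chain.from_iterable(combo))
            if len(used) == len(set(used)):
                best_cover = max(best_cover, len(used))
    blocks = chain_collinear_blocks(anchors)
    assert sum(b.n_anchors for b in blocks) == best_cover


def test_intrachromosomal_blocks_require_rank_separation():
    near = [AnchorPair(f"p{i}", f"q{i}", "chr1", "chr1", i, i + 3) for i in range(4)]
    far = [AnchorPair(f"u{i}", f"v{i}", "chr1", "chr1", i, i + 100) for i in range(4)]
    assert chain_collinear_blocks(near) == []
    blocks = chain_collinear_blocks(far)
    assert len(blocks) == 1 and blocks[0].chrom_a == blocks[0].chrom_b == "chr1"


# ------------------------------------------------------------------ summary


def test_summary_totals_and_matrix():
    b1 = chain_collinear_blocks([anchor(i, i) for i in range(5)])[0]
    b2 = chain_collinear_blocks([anchor(i, i, ca="chr1", cb="chr3") for i in range(4)])[0]
    totals, matrix = paralogon_summary([b1, b2])
    assert totals == {"chr1": 9, "chr2": 5, "chr3": 4}
    assert matrix.loc["chr1", "chr2"] == 5 and matrix.loc["chr2", "chr1"] == 5
    assert matrix.loc["chr1", "chr3"] == 4
    empty_totals, empty_matrix = paralogon_summary([], chromosomes=["chr1", "chr2"])
    assert empty_totals == {"chr1": 0, "chr2": 0}
    assert int(empty_matrix.values.sum()) == 0


def test_reversing_gene_order_flips_orientation_only():
    anchors = [anchor(i, i) for i in range(5)]
    flipped = [anchor(i, 100 - i) for i in range(5)]
    b = chain_collinear_blocks(anchors)[0]
    fb = chain_collinear_blocks(flipped)[0]
    assert b.orientation == "same" and fb.orientation == "inverted"
    assert b.n_anchors == fb.n_anchors


# ------------------------------------------------- simulated single WGD


def test_single_wgd_full_retention_pairs_each_chromosome_with_its_copy():
    genome = simulate_wgd_genome(
        WGDSimConfig(n_ancestral_genes=40, n_chromosomes=2, wgd_depths=(0.4,),
                     retention_prob=1.0, cds_length_codons=90, seed=21)
    )
    families = [
        ParalogFamily(fid, set(members))
        for fid, members in genome.truth_families.items()
        if len(members) > 1
    ]
    anchors = build_anchor_pairs(families, genome.genes)
    blocks = chain_collinear_blocks(anchors)
    pairs = {(b.chrom_a, b.chrom_b) for b in blocks}
    # each pre-duplication chromosome pairs exactly with its duplicate copy
    assert pairs == {("chr1_0", "chr1_1"), ("chr2_0", "chr2_1")}
    by_pair = {}
    for b in blocks:
        by_pair[(b.chrom_a, b.chrom_b)] = by_pair.get((b.chrom_a, b.chrom_b), 0) + b.n_anchors
    counts = {"chr1": 0, "chr2": 0}
    for members in genome.truth_families.values():
        if len(members) == 2:
            gene = next(g for g in genome.genes if g.gene_id == members[0])
            counts[gene.chromosome.split("_")[0]] += 1
    assert by_pair[("chr1_0", "chr1_1")] == counts["chr1"]
    assert by_pair[("chr2_0", "chr2_1")] == counts["chr2"]
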