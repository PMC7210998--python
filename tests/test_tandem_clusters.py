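import itertools

import numpy as np
import pytest

from wgdkit._align import protein_alignment_identity
from wgdkit.synthetic_data import WGDSimConfig, simulate_wgd_genome
from wgdkit.tandem_clusters import confirm_against_reference, find_tandem_clusters
from tests.conftest import make_genes

AAS = "ACDEFGHIKLMNPQRSTVWY"


# ------------------------------------------------------- independent oracle


def tandem_oracle(genes, max_intervening=5, min_identity=0.70, min_size=3):
    """Brute-force restatement of the tandem rule.

    Two same-name genes are chain-mates iff every adjacent gap in the full
    sorted occurrence list between them holds at most ``max_intervening``
    differently-named genes; within a chain, the >=70%-identity relation is
    closed transitively (Floyd-Warshall style) and each closure class of
    at least ``min_size`` genes is a cluster.
    """
    clusters = []
    by_key = {}
    for g in genes:
        by_key.setdefault((g.chromosome, g.name), []).append(g)
    for (chrom, name), occ in by_key.items():
        occ = sorted(occ, key=lambda g: g.start)
        n = len(occ)
        # chain-mate matrix from adjacent gaps
        adjacent_ok = [
            occ[i + 1].rank - occ[i].rank - 1 <= max_intervening for i in range(n - 1)
        ]
        same_chain = [[False] * n for _ in range(n)]
        for i in range(n):
            same_chain[i][i] = True
            for j in range(i + 1, n):
                same_chain[i][j] = same_chain[j][i] = all(adjacent_ok[i:j])
        # identity relation, transitively closed within chains
        related = [[False] * n for _ in range(n)]
        for i, j in itertools.combinations(range(n), 2):
            if not same_chain[i][j]:
                continue
            if not occ[i].protein or not occ[j].protein:
                continue
            if protein_alignment_identity(occ[i].protein, occ[j].protein) >= min_identity:
                related[i][j] = related[j][i] = True
        for i in range(n):
            related[i][i] = True
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    if related[i][k] and related[k][j] and same_chain[i][j]:
                        related[i][j] = True
        seen = set()
        for i in range(n):
            if i in seen:
                continue
            group = {j for j in range(n) if related[i][j]}
            seen |= group
            if len(group) >= min_size:
                clusters.append(
                    (chrom, name, tuple(sorted(occ[j].gene_id for j in group)))
                )
    return sorted(clusters)


def as_tuples(clusters):
    return sorted((c.chromosome, c.name, tuple(sorted(c.member_ids))) for c in clusters)


# ------------------------------------------------------------ worked orders


def spaced_layout(order, protein_by_name):
    entries = []
    for i, name in enumerate(order):
        gid = f"{name}{i}" if name != "x" else f"x{i}"
        entries.append((gid, name if name != "x" else f"filler{i}"))
    proteins = {}
    for gid, name in entries:
        if not name.startswith("filler"):
            proteins[gid] = protein_by_name[name]
    return make_genes({"chr1": entries}, proteins=proteins)


def test_three_copies_with_small_gaps_form_one_cluster():
    genes = spaced_layout(list("AxAxxxxxA"), {"A": "MKVLAHGG"})
    clusters = find_tandem_clusters(genes)
    assert len(clusters) == 1
    assert clusters[0].n_genes == 3
    assert clusters[0].name == "A"


def test_six_intervening_genes_break_the_chain():
    genes = spaced_layout(list("AxxxxxxAA"), {"A": "MKVLAHGG"})
    assert find_tandem_clusters(genes) == []


def test_low_identity_copy_is_dropped_and_cluster_dissolves():
    # three chained copies; the middle one diverged below 70% identity
    base = "MKVLAHGGPQRSTVVA"
    far = "MWYCDEFGHIKLNPQD"
    genes = make_genes(
        {"chr1": [("a1", "A"), ("a2", "A"), ("a3", "A")]},
        proteins={"a1": base, "a2": far, "a3": base[:-2] + "GG"},
    )
    assert protein_alignment_identity(base, far) < 0.70
    assert find_tandem_clusters(genes) == []


def test_span_and_member_order():
    genes = spaced_layout(list("AAA"), {"A": "MKVLAHGG"})
    cluster = find_tandem_clusters(genes)[0]
    assert cluster.member_ids == ["A0", "A1", "A2"]
    assert cluster.span_bp == genes[-1].end - genes[0].start


# ----------------------------------------------------------- random oracle


def random_annotation(rng, n_genes=40):
    names = [f"name{c}" for c in "ABC"] + [None]
    templates = {f"name{c}": "".join(AAS[i] for i in rng.integers(0, 20, 30)) for c in "ABC"}
    layout = []
    proteins = {}
    for i in range(n_genes):
        name = names[rng.integers(0, len(names))]
        gid = f"g{i:02d}"
        if name is None:
            layout.append((gid, f"unique{i}"))
        else:
            layout.append((gid, name))
            rate = float(rng.choice([0.0, 0.1, 0.25, 0.5]))
            prot = list(templates[name])
            for pos in np.flatnonzero(rng.random(len(prot)) < rate):
                prot[pos] = AAS[rng.integers(0, 20)]
            proteins[gid] = "".join(prot)
    chrom = "chr1" if rng.random() < 0.7 else "chr2"
    return make_genes({chrom: layout}, proteins=proteins)


def test_matches_brute_force_oracle_on_random_annotations():
    rng = np.random.default_rng(42)
    for _ in range(30):
        genes = random_annotation(rng)
        assert as_tuples(find_tandem_clusters(genes)) == tandem_oracle(genes)


def test_parameter_monotonicity():
    rng = np.random.default_rng(7)
    genes = random_annotation(rng, n_genes=30)
    loose = find_tandem_clusters(genes, max_intervening=8, min_identity=0.5)
    tight = find_tandem_clusters(genes, max_intervening=2, min_identity=0.5)
    sizes = lambda cs: {c.name: c.n_genes for c in cs}
    for name, size in sizes(tight).items():
        assert size <= sizes(loose).get(name, 0) or name not in sizes(loose)
    low_id = find_tandem_clusters(genes, max_intervening=5, min_identity=0.4)
    high_id = find_tandem_clusters(genes, max_intervening=5, min_identity=0.9)
    assert sum(c.n_genes for c in high_id) <= sum(c.n_genes for c in low_id)


# ------------------------------------------------- simulated genome arrays


def test_recovers_injected_tandem_arrays():
    genome = simulate_wgd_genome(
        WGDSimConfig(
            n_ancestral_genes=30, n_chromosomes=2, wgd_depths=(0.8,),
            retention_prob=0.5, cds_length_codons=90,
            tandem_arrays=((4, 0.9), (3, 0.85)), intergenic_genes=10, seed=13,
        )
    )
    clusters = find_tandem_clusters(genome.genes)
    found = sorted(tuple(sorted(c.member_ids)) for c in clusters)
    truth = sorted(tuple(sorted(ids)) for ids in genome.truth_tandem_clusters)
    assert found == truth


# ----------------------------------------------------------- confirmation


def test_confirmation_against_reference_proteins():
    prot = "MKVLAHGGPQRSTVVA"
    genes = make_genes(
        {"chr1": [("a1", "A"), ("a2", "A"), ("a3", "A")]},
        proteins={g: prot for g in ("a1", "a2", "a3")},
    )
    clusters = find_tandem_clusters(genes)
    member_proteins = {g.gene_id: g.protein for g in genes}
    confirmed = confirm_against_reference(
        clusters, member_proteins, {"ref1": prot, "ref2": "MWYCDEFGHIKLNPQD"}
    )
    assert confirmed[0].confirmed is True
    assert set(confirmed[0].best_reference.values()) == {"ref1"}
    with pytest.raises(ValueError):
        confirm_against_reference(clusters, member_proteins, {})


def test_split_best_hits_are_not_confirmed():
    pa, pb = "MKVLAHGGPQRSTVVA", "MKVLAHGGPQRSTWWC"
    genes = make_genes(
        {"chr1": [("a1", "A"), ("a2", "A"), ("a3", "A"), ("a4", "A")]},
        proteins={"a1": pa, "a2": pa, "a3": pb, "a4": pb},
    )
    clusters = find_tandem_clusters(genes, min_identity=0.6)
    confirmed = confirm_against_reference(
        clusters, {g.gene_id: g.protein for g in genes}, {"r1": pa, "r2": pb}
    )
    assert confirmed[0].confirmed is False
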