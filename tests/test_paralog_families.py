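import numpy as np
import pytest

from wgdkit.io_formats import read_similarity_tabular
from wgdkit.model import SimilarityEdge
from wgdkit.paralog_families import (
    ParalogFamily,
    all_vs_all_similarity,
    collapse_tandem_members,
    edge_weight,
    filter_family_sizes,
    mcl_cluster,
)
from tests.conftest import make_genes

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(n, rng):
    return "".join(AAS[i] for i in rng.integers(0, 20, size=n))


def unit_edge(a, b, evalue=1e-10):
    return SimilarityEdge(a, b, 100.0, 100, evalue, 100.0)


# ---------------------------------------------------------------- similarity


def test_identical_proteins_give_one_full_identity_edge(rng):
    p = random_protein(200, rng)
    edges = all_vs_all_similarity({"a": p, "b": p})
    assert len(edges) == 1
    assert edges[0].percent_identity == 100.0
    assert edges[0].evalue <= 1e-8


def test_random_proteins_never_reach_the_evalue_threshold(rng):
    hits = 0
    for _ in range(100):
        prots = {"a": random_protein(100, rng), "b": random_protein(100, rng)}
        hits += len(all_vs_all_similarity(prots))
    assert hits == 0


def test_precomputed_tabular_path_is_a_passthrough(tmp_path, rng):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "a\tb\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-30\t180\n"
        "b\ta\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-40\t190\n"
        "a\tc\t60.0\t80\t30\t2\t1\t80\t1\t80\t1e-3\t40\n"
    )
    prots = {x: random_protein(100, rng) for x in "abc"}
    edges = all_vs_all_similarity(prots, tabular_path=path)
    parsed = read_similarity_tabular(path, {k: 100 for k in prots}, {k: 100 for k in prots})
    # symmetric duplicates collapsed to the better E-value; weak hit dropped
    assert len(edges) == 1
    assert edges[0].evalue == 1e-40
    assert {(e.query_id, e.subject_id) for e in parsed} == {("a", "b"), ("b", "a"), ("a", "c")}


def test_similarity_requires_two_proteins(rng):
    with pytest.raises(ValueError):
        all_vs_all_similarity({"a": "MKV"})


# ----------------------------------------------------------------------- MCL


def test_disjoint_cliques_are_never_merged():
    edges = [unit_edge(a, b) for a, b in
             [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f")]]
    families = mcl_cluster(edges)
    assert sorted(sorted(f.members) for f in families) == [list("abc"), list("def")]


def test_isolated_node_becomes_singleton():
    families = mcl_cluster([unit_edge("a", "b")], nodes={"a", "b", "lonely"})
    assert sorted(sorted(f.members) for f in families) == [["a", "b"], ["lonely"]]


def mcl_fixed_point_oracle(nodes, weighted_edges, inflation=6.0):
    """Independent dense longdouble expansion/inflation iteration, no pruning."""
    names = sorted(nodes)
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    w = np.zeros((n, n), dtype=np.longdouble)
    for a, b, weight in weighted_edges:
        w[index[a], index[b]] = w[index[b], index[a]] = weight
    for i in range(n):
        incident = w[i].max()
        w[i, i] = incident if incident > 0 else 1.0
    m = w / w.sum(axis=0, keepdims=True)
    for _ in range(500):
        prev = m.copy()
        m = np.power(m @ m, inflation)
        m = m / m.sum(axis=0, keepdims=True)
        if np.abs(m - prev).max() < np.longdouble(1e-16):
            break
    reach = (m + m.T) > 1e-12
    labels = {}
    for i in range(n):
        for j in range(n):
            if reach[i, j]:
                root = min(labels.get(names[i], names[i]), labels.get(names[j], names[j]))
                labels[names[i]] = labels[names[j]] = root
    groups = {}
    for name in names:
        # resolve chains
        root = name
        while labels.get(root, root) != root:
            root = labels[root]
        groups.setdefault(root, set()).add(name)
    return sorted(sorted(g) for g in groups.values())


def test_weighted_path_matches_high_precision_oracle():
    edges = [unit_edge("a", "b", evalue=1e-1), unit_edge("b", "c", evalue=10 ** -0.01)]
    weights = [("a", "b", edge_weight(edges[0])), ("b", "c", edge_weight(edges[1]))]
    oracle = mcl_fixed_point_oracle({"a", "b", "c"}, weights)
    ours = sorted(sorted(f.members) for f in mcl_cluster(edges))
    assert ours == oracle


def test_clusters_equal_connected_components_on_random_clique_graphs(rng):
    for _ in range(10):
        n_cliques = int(rng.integers(2, 5))
        edges, expected, start = [], [], 0
        for _ in range(n_cliques):
            size = int(rng.integers(1, 5))
            members = [f"n{start + i:02d}" for i in range(size)]
            start += size
            expected.append(sorted(members))
            for i in range(size):
                for j in range(i + 1, size):
                    edges.append(unit_edge(members[i], members[j]))
        nodes = {m for group in expected for m in group}
        got = sorted(sorted(f.members) for f in mcl_cluster(edges, nodes=nodes))
        assert got == sorted(expected)


def test_mcl_output_partitions_nodes_and_is_label_equivariant():
    edges = [unit_edge("a", "b"), unit_edge("b", "c", 1e-2), unit_edge("d", "e")]
    families = mcl_cluster(edges, nodes=set("abcde"))
    members = sorted(m for f in families for m in f.members)
    assert members == list("abcde")
    relabel = {"a": "z9", "b": "z8", "c": "z7", "d": "z6", "e": "z5"}
    redges = [unit_edge(relabel[e.query_id], relabel[e.subject_id], e.evalue) for e in edges]
    refams = mcl_cluster(redges, nodes=set(relabel.values()))
    expected = sorted(sorted(relabel[m] for m in f.members) for f in families)
    assert sorted(sorted(f.members) for f in refams) == expected


# ------------------------------------------------------------------- filters


def test_family_size_filter_bounds():
    families = [
        ParalogFamily(f"F{i}", {f"g{i}_{j}" for j in range(size)})
        for i, size in enumerate([1, 2, 8, 9])
    ]
    assert sorted(f.size for f in filter_family_sizes(families)) == [2, 8]
    assert sorted(f.size for f in filter_family_sizes(families, min_size=1)) == [1, 2, 8]
    assert filter_family_sizes([]) == []


# ---------------------------------------------------------- tandem collapsing


def test_adjacent_members_collapse_to_longest_protein():
    genes = make_genes(
        {"chr1": [("t1", "x"), ("t2", "x"), ("far", "y")]},
        proteins={"t1": "MKVLA", "t2": "MKV", "far": "MM"},
    )
    family = ParalogFamily("F0", {"t1", "t2"})
    collapsed = collapse_tandem_members(family, genes)
    assert collapsed.representatives == {"t1"}
    assert collapsed.members == {"t1", "t2"}


def test_members_on_different_chromosomes_are_kept():
    genes = make_genes({"chr1": [("a", "x")], "chr2": [("b", "x")]},
                       proteins={"a": "MKV", "b": "MKV"})
    collapsed = collapse_tandem_members(ParalogFamily("F0", {"a", "b"}), genes)
    assert collapsed.representatives == {"a", "b"}


def test_chained_members_group_transitively():
    layout = {"chr1": [("a", "x"), ("s1", "d1"), ("s2", "d2"), ("b", "x"),
                       ("s3", "d3"), ("s4", "d4"), ("c", "x")]}
    genes = make_genes(layout, proteins={"a": "MKVA", "b": "MKV", "c": "MK"})
    collapsed = collapse_tandem_members(ParalogFamily("F0", {"a", "b", "c"}), genes)
    assert collapsed.representatives == {"a"}
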