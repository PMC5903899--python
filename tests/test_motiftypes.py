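import itertools

import networkx as nx
import pytest

from conftest import random_digraph
from motifclust.errors import PatternSetError
from motifclust.motifcore import FBL, FFL, find_instances
from motifclust.motiftypes import (
    canonical_certificate,
    classify_pair,
    enumerate_types,
    extract_motif_subnetwork,
    mcd,
    type_distribution,
)
from oracles import (
    brute_catalog,
    brute_classify,
    brute_mcd,
    brute_type_counts,
    brute_union_graph,
)


@pytest.fixture(scope="module")
def ffl_catalog():
    return enumerate_types([FFL])


# ---------------------------------------------------------------------------
# catalog


def test_ffl_catalog_has_twelve_types(ffl_catalog):
    assert len(ffl_catalog) == 12
    one_node = [e for e in ffl_catalog if e.n_shared == 1]
    two_node = [e for e in ffl_catalog if e.n_shared == 2]
    assert len(one_node) == 6 and len(two_node) == 6
    assert all(e.n_nodes == 5 and e.n_edges == 6 for e in one_node)
    assert all(e.n_nodes == 4 and e.n_edges == 5 for e in two_node)
    assert sorted(e.type_id for e in one_node) == list(range(1, 7))
    assert sorted(e.type_id for e in two_node) == list(range(7, 13))


def test_fbl_catalog_has_two_types():
    catalog = enumerate_types([FBL])
    assert len(catalog) == 2
    by_id = {e.type_id: e for e in catalog}
    assert by_id[1].n_shared == 1 and by_id[1].n_edges == 6
    assert by_id[2].n_shared == 2 and by_id[2].n_edges == 5


@pytest.mark.parametrize("pattern", [FFL, FBL], ids=["ffl", "fbl"])
def test_catalog_agrees_with_brute_force_identification(pattern):
    catalog = enumerate_types([pattern])
    oracle = brute_catalog(pattern)
    assert len(catalog) == len(oracle)
    # bijection: every oracle graph matches exactly one catalog entry
    for union in oracle:
        matches = [e.type_id for e in catalog if nx.is_isomorphic(union, e.graph)]
        assert len(matches) == 1


def test_catalog_entries_pairwise_nonisomorphic(ffl_catalog):
    for e1, e2 in itertools.combinations(ffl_catalog, 2):
        assert not nx.is_isomorphic(e1.graph, e2.graph)


def test_heterologous_catalog_matches_cross_pattern_oracle():
    """FFL+FBL cross-type entries equal the brute-force count of
    non-isomorphic FFL-union-FBL overlap graphs."""
    het = enumerate_types([FFL, FBL], mode="heterologous")
    # independent count: all identifications of an FFL copy with an FBL copy
    base1, base2 = FFL.graph(), FBL.graph()
    copy1 = nx.relabel_nodes(base1, {r: ("p", r) for r in FFL.roles})
    reps = []
    for s in (1, 2, 3):
        for own in itertools.combinations(FFL.roles, s):
            for other in itertools.permutations(FBL.roles, s):
                relabel = {r: ("q", r) for r in FBL.roles}
                for q_role, p_role in zip(other, own):
                    relabel[q_role] = ("p", p_role)
                copy2 = nx.relabel_nodes(base2, relabel)
                union = nx.compose(copy1, copy2)
                if set(union.subgraph(copy1.nodes).edges) != set(copy1.edges):
                    continue
                if set(union.subgraph(copy2.nodes).edges) != set(copy2.edges):
                    continue
                if not any(nx.is_isomorphic(union, rep) for rep in reps):
                    reps.append(union)
    assert len(het) == len(reps)
    mixed = [e for e in het if e.pattern_pair == ("ffl", "fbl")]
    assert len(mixed) == len(het)


def test_full_catalog_is_union_of_modes():
    full = enumerate_types([FFL, FBL])
    hom = enumerate_types([FFL, FBL], mode="homologous")
    het = enumerate_types([FFL, FBL], mode="heterologous")
    assert len(full) == len(hom) + len(het)


def test_canonical_certificate_invariant_under_relabeling():
    g = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c"), ("d", "a")])
    cert1 = canonical_certificate(list(g.nodes), g.edges)
    h = nx.relabel_nodes(g, {"a": "z", "b": "q", "c": "m", "d": "w"})
    cert2 = canonical_certificate(list(h.nodes), h.edges)
    assert cert1 == cert2


# ---------------------------------------------------------------------------
# published numbering anchors


def test_type6_is_shared_input(ffl_catalog, two_ffls_sharing_input):
    i1, i2 = find_instances(two_ffls_sharing_input, FFL)
    assert classify_pair(i1, i2, ffl_catalog) == 6


def test_type12_is_duplicated_output(ffl_catalog):
    g = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("b", "d")])
    i1, i2 = find_instances(g, FFL)
    assert classify_pair(i1, i2, ffl_catalog) == 12


def test_type10_is_duplicated_intermediate(ffl_catalog):
    g = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("d", "c")])
    i1, i2 = find_instances(g, FFL)
    assert classify_pair(i1, i2, ffl_catalog) == 10


def test_type7_is_duplicated_input(ffl_catalog):
    g = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c"), ("d", "b"), ("d", "c")])
    i1, i2 = find_instances(g, FFL)
    assert classify_pair(i1, i2, ffl_catalog) == 7


def test_type9_is_three_level_hierarchy_with_linked_intermediates(ffl_catalog):
    # d -> a -> b three-level chain, d->b shortcut, plus a->c, b->c
    g = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c"), ("d", "a"), ("d", "b")])
    i1, i2 = find_instances(g, FFL)
    assert classify_pair(i1, i2, ffl_catalog) == 9


def test_type4_is_shared_intermediate(ffl_catalog):
    g = nx.DiGraph(
        [("a", "h"), ("a", "c"), ("h", "c"), ("d", "h"), ("d", "e"), ("h", "e")]
    )
    i1, i2 = find_instances(g, FFL)
    assert classify_pair(i1, i2, ffl_catalog) == 4


def test_disjoint_pair_is_not_classified(ffl_catalog, two_disjoint_ffls):
    i1, i2 = find_instances(two_disjoint_ffls, FFL)
    assert classify_pair(i1, i2, ffl_catalog) is None


def test_classification_matches_union_graph_isomorphism(ffl_catalog):
    """Descriptor lookup and explicit union-graph isomorphism agree."""
    for seed in range(8):
        g = random_digraph(n=12, p=0.25, seed=200 + seed)
        instances = find_instances(g, FFL)
        for i1, i2 in itertools.combinations(instances, 2):
            if not i1.node_set & i2.node_set:
                continue
            union = nx.DiGraph(list(i1.edges | i2.edges))
            assert classify_pair(i1, i2, ffl_catalog) == brute_classify(
                union, ffl_catalog
            )


# ---------------------------------------------------------------------------
# distributions


def test_star_of_ffls_is_pure_type6(ffl_catalog):
    k = 4
    g = nx.DiGraph()
    for i in range(k):
        g.add_edges_from([("h", f"b{i}"), ("h", f"c{i}"), (f"b{i}", f"c{i}")])
    dist = type_distribution(g, [FFL], catalog=ffl_catalog)
    assert dist.n_pairs_clustered == k * (k - 1) // 2
    assert dist.fractions[6] == 1.0
    assert sum(dist.fractions.values()) == pytest.approx(1.0)


def test_single_ffl_empty_distribution(single_ffl, ffl_catalog):
    dist = type_distribution(single_ffl, [FFL], catalog=ffl_catalog)
    assert dist.n_pairs_clustered == 0
    assert all(v == 0 for v in dist.counts.values())


def test_output_duplicated_pair_is_pure_type12(ffl_catalog):
    g = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"), ("b", "d")])
    dist = type_distribution(g, [FFL], catalog=ffl_catalog)
    assert dist.fractions[12] == 1.0 and dist.n_pairs_clustered == 1


@pytest.mark.parametrize("seed", range(8))
def test_distribution_matches_brute_force(seed, ffl_catalog):
    g = random_digraph(n=13, p=0.22, seed=300 + seed)
    dist = type_distribution(g, [FFL], catalog=ffl_catalog)
    oracle = brute_type_counts(g, FFL, ffl_catalog)
    assert {k: v for k, v in dist.counts.items() if v} == dict(oracle)


def test_counts_invariant_under_relabeling(ffl_catalog):
    g = random_digraph(n=12, p=0.3, seed=77)
    h = nx.relabel_nodes(g, {v: f"zz_{v}" for v in g.nodes})
    d1 = type_distribution(g, [FFL], catalog=ffl_catalog)
    d2 = type_distribution(h, [FFL], catalog=ffl_catalog)
    assert d1.counts == d2.counts


# ---------------------------------------------------------------------------
# MCD


def test_node_in_no_motif_has_mcd_zero(ffl_catalog):
    g = nx.DiGraph([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])
    assert mcd(g, [FFL], catalog=ffl_catalog)["d"] == 0


def test_hub_of_type6_star_has_mcd_one(ffl_catalog):
    g = nx.DiGraph()
    for i in range(4):
        g.add_edges_from([("h", f"b{i}"), ("h", f"c{i}"), (f"b{i}", f"c{i}")])
    table = mcd(g, [FFL], catalog=ffl_catalog)
    assert table["h"] == 1  # many pairs, all the same type
    assert table["b0"] == 0  # in a single motif only


def test_node_in_pairs_of_three_distinct_types(ffl_catalog):
    """Input a participates in three motifs whose pairs realize three
    distinct clustering types (12, 10 and 6); verified by brute force."""
    g = nx.DiGraph(
        [
            ("a", "b"), ("a", "c"), ("b", "c"),   # M1
            ("a", "d"), ("b", "d"),               # M2 shares a,b -> type 12
            ("a", "e"), ("e", "c"),               # M3 shares a,c -> type 10
        ]
    )
    table = mcd(g, [FFL], catalog=ffl_catalog)
    oracle = brute_mcd(g, FFL, ffl_catalog)
    assert table == oracle
    assert table["a"] == 3


@pytest.mark.parametrize("seed", range(6))
def test_mcd_matches_brute_force(seed, ffl_catalog):
    g = random_digraph(n=12, p=0.25, seed=400 + seed)
    assert mcd(g, [FFL], catalog=ffl_catalog) == brute_mcd(g, FFL, ffl_catalog)


def test_mcd_bounded_by_catalog_size(ffl_catalog):
    g = random_digraph(n=16, p=0.35, seed=5)
    table = mcd(g, [FFL], catalog=ffl_catalog)
    assert all(0 <= v <= 12 for v in table.values())


# ---------------------------------------------------------------------------
# extraction


def test_extract_no_motifs():
    g = nx.DiGraph([("a", "b"), ("b", "c")])
    sub, cov = extract_motif_subnetwork(g, [FFL])
    assert sub.number_of_nodes() == 0 and cov.node_fraction == 0.0


def test_extract_whole_network_is_one_ffl(single_ffl):
    sub, cov = extract_motif_subnetwork(single_ffl, [FFL])
    assert cov.node_fraction == 1.0 and cov.edge_fraction == 1.0


def test_extract_dangling_edge_excluded(single_ffl):
    single_ffl.add_edge("c", "d")
    sub, cov = extract_motif_subnetwork(single_ffl, [FFL])
    assert cov.n_nodes == 3 and cov.n_edges == 3
    assert cov.node_fraction == 0.75 and cov.edge_fraction == 0.75


def test_validation_error_for_bad_pattern_set():
    g = nx.DiGraph([("a", "b")])
    chain = __import__("motifclust.motifcore", fromlist=["MotifPattern"]).MotifPattern(
        "chain2", ("x", "y"), frozenset({("x", "y")})
    )
    with pytest.raises(PatternSetError):
        type_distribution(g, [chain, FFL])
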