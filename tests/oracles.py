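"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive: exhaustive iteration over node
tuples, direct evaluation of the pairwise sums, and isomorphism checks via
``networkx.is_isomorphic`` on explicitly constructed union graphs.  None
of it shares code with the package's census, descriptor-lookup
classification, or permutation-canonicalization machinery.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx


def brute_instances(graph: nx.DiGraph, pattern) -> dict[frozenset, dict]:
    """All induced occurrences by exhaustive iteration over node tuples.

    Returns {node_set: {role: node}} with one (arbitrary but fixed)
    automorphism representative per node set.
    """
    roles = pattern.roles
    pattern_edges = set(pattern.edges)
    found: dict[frozenset, dict] = {}
    nodes = list(graph.nodes)
    for combo in itertools.combinations(nodes, len(roles)):
        induced = {
            (u, v)
            for u, v in itertools.permutations(combo, 2)
            if graph.has_edge(u, v)
        }
        for perm in itertools.permutations(combo):
            mapping = dict(zip(roles, perm))
            mapped = {(mapping[u], mapping[v]) for u, v in pattern_edges}
            if mapped == induced:
                found.setdefault(frozenset(combo), mapping)
                break
    return found


def brute_s_t(node_sets: list[frozenset]) -> tuple[int, int]:
    """Direct double-loop evaluation of the shared-node sums S and T."""
    s = t = 0
    for i in range(len(node_sets)):
        for j in range(i + 1, len(node_sets)):
            s += len(node_sets[i] & node_sets[j])
            t += min(len(node_sets[i]), len(node_sets[j])) - 1
    return s, t


def brute_union_graph(map1: dict, map2: dict, pattern) -> nx.DiGraph:
    g = nx.DiGraph()
    for mapping in (map1, map2):
        g.add_nodes_from(mapping.values())
        g.add_edges_from((mapping[u], mapping[v]) for u, v in pattern.edges)
    return g


def brute_catalog(pattern) -> list[nx.DiGraph]:
    """Independent enumeration of all two-copy overlap graphs.

    Builds the union of two relabeled pattern copies for every injective
    partial node identification, keeps those where both copies stay
    induced, and deduplicates with ``nx.is_isomorphic``.
    """
    base = pattern.graph()
    copy1 = nx.relabel_nodes(base, {r: ("p", r) for r in pattern.roles})
    reps: list[nx.DiGraph] = []
    k = pattern.n_nodes
    for n_shared in range(1, k):
        for own in itertools.combinations(pattern.roles, n_shared):
            for other in itertools.permutations(pattern.roles, n_shared):
                relabel = {r: ("q", r) for r in pattern.roles}
                for q_role, p_role in zip(other, own):
                    relabel[q_role] = ("p", p_role)
                copy2 = nx.relabel_nodes(base, relabel)
                union = nx.compose(copy1, copy2)
                ok = True
                for copy in (copy1, copy2):
                    if set(union.subgraph(copy.nodes).edges) != set(copy.edges):
                        ok = False
                        break
                if not ok:
                    continue
                if not any(nx.is_isomorphic(union, rep) for rep in reps):
                    reps.append(union)
    return reps


def brute_classify(union: nx.DiGraph, catalog) -> int | None:
    """Type id by direct isomorphism against every catalog union graph."""
    matches = [
        e.type_id for e in catalog if nx.is_isomorphic(union, e.graph)
    ]
    assert len(matches) <= 1, f"catalog not isomorphism-disjoint: {matches}"
    return matches[0] if matches else None


def brute_type_counts(graph: nx.DiGraph, pattern, catalog) -> Counter:
    """Counts per type over all clustered instance pairs."""
    instances = list(brute_instances(graph, pattern).items())
    counts: Counter = Counter()
    for (set1, map1), (set2, map2) in itertools.combinations(instances, 2):
        if not set1 & set2:
            continue
        tid = brute_classify(brute_union_graph(map1, map2, pattern), catalog)
        assert tid is not None
        counts[tid] += 1
    return counts


def brute_mcd(graph: nx.DiGraph, pattern, catalog) -> dict[str, int]:
    """Per-node count of distinct types among pairs of motifs containing
    the node (both motifs of a pair contain it)."""
    instances = list(brute_instances(graph, pattern).items())
    table: dict[str, int] = {}
    for node in graph.nodes:
        members = [(s, m) for s, m in instances if node in s]
        types = set()
        for (s1, m1), (s2, m2) in itertools.combinations(members, 2):
            tid = brute_classify(brute_union_graph(m1, m2, pattern), catalog)
            if tid is not None:
                types.add(tid)
        table[str(node)] = len(types)
    return table
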