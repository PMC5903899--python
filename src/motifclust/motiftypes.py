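"""Pairwise motif clustering types, type distributions, and MCD.

Two overlapping motif instances define a *clustering type*: the
isomorphism class of the union graph built from the two instances' own
edges on the union of their node sets.  The catalog of all possible types
is generated by enumerating every identification of one or more nodes
between two pattern copies such that each copy remains an **induced**
occurrence in the union (this forbids, e.g., antiparallel identification
of a shared edge), deduplicated by exhaustive canonical labeling of the
small (<= 2 * pattern size) union graphs.

For the feed-forward loop this yields exactly 12 types: six sharing one
node (6-edge unions) and six sharing two nodes (5-edge unions).  The
numbering follows the published taxonomy anchors:

====  ==========================================================
type  identification (A = input, B = intermediate, C = output)
====  ==========================================================
1     one node, output of both
2     one node, intermediate of one / output of the other
3     one node, input of one / output of the other
4     one node, intermediate of both
5     one node, input of one / intermediate of the other
6     one node, input of both
7     edge B->C of both (duplicated input)
8     edge A->B of one with A->C of the other
9     edge A->B of one with B->C of the other (3-level hierarchy)
10    edge A->C of both (duplicated intermediate)
11    edge A->C of one with B->C of the other
12    edge A->B of both (duplicated output)
====  ==========================================================

Any pattern structurally isomorphic to the FFL receives this numbering;
other catalogs (e.g. the two feedback-loop types) are ordered by shared
node count, then by canonical certificate.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from motifclust.errors import ClassificationError, ValidationError
from motifclust.motifcore import (
    MotifInstance,
    MotifPattern,
    find_instances,
    validate_pattern_set,
)

Descriptor = tuple[tuple[int, int], ...]

# Canonical FFL type numbering keyed by the node-identification descriptor
# in *structural* role indices (0 = input, 1 = intermediate, 2 = output),
# canonicalized under swapping the two copies.
_FFL_TYPE_IDS: dict[Descriptor, int] = {
    ((2, 2),): 1,
    ((1, 2),): 2,
    ((0, 2),): 3,
    ((1, 1),): 4,
    ((0, 1),): 5,
    ((0, 0),): 6,
    ((1, 1), (2, 2)): 7,
    ((0, 0), (1, 2)): 8,
    ((0, 1), (1, 2)): 9,
    ((0, 0), (2, 2)): 10,
    ((0, 1), (2, 2)): 11,
    ((0, 0), (1, 1)): 12,
}


def canonical_certificate(
    nodes: Sequence[object], edges: Iterable[tuple[object, object]]
) -> tuple:
    """Canonical form of a small digraph by exhaustive relabeling.

    Minimum, over all node permutations, of the sorted integer edge list.
    Exponential in node count, intended for union graphs of two motif
    copies (<= 6 nodes for 3-node motifs).
    """
    nodes = list(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edge_idx = [(index[u], index[v]) for u, v in edges]
    n = len(nodes)
    best = None
    for perm in itertools.permutations(range(n)):
        candidate = tuple(sorted((perm[u], perm[v]) for u, v in edge_idx))
        if best is None or candidate < best:
            best = candidate
    return (n, best if best is not None else ())


def _structural_ffl_roles(pattern: MotifPattern) -> dict[str, int] | None:
    """Map role -> structural index (0 in, 1 inter, 2 out) if the pattern
    is structurally a feed-forward loop, else None."""
    if pattern.n_nodes != 3 or len(pattern.edges) != 3:
        return None
    g = pattern.graph()
    mapping: dict[str, int] = {}
    for role in pattern.roles:
        ins, outs = g.in_degree(role), g.out_degree(role)
        if (ins, outs) == (0, 2):
            mapping[role] = 0
        elif (ins, outs) == (1, 1):
            mapping[role] = 1
        elif (ins, outs) == (2, 0):
            mapping[role] = 2
        else:
            return None
    return mapping if sorted(mapping.values()) == [0, 1, 2] else None


def _canon_descriptor(desc: Descriptor, symmetric: bool) -> Descriptor:
    desc = tuple(sorted(desc))
    if symmetric:
        swapped = tuple(sorted((b, a) for a, b in desc))
        return min(desc, swapped)
    return desc


@dataclass(frozen=True)
class CatalogEntry:
    """One clustering type: a canonical union graph plus metadata."""

    type_id: int
    pattern_pair: tuple[str, str]
    n_shared: int
    n_nodes: int
    n_edges: int
    certificate: tuple = field(compare=False)
    graph: nx.DiGraph = field(compare=False, repr=False)
    descriptors: frozenset[Descriptor] = field(compare=False, repr=False)


class ClusteringTypeCatalog:
    """Ordered, isomorphism-deduplicated set of pairwise clustering types."""

    def __init__(
        self, patterns: tuple[MotifPattern, ...], entries: list[CatalogEntry]
    ) -> None:
        self.patterns = patterns
        self.entries = entries
        self.pattern_by_name = {p.name: p for p in patterns}
        self._pattern_order = {p.name: i for i, p in enumerate(patterns)}
        self._by_descriptor: dict[tuple[str, str, Descriptor], CatalogEntry] = {}
        self._by_certificate: dict[tuple, CatalogEntry] = {}
        for entry in entries:
            self._by_certificate[entry.certificate] = entry
            for desc in entry.descriptors:
                self._by_descriptor[
                    (entry.pattern_pair[0], entry.pattern_pair[1], desc)
                ] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def type_ids(self) -> list[int]:
        return [entry.type_id for entry in self.entries]

    def entry(self, type_id: int) -> CatalogEntry:
        for e in self.entries:
            if e.type_id == type_id:
                return e
        raise KeyError(type_id)

    def lookup_descriptor(
        self, name1: str, name2: str, desc: Descriptor
    ) -> CatalogEntry | None:
        return self._by_descriptor.get((name1, name2, desc))

    def lookup_certificate(self, certificate: tuple) -> CatalogEntry | None:
        return self._by_certificate.get(certificate)


def _enumerate_overlaps(
    p1: MotifPattern, p2: MotifPattern
) -> dict[tuple, dict]:
    """All valid union graphs of one copy of ``p1`` and one of ``p2``.

    Returns certificate -> {graph, n_shared, descriptors}.  A candidate
    identification is valid when each copy's node set induces exactly its
    own edges in the union.
    """
    same = p1 is p2 or (p1.roles == p2.roles and p1.edges == p2.edges)
    found: dict[tuple, dict] = {}
    max_shared = min(p1.n_nodes, p2.n_nodes)
    for s in range(1, max_shared + 1):
        if s == p1.n_nodes == p2.n_nodes:
            # full identification would make the two copies a single
            # instance (a node set hosts one induced occurrence)
            continue
        for subset1 in itertools.combinations(p1.roles, s):
            for target in itertools.permutations(p2.roles, s):
                ident = dict(zip(subset1, target))
                inv = {v: k for k, v in ident.items()}
                node1 = {r: ("1", r) for r in p1.roles}
                node2 = {
                    r: ("1", inv[r]) if r in inv else ("2", r) for r in p2.roles
                }
                edges1 = {(node1[u], node1[v]) for u, v in p1.edges}
                edges2 = {(node2[u], node2[v]) for u, v in p2.edges}
                union_edges = edges1 | edges2
                set1 = set(node1.values())
                set2 = set(node2.values())
                induced1 = {
                    (u, v) for u, v in union_edges if u in set1 and v in set1
                }
                induced2 = {
                    (u, v) for u, v in union_edges if u in set2 and v in set2
                }
                if induced1 != edges1 or induced2 != edges2:
                    continue
                nodes = sorted(set1 | set2)
                cert = canonical_certificate(nodes, union_edges)
                desc = _canon_descriptor(
                    tuple(
                        (p1.role_index(r), p2.role_index(ident[r]))
                        for r in subset1
                    ),
                    symmetric=same,
                )
                record = found.setdefault(
                    cert,
                    {"n_shared": s, "descriptors": set(), "edges": union_edges,
                     "nodes": nodes},
                )
                record["descriptors"].add(desc)
    return found


def enumerate_types(
    patterns: Iterable[MotifPattern], mode: str = "all"
) -> ClusteringTypeCatalog:
    """Generate the catalog of pairwise clustering types for a motif set.

    ``mode`` restricts which pattern pairs are enumerated: ``"all"``
    (default), ``"homologous"`` (same-type pairs only) or
    ``"heterologous"`` (cross-type pairs only).
    """
    patterns = validate_pattern_set(tuple(patterns))
    if mode not in {"all", "homologous", "heterologous"}:
        raise ValidationError(f"unknown enumeration mode {mode!r}")

    raw: list[dict] = []
    for i, p1 in enumerate(patterns):
        for j in range(i, len(patterns)):
            p2 = patterns[j]
            if mode == "homologous" and i != j:
                continue
            if mode == "heterologous" and i == j:
                continue
            for cert, record in _enumerate_overlaps(p1, p2).items():
                raw.append(
                    {
                        "pattern_pair": (p1.name, p2.name),
                        "certificate": cert,
                        **record,
                    }
                )

    # Numbering: the published FFL taxonomy when the catalog is for a single
    # FFL-structured pattern, otherwise (n_shared, certificate) order.
    entries: list[CatalogEntry] = []
    ffl_roles = (
        _structural_ffl_roles(patterns[0]) if len(patterns) == 1 else None
    )
    if ffl_roles is not None and len(patterns) == 1 and mode != "heterologous":
        pat = patterns[0]
        # translate actual role indices -> structural indices
        struct_of_index = {pat.role_index(r): s for r, s in ffl_roles.items()}

        def ffl_id(record: dict) -> int:
            descs = record["descriptors"]
            ids = set()
            for desc in descs:
                sdesc = _canon_descriptor(
                    tuple(
                        (struct_of_index[a], struct_of_index[b]) for a, b in desc
                    ),
                    symmetric=True,
                )
                ids.add(_FFL_TYPE_IDS[sdesc])
            if len(ids) != 1:  # pragma: no cover - taxonomy is a bijection
                raise ClassificationError(
                    f"ambiguous FFL type ids {ids} for one union graph"
                )
            return ids.pop()

        raw.sort(key=ffl_id)
        numbered = [(ffl_id(r), r) for r in raw]
    else:
        raw.sort(key=lambda r: (r["n_shared"], r["certificate"]))
        numbered = [(k + 1, r) for k, r in enumerate(raw)]

    for type_id, record in numbered:
        graph = nx.DiGraph()
        graph.add_nodes_from(record["nodes"])
        graph.add_edges_from(record["edges"])
        entries.append(
            CatalogEntry(
                type_id=type_id,
                pattern_pair=record["pattern_pair"],
                n_shared=record["n_shared"],
                n_nodes=len(record["nodes"]),
                n_edges=len(record["edges"]),
                certificate=record["certificate"],
                graph=graph,
                descriptors=frozenset(record["descriptors"]),
            )
        )
    return ClusteringTypeCatalog(patterns, entries)


def classify_pair(
    inst1: MotifInstance,
    inst2: MotifInstance,
    catalog: ClusteringTypeCatalog,
) -> int | None:
    """Catalog type id of a clustered instance pair, or None when disjoint.

    The pair subgraph is the union of the two instances' own edges (never
    the induced graph on their node union, so bystander edges between
    non-shared nodes cannot break classification).  Classification is a
    descriptor lookup validated against the enumerated catalog; a clustered
    pair of induced instances that matches no entry indicates an internal
    inconsistency and raises :class:`ClassificationError`.
    """
    shared = inst1.node_set & inst2.node_set
    if not shared:
        return None
    order = catalog._pattern_order
    a, b = inst1, inst2
    if order[b.pattern] < order[a.pattern]:
        a, b = b, a
    pa = catalog.pattern_by_name[a.pattern]
    pb = catalog.pattern_by_name[b.pattern]
    same = pa.name == pb.name
    desc = _canon_descriptor(
        tuple(
            (pa.role_index(a.roles_of(v)[0]), pb.role_index(b.roles_of(v)[0]))
            for v in shared
        ),
        symmetric=same,
    )
    entry = catalog.lookup_descriptor(pa.name, pb.name, desc)
    if entry is None:
        # fall back to union-graph isomorphism (should not be needed for
        # induced instances; kept as a safety net for hand-built instances)
        nodes = sorted(inst1.node_set | inst2.node_set)
        cert = canonical_certificate(nodes, inst1.edges | inst2.edges)
        entry = catalog.lookup_certificate(cert)
    if entry is None:
        raise ClassificationError(
            f"clustered pair {sorted(inst1.node_set)} / {sorted(inst2.node_set)} "
            "matches no catalog entry; instances are not induced occurrences "
            "of the catalog's patterns"
        )
    return entry.type_id


@dataclass(frozen=True)
class TypeDistribution:
    """Counts and fractions of clustering types over clustered pairs."""

    counts: dict[int, int]
    fractions: dict[int, float]
    n_pairs_clustered: int
    n_instances: int


def _cooccurring_pairs(
    instances: Sequence[MotifInstance],
) -> tuple[dict[str, list[int]], set[tuple[int, int]]]:
    by_node: dict[str, list[int]] = defaultdict(list)
    for idx, inst in enumerate(instances):
        for v in inst.node_set:
            by_node[v].append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in by_node.values():
        for i, j in itertools.combinations(members, 2):
            pairs.add((i, j) if i < j else (j, i))
    return by_node, pairs


def type_distribution(
    network: nx.DiGraph,
    patterns: Iterable[MotifPattern],
    catalog: ClusteringTypeCatalog | None = None,
    instances: Sequence[MotifInstance] | None = None,
) -> TypeDistribution:
    """Classify all clustered instance pairs and normalize the counts.

    Disjoint pairs are neglected; fractions are over clustered pairs only
    and include explicit zeros for unobserved catalog types.
    """
    patterns = validate_pattern_set(tuple(patterns))
    if catalog is None:
        catalog = enumerate_types(patterns)
    if instances is None:
        instances = [
            inst for pattern in patterns for inst in find_instances(network, pattern)
        ]
    _, pairs = _cooccurring_pairs(instances)
    counts: Counter[int] = Counter()
    for i, j in pairs:
        tid = classify_pair(instances[i], instances[j], catalog)
        if tid is not None:
            counts[tid] += 1
    n_pairs = sum(counts.values())
    all_ids = catalog.type_ids
    full_counts = {tid: counts.get(tid, 0) for tid in all_ids}
    fractions = {
        tid: (c / n_pairs if n_pairs else 0.0) for tid, c in full_counts.items()
    }
    return TypeDistribution(
        counts=full_counts,
        fractions=fractions,
        n_pairs_clustered=n_pairs,
        n_instances=len(instances),
    )


def mcd(
    network: nx.DiGraph,
    patterns: Iterable[MotifPattern],
    catalog: ClusteringTypeCatalog | None = None,
    instances: Sequence[MotifInstance] | None = None,
) -> dict[str, int]:
    """Motif clustering diversity per node.

    For each node, all motif instances containing it are extracted, every
    pair of those instances is classified, and the MCD is the number of
    distinct clustering types among the pairs.  Nodes in fewer than two
    motifs have MCD 0.
    """
    patterns = validate_pattern_set(tuple(patterns))
    if catalog is None:
        catalog = enumerate_types(patterns)
    if instances is None:
        instances = [
            inst for pattern in patterns for inst in find_instances(network, pattern)
        ]
    by_node, _ = _cooccurring_pairs(instances)
    memo: dict[tuple[int, int], int | None] = {}
    table: dict[str, int] = {}
    for node in network.nodes:
        members = by_node.get(node, [])
        types: set[int] = set()
        for i, j in itertools.combinations(members, 2):
            key = (i, j) if i < j else (j, i)
            if key not in memo:
                memo[key] = classify_pair(instances[key[0]], instances[key[1]], catalog)
            tid = memo[key]
            if tid is not None:
                types.add(tid)
        table[str(node)] = len(types)
    return table


@dataclass(frozen=True)
class Coverage:
    """Node/edge coverage of the extracted motif subnetwork."""

    n_nodes: int
    n_edges: int
    node_fraction: float
    edge_fraction: float


def extract_motif_subnetwork(
    network: nx.DiGraph,
    patterns: Iterable[MotifPattern],
    instances: Sequence[MotifInstance] | None = None,
) -> tuple[nx.DiGraph, Coverage]:
    """Union of all motif instances (their nodes and their own edges).

    Returns the subnetwork plus node/edge coverage fractions relative to
    the whole network.
    """
    patterns = validate_pattern_set(tuple(patterns))
    if instances is None:
        instances = [
            inst for pattern in patterns for inst in find_instances(network, pattern)
        ]
    sub = nx.DiGraph()
    for inst in instances:
        sub.add_nodes_from(inst.node_set)
        sub.add_edges_from(inst.edges)
    n, e = network.number_of_nodes(), network.number_of_edges()
    coverage = Coverage(
        n_nodes=sub.number_of_nodes(),
        n_edges=sub.number_of_edges(),
        node_fraction=sub.number_of_nodes() / n if n else 0.0,
        edge_fraction=sub.number_of_edges() / e if e else 0.0,
    )
    sub.graph["name"] = f"{network.graph.get('name', 'network')}-motifs"
    return sub, coverage
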