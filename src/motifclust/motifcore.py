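"""Motif patterns and the induced-occurrence census.

A :class:`MotifPattern` is a tiny role-labeled digraph used as a search
template.  Matching is **induced**: an occurrence is a node set whose
induced subgraph in the host network is edge-identical to the pattern.
Induced semantics is what makes the pairwise clustering-type taxonomy
finite and total (two FFLs sharing one node always give a 5-node/6-edge
union, two sharing two nodes a 4-node/5-edge union), and it is applied
consistently across the whole package.

Occurrences are deduplicated up to pattern automorphism: a node set hosts
at most one instance per pattern, so the set of found motifs is exactly a
set of node sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from networkx.algorithms import isomorphism as iso

from motifclust.errors import ParseError, PatternSetError, ValidationError


@dataclass(frozen=True)
class MotifPattern:
    """A role-labeled directed pattern graph.

    Parameters
    ----------
    name:
        Identifier used in results ("ffl", "fbl", ...).
    roles:
        Ordered role labels; order fixes the canonical role indexing used
        by the clustering-type catalog.
    edges:
        Directed role pairs.
    """

    name: str
    roles: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.roles)) != len(self.roles):
            raise ValidationError(f"pattern {self.name!r}: duplicate roles")
        if len(self.roles) < 2:
            raise ValidationError(f"pattern {self.name!r}: needs at least 2 roles")
        role_set = set(self.roles)
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"pattern {self.name!r}: self-loop on {u!r}")
            if u not in role_set or v not in role_set:
                raise ValidationError(
                    f"pattern {self.name!r}: edge ({u!r},{v!r}) uses unknown role"
                )
        if not nx.is_weakly_connected(self.graph()):
            raise ValidationError(f"pattern {self.name!r}: not weakly connected")

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    def role_index(self, role: str) -> int:
        return self.roles.index(role)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.roles)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "MotifPattern":
        """Load a custom pattern from a tiny edge list with a role header.

        Format::

            roles: input intermediate output
            input intermediate
            input output
            intermediate output

        Comment lines start with ``#``.
        """
        path = Path(path)
        roles: tuple[str, ...] | None = None
        edges: set[tuple[str, str]] = set()
        with open(path, encoding="utf-8") as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if line.lower().startswith("roles:"):
                    roles = tuple(line.split(":", 1)[1].split())
                    continue
                tokens = line.split()
                if len(tokens) != 2:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 'source target', got {line!r}"
                    )
                edges.add((tokens[0], tokens[1]))
        if roles is None:
            raise ParseError(f"{path}: missing 'roles:' header line")
        return cls(name or path.stem, roles, frozenset(edges))


#: Feed-forward loop: input regulates intermediate and output, intermediate
#: also regulates output.
FFL = MotifPattern(
    "ffl",
    ("input", "intermediate", "output"),
    frozenset(
        {
            ("input", "intermediate"),
            ("input", "output"),
            ("intermediate", "output"),
        }
    ),
)

#: Feedback loop: a directed 3-cycle.
FBL = MotifPattern(
    "fbl",
    ("a", "b", "c"),
    frozenset({("a", "b"), ("b", "c"), ("c", "a")}),
)

_BUILTINS = {"ffl": FFL, "fbl": FBL}


def builtin_pattern(name: str) -> MotifPattern:
    """Look up a built-in pattern by name (``"ffl"`` or ``"fbl"``)."""
    try:
        return _BUILTINS[name.lower()]
    except KeyError:
        raise ValidationError(
            f"unknown built-in motif {name!r}; available: {sorted(_BUILTINS)}"
        ) from None


def validate_pattern_set(patterns: Sequence[MotifPattern]) -> tuple[MotifPattern, ...]:
    """Check the no-mutual-subisomorphism rule and duplicate names.

    Within a pattern set no pattern may be an induced subgraph isomorph of
    another; otherwise every occurrence of the larger would spawn spurious
    occurrences of the smaller and the pairwise taxonomy would double-count.
    """
    patterns = tuple(patterns)
    if not patterns:
        raise ValidationError("empty pattern set")
    names = [p.name for p in patterns]
    if len(set(names)) != len(names):
        raise PatternSetError(f"duplicate pattern names in set: {names}")
    for i, p in enumerate(patterns):
        for j, q in enumerate(patterns):
            if i == j:
                continue
            if p.n_nodes <= q.n_nodes:
                matcher = iso.DiGraphMatcher(q.graph(), p.graph())
                if matcher.subgraph_is_isomorphic():
                    raise PatternSetError(
                        f"pattern {p.name!r} is a subisomorphism of {q.name!r}; "
                        "pattern sets must be subisomorphism-free"
                    )
    return patterns


@dataclass(frozen=True)
class MotifInstance:
    """One induced occurrence of a pattern in a network.

    ``mapping`` pairs each pattern role with its network node, in pattern
    role order; among automorphic mappings of the same node set the
    lexicographically smallest node tuple is kept, so instances are unique
    and deterministic.
    """

    pattern: str
    mapping: tuple[tuple[str, str], ...]
    node_set: frozenset[str] = field(compare=False)
    edges: frozenset[tuple[str, str]] = field(compare=False)

    def node_of(self, role: str) -> str:
        for r, n in self.mapping:
            if r == role:
                return n
        raise KeyError(role)

    def roles_of(self, node: str) -> list[str]:
        return [r for r, n in self.mapping if n == node]

    @property
    def nodes_in_role_order(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.mapping)


def find_instances(network: nx.DiGraph, pattern: MotifPattern) -> list[MotifInstance]:
    """Enumerate every induced occurrence of ``pattern`` exactly once.

    Uses the VF2 matcher; mappings that differ only by a pattern
    automorphism (e.g. the three rotations of a feedback loop) are merged.
    The result is sorted by node set, so the order is deterministic.
    """
    pattern_graph = pattern.graph()
    matcher = iso.DiGraphMatcher(network, pattern_graph)
    best: dict[frozenset[str], tuple[str, ...]] = {}
    for mapping in matcher.subgraph_isomorphisms_iter():
        # mapping: network node -> pattern role
        by_role = {role: node for node, role in mapping.items()}
        node_tuple = tuple(by_role[r] for r in pattern.roles)
        key = frozenset(node_tuple)
        if key not in best or node_tuple < best[key]:
            best[key] = node_tuple
    instances = []
    for node_tuple in best.values():
        by_role = dict(zip(pattern.roles, node_tuple))
        edges = frozenset((by_role[u], by_role[v]) for u, v in pattern.edges)
        instances.append(
            MotifInstance(
                pattern=pattern.name,
                mapping=tuple(zip(pattern.roles, node_tuple)),
                node_set=frozenset(node_tuple),
                edges=edges,
            )
        )
    instances.sort(key=lambda inst: sorted(inst.node_set))
    return instances


def count_instances(network: nx.DiGraph, pattern: MotifPattern) -> int:
    """Number of induced occurrences of ``pattern`` in ``network``."""
    return len(find_instances(network, pattern))


def find_all_instances(
    network: nx.DiGraph, patterns: Iterable[MotifPattern]
) -> list[MotifInstance]:
    """Census for a validated pattern set, concatenated in pattern order."""
    validated = validate_pattern_set(tuple(patterns))
    out: list[MotifInstance] = []
    for pattern in validated:
        out.extend(find_instances(network, pattern))
    return out
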