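"""Deterministic synthetic networks with known motif-clustering ground truth.

Every recipe builds a network of feed-forward loops whose clustered pairs
all realize a single requested clustering type, together with a
:class:`FixtureSpec` holding the exact expected motif count, clustering
coefficient, type distribution, and per-node MCD.  The ground truth is
derived arithmetically from the construction — never by running the
analysis code these fixtures are meant to test.

Construction per type (k = number of FFLs):

* diagonal one-node types (1, 4, 6): a star — k otherwise-disjoint FFLs
  share one hub playing the same role in all of them; every pair shares
  exactly the hub.
* off-diagonal one-node types (2, 3, 5): a chain — consecutive motifs
  share one node in the two required roles; non-consecutive motifs are
  disjoint, so all clustered pairs have the requested type.
* diagonal two-node types (7, 10, 12): a star on a shared edge — all k
  motifs contain the same directed edge in the same role pair.
* off-diagonal two-node types (8, 9, 11): k/2 disjoint two-motif blocks.
  Chaining these types is impossible without creating clustered pairs of
  *other* types (the third motif inevitably shares a single node with the
  first), so k must be even.

All constructions were checked by hand to introduce no spurious induced
FFLs and no unintended overlaps; the test suite re-verifies this via the
analysis code and independent brute-force oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from motifclust.errors import ValidationError

_STAR_ONE = {1: "output", 4: "intermediate", 6: "input"}
_CHAIN = {2: ("intermediate", "output"), 3: ("input", "output"), 5: ("input", "intermediate")}
_STAR_EDGE = {7: ("intermediate", "output"), 10: ("input", "output"), 12: ("input", "intermediate")}
_BLOCK = {8, 9, 11}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe parameters plus constructed (not computed) ground truth."""

    recipe: str
    params: dict = field(repr=False)
    motif_count: int
    s: int
    t: int
    mc: float
    counts: dict[int, int]
    fractions: dict[int, float]
    n_pairs_clustered: int
    mcd: dict[str, int] = field(repr=False)


def _choose2(n: int) -> int:
    return n * (n - 1) // 2


def _add_ffl(graph: nx.DiGraph, a: str, b: str, c: str) -> None:
    graph.add_edges_from([(a, b), (a, c), (b, c)])


def _full_fractions(counts: dict[int, int]) -> dict[int, float]:
    total = sum(counts.values())
    return {
        tid: (counts.get(tid, 0) / total if total else 0.0) for tid in range(1, 13)
    }


def make_type_fixture(
    type_id: int, k: int, seed=None
) -> tuple[nx.DiGraph, FixtureSpec]:
    """k FFLs whose every clustered pair realizes exactly ``type_id``.

    ``seed`` is accepted for interface uniformity; the constructions are
    deterministic and ignore it.
    """
    if type_id not in range(1, 13):
        raise ValidationError(f"type_id must be 1..12, got {type_id}")
    if k < 2:
        raise ValidationError("k must be >= 2 (a clustered pair needs two motifs)")
    graph = nx.DiGraph(name=f"type{type_id}-k{k}")
    mcd_truth: dict[str, int] = {}

    if type_id in _STAR_ONE:
        hub_role = _STAR_ONE[type_id]
        hub = "hub"
        for i in range(k):
            members = {"input": f"a{i}", "intermediate": f"b{i}", "output": f"c{i}"}
            members[hub_role] = hub
            _add_ffl(graph, members["input"], members["intermediate"], members["output"])
            for role, node in members.items():
                if node != hub:
                    mcd_truth[node] = 0
        mcd_truth[hub] = 1
        n_pairs = _choose2(k)
        s = n_pairs  # each pair shares exactly the hub
    elif type_id in _CHAIN:
        early_role, late_role = _CHAIN[type_id]
        # shared node plays late_role in motif i, early_role in motif i+1
        for i in range(k):
            members = {"input": f"a{i}", "intermediate": f"b{i}", "output": f"c{i}"}
            members[late_role] = f"x{i + 1}"
            members[early_role] = f"x{i}"
            _add_ffl(graph, members["input"], members["intermediate"], members["output"])
            for node in members.values():
                mcd_truth.setdefault(node, 0)
        for i in range(1, k):  # interior chain nodes sit in two motifs
            mcd_truth[f"x{i}"] = 1
        n_pairs = k - 1
        s = k - 1
    elif type_id in _STAR_EDGE:
        u_role, v_role = _STAR_EDGE[type_id]
        u, v = "u", "v"
        for i in range(k):
            members = {"input": f"a{i}", "intermediate": f"b{i}", "output": f"c{i}"}
            members[u_role] = u
            members[v_role] = v
            _add_ffl(graph, members["input"], members["intermediate"], members["output"])
            for node in members.values():
                mcd_truth.setdefault(node, 0)
        mcd_truth[u] = mcd_truth[v] = 1
        n_pairs = _choose2(k)
        s = 2 * n_pairs
    else:  # blocks: 8, 9, 11
        if k % 2:
            raise ValidationError(
                f"type {type_id} cannot be chained pairwise-pure: a third "
                "motif sharing the edge pair necessarily shares a single "
                "node with the first, creating a one-node clustering type; "
                "use an even k (disjoint two-motif blocks)"
            )
        for blk in range(k // 2):
            p = f"blk{blk}_"
            if type_id == 8:  # M2 (input, output) = M1 (input, intermediate)
                _add_ffl(graph, p + "a", p + "b", p + "c")
                _add_ffl(graph, p + "a", p + "d", p + "b")
                shared = (p + "a", p + "b")
            elif type_id == 9:  # M2 (intermediate, output) = M1 (input, intermediate)
                _add_ffl(graph, p + "a", p + "b", p + "c")
                _add_ffl(graph, p + "d", p + "a", p + "b")
                shared = (p + "a", p + "b")
            else:  # 11: M2 (intermediate, output) = M1 (input, output)
                _add_ffl(graph, p + "a", p + "b", p + "c")
                _add_ffl(graph, p + "d", p + "a", p + "c")
                shared = (p + "a", p + "c")
            for node in (p + "a", p + "b", p + "c", p + "d"):
                mcd_truth[node] = 0
            for node in shared:
                mcd_truth[node] = 1
        n_pairs = k // 2
        s = 2 * n_pairs

    t = 2 * _choose2(k)  # every pair of 3-node motifs can share at most 2 nodes
    counts = {type_id: n_pairs}
    spec = FixtureSpec(
        recipe="type_fixture",
        params={"type_id": type_id, "k": k},
        motif_count=k,
        s=s,
        t=t,
        mc=s / t,
        counts=counts,
        fractions=_full_fractions(counts),
        n_pairs_clustered=n_pairs,
        mcd=mcd_truth,
    )
    return graph, spec


def make_mixed_fixture(
    composition: dict[int, float],
    total_pairs: int = 8,
    seed=None,
) -> tuple[nx.DiGraph, FixtureSpec]:
    """Disjoint union of pure two-motif blocks approximating a requested
    type composition.

    ``composition`` maps type id -> desired fraction of clustered pairs
    (must sum to 1; an empty dict yields an empty network).  Each type
    contributes ``round(fraction * total_pairs)`` node-disjoint two-motif
    blocks, so every block adds exactly one clustered pair and cross-block
    pairs are disjoint.  The spec records the exactly achieved distribution.
    """
    if composition:
        if any(t not in range(1, 13) for t in composition):
            raise ValidationError("composition keys must be type ids 1..12")
        if not math.isclose(sum(composition.values()), 1.0, abs_tol=1e-9):
            raise ValidationError("composition fractions must sum to 1")
    pair_counts = {
        t: round(f * total_pairs) for t, f in composition.items() if round(f * total_pairs)
    }
    if composition and not pair_counts:
        raise ValidationError(
            f"composition infeasible at total_pairs={total_pairs}: "
            "every requested fraction rounds to zero blocks"
        )
    graph = nx.DiGraph(name="mixed-fixture")
    mcd_truth: dict[str, int] = {}
    motif_count = 0
    s = 0
    for type_id in sorted(pair_counts):
        for rep in range(pair_counts[type_id]):
            block, block_spec = make_type_fixture(type_id, 2)
            rename = {v: f"t{type_id}r{rep}_{v}" for v in block.nodes}
            graph.update(nx.relabel_nodes(block, rename))
            for old, value in block_spec.mcd.items():
                mcd_truth[rename[old]] = value
            motif_count += 2
            s += block_spec.s
    n_pairs = sum(pair_counts.values())
    t = 2 * _choose2(motif_count)
    counts = dict(sorted(pair_counts.items()))
    spec = FixtureSpec(
        recipe="mixed_fixture",
        params={"composition": dict(composition), "total_pairs": total_pairs},
        motif_count=motif_count,
        s=s,
        t=t,
        mc=(s / t) if t else math.nan,
        counts=counts,
        fractions=_full_fractions(counts),
        n_pairs_clustered=n_pairs,
        mcd=mcd_truth,
    )
    return graph, spec
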