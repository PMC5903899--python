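"""The motif clustering coefficient and its homologous/heterologous variants.

For a network G and motif set M, let F = {f_1, ..., f_n} be the node sets
of all induced motif occurrences.  The motif clustering coefficient is

    Mc = S / T,
    S  = sum_{i<j} |f_i  intersect  f_j|,
    T  = sum_{i<j} ( min(|f_i|, |f_j|) - 1 ),

i.e. the observed shared-node count over the maximum possible had every
pair been fully clustered (two motifs can share at most min(|f_i|,|f_j|)-1
nodes without coinciding).  For a single pattern of size |M| the closed
form T = C(n,2)(|M|-1) holds.

With several motif types, S and T split into same-type (homologous,
Mc+) and cross-type (heterologous, Mc+/-) parts.  Undefined ratios
(T = 0, e.g. fewer than two motifs) are reported as NaN, never 0: zero is
a meaningful value meaning "fully isolated motifs".
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from motifclust.motifcore import (
    MotifInstance,
    MotifPattern,
    find_instances,
    validate_pattern_set,
)


@dataclass(frozen=True)
class ClusteringResult:
    """Motif clustering coefficient with its ingredients."""

    mc: float  #: S/T, or NaN when undefined (fewer than two motifs)
    s: int  #: total shared nodes over all unordered motif pairs
    t: int  #: maximum possible shared nodes over all pairs
    n: int  #: number of motif instances


@dataclass(frozen=True)
class HomHetResult:
    """Homologous (same-type) and heterologous (cross-type) clustering."""

    mc_plus: float
    mc_minus: float
    s_plus: int
    t_plus: int
    s_minus: int
    t_minus: int
    per_pair: dict[tuple[str, str], tuple[int, int]] = field(compare=False)
    n: int = 0


def _pairwise_s(instances: Sequence[MotifInstance]) -> int:
    # sum over pairs of |f_i ∩ f_j| == sum over nodes of C(d_v, 2)
    counts: Counter[str] = Counter()
    for inst in instances:
        counts.update(inst.node_set)
    return sum(d * (d - 1) // 2 for d in counts.values())


def _cross_s(a: Sequence[MotifInstance], b: Sequence[MotifInstance]) -> int:
    ca: Counter[str] = Counter()
    cb: Counter[str] = Counter()
    for inst in a:
        ca.update(inst.node_set)
    for inst in b:
        cb.update(inst.node_set)
    return sum(ca[v] * cb[v] for v in ca.keys() & cb.keys())


def _pairwise_t(instances: Sequence[MotifInstance]) -> int:
    sizes = sorted(len(inst.node_set) for inst in instances)
    total = 0
    # sizes sorted ascending: pair (i, j) with i < j has min size sizes[i]
    for i, size in enumerate(sizes):
        total += (len(sizes) - 1 - i) * (size - 1)
    return total


def _cross_t(a: Sequence[MotifInstance], b: Sequence[MotifInstance]) -> int:
    return sum(
        min(len(x.node_set), len(y.node_set)) - 1 for x in a for y in b
    )


def _ratio(s: int, t: int, what: str) -> float:
    if t == 0:
        warnings.warn(
            f"{what} undefined (maximum possible shared-node count is 0); "
            "reporting NaN",
            stacklevel=3,
        )
        return math.nan
    return s / t


def motif_clustering(
    network: nx.DiGraph,
    patterns: Iterable[MotifPattern],
    instances: Sequence[MotifInstance] | None = None,
) -> ClusteringResult:
    """Motif clustering coefficient Mc = S/T over all motif pairs.

    ``instances`` may be supplied to reuse a precomputed census; otherwise
    the induced census is run for every pattern in the validated set.
    """
    patterns = validate_pattern_set(tuple(patterns))
    if instances is None:
        instances = [
            inst for pattern in patterns for inst in find_instances(network, pattern)
        ]
    s = _pairwise_s(instances)
    t = _pairwise_t(instances)
    mc = _ratio(s, t, "motif clustering coefficient")
    return ClusteringResult(mc=mc, s=s, t=t, n=len(instances))


def homologous_heterologous(
    network: nx.DiGraph,
    patterns: Iterable[MotifPattern],
    instances: Sequence[MotifInstance] | None = None,
) -> HomHetResult:
    """Split motif clustering into same-type (Mc+) and cross-type parts.

    Mc+ pools the within-type numerators and denominators over all types;
    the heterologous coefficient pools all unordered cross-type pairs.
    With a single pattern type Mc+ equals plain Mc and the heterologous
    value is undefined (NaN).
    """
    patterns = validate_pattern_set(tuple(patterns))
    if instances is None:
        instances = [
            inst for pattern in patterns for inst in find_instances(network, pattern)
        ]
    by_type: dict[str, list[MotifInstance]] = {p.name: [] for p in patterns}
    for inst in instances:
        by_type[inst.pattern].append(inst)

    per_pair: dict[tuple[str, str], tuple[int, int]] = {}
    s_plus = t_plus = s_minus = t_minus = 0
    names = [p.name for p in patterns]
    for i, name_i in enumerate(names):
        group_i = by_type[name_i]
        s_ii = _pairwise_s(group_i)
        t_ii = _pairwise_t(group_i)
        per_pair[(name_i, name_i)] = (s_ii, t_ii)
        s_plus += s_ii
        t_plus += t_ii
        for name_j in names[i + 1 :]:
            group_j = by_type[name_j]
            s_ij = _cross_s(group_i, group_j)
            t_ij = _cross_t(group_i, group_j)
            per_pair[(name_i, name_j)] = (s_ij, t_ij)
            s_minus += s_ij
            t_minus += t_ij

    mc_plus = _ratio(s_plus, t_plus, "homologous motif clustering")
    if len(names) < 2:
        warnings.warn(
            "heterologous motif clustering undefined with a single motif type; "
            "reporting NaN",
            stacklevel=2,
        )
        mc_minus = math.nan
    else:
        mc_minus = _ratio(s_minus, t_minus, "heterologous motif clustering")
    return HomHetResult(
        mc_plus=mc_plus,
        mc_minus=mc_minus,
        s_plus=s_plus,
        t_plus=t_plus,
        s_minus=s_minus,
        t_minus=t_minus,
        per_pair=per_pair,
        n=len(instances),
    )
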