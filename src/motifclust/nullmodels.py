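"""Null models: random generators, randomizers, significance, robustness.

Four nulls are provided, each matched to a question:

* Erdős-Rényi digraphs — what does pure random wiring produce?
* Duplication growth — what does neutral copy-and-paste evolution produce?
  (Duplicating any motif node creates a new, fully clustered instance of
  the same motif; unbiased duplication from an FFL template leaves the
  characteristic 7/10/12 two-node-type signature.)
* Degree-preserving edge swaps — is the motif count itself significant?
* Motif-count-preserving rejection sampling — is the *clustering* of the
  motifs significant given how many there are?

All generators take an integer seed (or a ``numpy.random.Generator``) and
are exactly reproducible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from motifclust.errors import SamplingError, ValidationError
from motifclust.clustering import motif_clustering
from motifclust.motifcore import MotifPattern, count_instances
from motifclust.motiftypes import (
    ClusteringTypeCatalog,
    enumerate_types,
    type_distribution,
)

logger = logging.getLogger(__name__)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# generators


def erdos_renyi(n: int, p: float, seed=None, name: str = "er") -> nx.DiGraph:
    """Directed G(n, p): each ordered pair (u, v), u != v, is an edge
    independently with probability p.  Nodes are "n0" ... "n{n-1}"."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"edge probability p={p} outside [0, 1]")
    if n < 0:
        raise ValidationError("n must be non-negative")
    rng = _rng(seed)
    graph = nx.DiGraph(name=name)
    labels = [f"n{i}" for i in range(n)]
    graph.add_nodes_from(labels)
    if p > 0 and n > 1:
        # vectorized Bernoulli over the n*(n-1) ordered non-diagonal pairs
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        rows, cols = np.nonzero(mask)
        graph.add_edges_from((labels[i], labels[j]) for i, j in zip(rows, cols))
    return graph


def duplication_growth(
    template: MotifPattern,
    target_n: int,
    seed=None,
    role_bias: dict[str, float] | None = None,
) -> nx.DiGraph:
    """Grow a network from a template motif by whole-node duplication.

    At each step a node is chosen (uniformly, or weighted by
    ``role_bias`` over the template role its lineage descends from) and a
    copy with identical in- and out-neighborhoods is added.  The copy
    gains no edge to its originator (pure neighborhood copying).  Growth
    stops at ``target_n`` nodes.  Node attribute ``"role"`` records each
    node's template role.
    """
    if target_n < template.n_nodes:
        raise ValidationError(
            f"target_n={target_n} smaller than template size {template.n_nodes}"
        )
    if role_bias is not None:
        unknown = set(role_bias) - set(template.roles)
        if unknown:
            raise ValidationError(f"role_bias names unknown roles: {sorted(unknown)}")
        weights = {r: float(role_bias.get(r, 0.0)) for r in template.roles}
        if any(w < 0 for w in weights.values()):
            raise ValidationError("role_bias weights must be non-negative")
        if sum(weights.values()) == 0:
            raise ValidationError("role_bias weights sum to zero")
    else:
        weights = {r: 1.0 for r in template.roles}
    rng = _rng(seed)
    graph = nx.DiGraph(name=f"dup-{template.name}")
    for role in template.roles:
        graph.add_node(f"{role}0", role=role)
    graph.add_edges_from((f"{u}0", f"{v}0") for u, v in template.edges)
    counter = 1
    while graph.number_of_nodes() < target_n:
        nodes = list(graph.nodes)
        w = np.array([weights[graph.nodes[v]["role"]] for v in nodes])
        probs = w / w.sum()
        chosen = nodes[rng.choice(len(nodes), p=probs)]
        role = graph.nodes[chosen]["role"]
        copy = f"{role}{counter}"
        counter += 1
        preds = list(graph.predecessors(chosen))
        succs = list(graph.successors(chosen))
        graph.add_node(copy, role=role)
        graph.add_edges_from((u, copy) for u in preds)
        graph.add_edges_from((copy, v) for v in succs)
    return graph


def degree_preserving_randomize(
    network: nx.DiGraph, n_swaps_per_edge: int = 10, seed=None
) -> nx.DiGraph:
    """Randomize by directed double-edge swaps, preserving every node's
    in- and out-degree exactly.

    Attempts ``n_swaps_per_edge * |E|`` swaps (a→b, c→d) ⇒ (a→d, c→b),
    rejecting any swap that would create a self-loop or a duplicate edge.
    """
    if network.number_of_edges() < 2:
        return network.copy()
    rng = _rng(seed)
    graph = network.copy()
    edges = list(graph.edges())
    edge_set = set(edges)
    attempts = int(n_swaps_per_edge * len(edges))
    n_accepted = 0
    for _ in range(attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue
        new1, new2 = (a, d), (c, b)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i], edges[j] = new1, new2
        n_accepted += 1
    out = nx.DiGraph(name=f"{network.graph.get('name', 'net')}-rewired")
    out.add_nodes_from(network.nodes)
    out.add_edges_from(edge_set)
    logger.debug(
        "degree-preserving randomization: %d/%d swaps accepted", n_accepted, attempts
    )
    return out


def motif_preserving_sample(
    network: nx.DiGraph,
    pattern: MotifPattern,
    seed=None,
    max_restarts: int = 10_000,
) -> nx.DiGraph:
    """Rejection-sample a network with the same node count, edge count and
    motif count as the original.

    Starting from an empty network on the same nodes, motif copies are
    placed on uniformly drawn node tuples until the original instance
    count is reached, then outstanding edges are placed uniformly at
    random.  Whenever the motif count or the edge count exceeds the
    original's — or edge placement destroys induced instances so the final
    counts cannot match — the attempt is rejected and restarted.  Raises
    :class:`SamplingError` once ``max_restarts`` attempts all fail.
    """
    rng = _rng(seed)
    target_motifs = count_instances(network, pattern)
    target_edges = network.number_of_edges()
    nodes = list(network.nodes)
    if len(nodes) < pattern.n_nodes and target_motifs > 0:
        raise ValidationError("network smaller than pattern but has instances?")

    for attempt in range(max_restarts + 1):
        graph = nx.DiGraph(name=f"{network.graph.get('name', 'net')}-motifnull")
        graph.add_nodes_from(nodes)
        ok = True
        # phase 1: place motifs
        guard = 0
        while count_instances(graph, pattern) < target_motifs:
            guard += 1
            if guard > 20 * max(target_motifs, 1):
                ok = False  # stuck: placements keep cancelling each other
                break
            placement = rng.choice(len(nodes), size=pattern.n_nodes, replace=False)
            chosen = [nodes[k] for k in placement]
            by_role = dict(zip(pattern.roles, chosen))
            graph.add_edges_from(
                (by_role[u], by_role[v]) for u, v in pattern.edges
            )
            if (
                graph.number_of_edges() > target_edges
                or count_instances(graph, pattern) > target_motifs
            ):
                ok = False
                break
        # phase 2: outstanding edges
        if ok:
            while graph.number_of_edges() < target_edges:
                u, v = (nodes[k] for k in rng.integers(0, len(nodes), size=2))
                if u == v or graph.has_edge(u, v):
                    continue
                graph.add_edge(u, v)
                if count_instances(graph, pattern) != target_motifs:
                    ok = False
                    break
        if ok and count_instances(graph, pattern) == target_motifs:
            if attempt:
                logger.debug("motif-preserving sample accepted after %d restarts", attempt)
            graph.graph["n_restarts"] = attempt
            return graph
    raise SamplingError(
        f"motif-preserving sampler exhausted its restart budget "
        f"(max_restarts={max_restarts}) without matching "
        f"{target_motifs} motifs / {target_edges} edges"
    )


# ---------------------------------------------------------------------------
# significance


@dataclass(frozen=True)
class SignificanceResult:
    """z-score of an observed statistic against a null ensemble."""

    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float  #: (r + 1) / (n + 1), r = #samples >= observed
    n_samples: int
    seed: int | None
    null_model: str
    n_rejected: int = 0
    null_values: tuple[float, ...] = field(default=(), repr=False, compare=False)


_DEFAULT_NULLS = {"motif_count": "degree_preserving", "mc": "motif_preserving"}


def significance(
    network: nx.DiGraph,
    statistic: str = "motif_count",
    null: str | None = None,
    n_samples: int = 1000,
    seed=None,
    pattern: MotifPattern | None = None,
    patterns: Sequence[MotifPattern] | None = None,
    n_swaps_per_edge: int = 10,
    max_restarts: int = 10_000,
) -> SignificanceResult:
    """Significance of a motif statistic against a randomized ensemble.

    ``statistic`` is ``"motif_count"`` (default null: degree-preserving
    swaps) or ``"mc"`` (default null: motif-count-preserving rejection
    sampling — clustering is judged *given* the motif count).  A
    degenerate null (sd = 0) yields a signed-infinity z sentinel with a
    warning, or 0 when the observed value equals the null mean.
    """
    if statistic not in _DEFAULT_NULLS:
        raise ValidationError(
            f"unknown statistic {statistic!r}; choose from {sorted(_DEFAULT_NULLS)}"
        )
    if n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    null = null or _DEFAULT_NULLS[statistic]
    if null not in {"degree_preserving", "motif_preserving"}:
        raise ValidationError(f"unknown null model {null!r}")
    if pattern is None:
        if patterns:
            pattern = patterns[0]
        else:
            from motifclust.motifcore import FFL

            pattern = FFL
    stat_patterns = tuple(patterns) if patterns else (pattern,)

    def stat(g: nx.DiGraph) -> float:
        if statistic == "motif_count":
            return float(
                sum(count_instances(g, p) for p in stat_patterns)
            )
        return motif_clustering(g, stat_patterns).mc

    rng = _rng(seed)
    observed = stat(network)
    values = []
    n_rejected = 0
    for _ in range(n_samples):
        if null == "degree_preserving":
            sample = degree_preserving_randomize(
                network, n_swaps_per_edge=n_swaps_per_edge, seed=rng
            )
        else:
            sample = motif_preserving_sample(
                network, pattern, seed=rng, max_restarts=max_restarts
            )
            n_rejected += sample.graph.get("n_restarts", 0)
        values.append(stat(sample))
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    null_mean = float(finite.mean()) if finite.size else math.nan
    null_sd = float(finite.std(ddof=1)) if finite.size > 1 else math.nan
    diff = observed - null_mean
    if null_sd == 0:
        if diff == 0:
            z = 0.0
        else:
            z = math.inf if diff > 0 else -math.inf
        warnings.warn(
            "null ensemble has zero standard deviation; z reported as "
            f"{z!r} sentinel",
            stacklevel=2,
        )
    else:
        z = diff / null_sd
    r = int(np.sum(arr >= observed))
    p_emp = (r + 1) / (n_samples + 1)
    return SignificanceResult(
        statistic=statistic,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_empirical=p_emp,
        n_samples=n_samples,
        seed=seed if isinstance(seed, int) else None,
        null_model=null,
        n_rejected=n_rejected,
        null_values=tuple(values),
    )


# ---------------------------------------------------------------------------
# robustness


@dataclass(frozen=True)
class RobustnessPoint:
    """Averages over trials at one edge-removal fraction."""

    fraction: float
    n_removed: int
    mean_fractions: dict[int, float]
    mean_motif_count: float
    mean_pairs_clustered: float


def edge_removal_robustness(
    network: nx.DiGraph,
    fractions: Iterable[float],
    trials: int = 500,
    seed=None,
    patterns: Sequence[MotifPattern] | None = None,
    catalog: ClusteringTypeCatalog | None = None,
) -> list[RobustnessPoint]:
    """Average clustering-type distributions under random edge removal.

    For each fraction, ``round(fraction * |E|)`` distinct edges are removed
    uniformly at random in each of ``trials`` independent trials; the
    clustering-type fraction vector (all-zero when no clustered pairs
    remain) and the motif count are averaged across trials.
    """
    if trials < 1:
        raise ValidationError("trials must be >= 1")
    fractions = list(fractions)
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValidationError(f"removal fraction {f} outside (0, 1]")
    if patterns is None:
        from motifclust.motifcore import FFL

        patterns = (FFL,)
    patterns = tuple(patterns)
    if catalog is None:
        catalog = enumerate_types(patterns)
    rng = _rng(seed)
    edges = list(network.edges())
    n_edges = len(edges)
    results = []
    for fraction in fractions:
        n_remove = round(fraction * n_edges)
        sums = {tid: 0.0 for tid in catalog.type_ids}
        count_sum = 0.0
        pairs_sum = 0.0
        for _ in range(trials):
            if n_remove:
                keep_idx = rng.permutation(n_edges)[n_remove:]
                trial_graph = nx.DiGraph()
                trial_graph.add_nodes_from(network.nodes)
                trial_graph.add_edges_from(edges[k] for k in keep_idx)
            else:
                trial_graph = network
            dist = type_distribution(trial_graph, patterns, catalog=catalog)
            for tid, frac in dist.fractions.items():
                sums[tid] += frac
            count_sum += dist.n_instances
            pairs_sum += dist.n_pairs_clustered
        results.append(
            RobustnessPoint(
                fraction=fraction,
                n_removed=n_remove,
                mean_fractions={tid: s / trials for tid, s in sums.items()},
                mean_motif_count=count_sum / trials,
                mean_pairs_clustered=pairs_sum / trials,
            )
        )
    return results
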