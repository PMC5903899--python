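"""Node spin: normalized in/out degree imbalance.

spin(v) = (k_in - k_out) / (k_in + k_out)

classifies a node as a producer/source (-1), relayer/pass-through (0) or
receiver/sink (+1) of information.  Sinks are positive and sources
negative by convention; reversing every edge negates every spin.  Isolated
nodes (k_in + k_out = 0) have undefined spin, reported as NaN per node and
excluded (with a logged count) from the distribution.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np

from motifclust.errors import ValidationError

logger = logging.getLogger(__name__)


def node_spin(network: nx.DiGraph, node: str) -> float:
    """Spin of one node; NaN for isolated nodes."""
    if not network.has_node(node):
        raise KeyError(f"node {node!r} not in network")
    k_in = network.in_degree(node)
    k_out = network.out_degree(node)
    total = k_in + k_out
    if total == 0:
        return math.nan
    return (k_in - k_out) / total


def spin_table(network: nx.DiGraph) -> dict[str, float]:
    """Spin for every node (NaN where isolated)."""
    return {str(v): node_spin(network, v) for v in network.nodes}


def spin_distribution(
    network: nx.DiGraph, bins: int = 21
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized spin histogram over [-1, 1].

    Returns (bin centers, mass).  The default 21 bins are centered so that
    -1, 0 and +1 fall exactly on bin centers.  Mass sums to 1 over
    non-isolated nodes; isolated nodes are excluded with a logged count.
    An empty network (or all-isolated) yields zero mass.
    """
    if bins < 1:
        raise ValidationError("bins must be >= 1")
    width = 2.0 / max(bins - 1, 1)
    edges = np.linspace(-1.0 - width / 2, 1.0 + width / 2, bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    spins = [s for s in spin_table(network).values() if not math.isnan(s)]
    n_isolated = network.number_of_nodes() - len(spins)
    if n_isolated:
        logger.info("spin distribution: excluded %d isolated node(s)", n_isolated)
    counts, _ = np.histogram(spins, bins=edges)
    total = counts.sum()
    mass = counts / total if total else counts.astype(float)
    return centers, mass
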