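"""Label enrichment across MCD strata and top-k measure comparison.

Whether a binary node property (e.g. gene essentiality) concentrates at
particular MCD values is assessed with a group-size-adjusted z-score:
within each MCD group of size n_g, the labeled count under random
assignment follows a fixed-margin hypergeometric distribution (population
N scored nodes, K labeled, draw n_g), so

    z_g = (obs_g - n_g K / N) / sd_hypergeom(N, K, n_g).

A label-permutation null (shuffling the labels over nodes) is provided as
a cross-check since the two differ only in how ties between groups are
handled.  The top-k comparison ranks nodes by MCD, total degree and
(normalized, directed) betweenness centrality; ties at the k-th value are
threshold-inclusive, mirroring selection rules of the form "all nodes
with the maximal MCD".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from motifclust.errors import ValidationError
from motifclust.motifcore import MotifPattern
from motifclust.motiftypes import mcd as compute_mcd

_TRUTHY = {"1", "true", "yes", "y", "essential"}
_FALSY = {"0", "false", "no", "n", "nonessential", "non-essential"}


def _as_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValidationError(
        f"cannot interpret label {value!r} as binary; use true/false, yes/no or 1/0"
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-MCD-group enrichment table plus the margins it was built from."""

    table: pd.DataFrame = field(repr=False)
    n_nodes: int
    n_labeled: int

    def z_of(self, mcd_value: int) -> float:
        row = self.table[self.table["mcd"] == mcd_value]
        if row.empty:
            raise KeyError(mcd_value)
        return float(row["z"].iloc[0])


def mcd_enrichment(
    mcd_table: Mapping[str, int],
    labels: Mapping[str, object],
) -> EnrichmentResult:
    """Group-size-adjusted enrichment of a binary label per MCD value.

    Every scored node must carry a label; unlabeled nodes raise a
    validation error listing them.  Degenerate groups (sd = 0, e.g. when
    every node is labeled) report z = 0 with a warning.
    """
    missing = sorted(v for v in mcd_table if v not in labels)
    if missing:
        preview = ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
        raise ValidationError(
            f"{len(missing)} scored node(s) lack labels: {preview}"
        )
    flags = {v: _as_bool(labels[v]) for v in mcd_table}
    total = len(mcd_table)
    n_labeled = sum(flags.values())
    rows = []
    degenerate = False
    for value in sorted(set(mcd_table.values())):
        members = [v for v, g in mcd_table.items() if g == value]
        n_g = len(members)
        obs = sum(flags[v] for v in members)
        # fixed-margin hypergeometric moments in closed form
        frac = n_labeled / total
        expected = n_g * frac
        var = (
            n_g * frac * (1 - frac) * (total - n_g) / (total - 1)
            if total > 1
            else 0.0
        )
        sd = var**0.5
        if sd == 0.0:
            degenerate = True
            z = 0.0
        else:
            z = (obs - expected) / sd
        # one-sided enrichment p: P(X >= obs)
        p_upper = float(stats.hypergeom.sf(obs - 1, total, n_labeled, n_g))
        rows.append(
            {
                "mcd": value,
                "size": n_g,
                "labeled": obs,
                "expected": expected,
                "sd": sd,
                "z": z,
                "p_upper": p_upper,
            }
        )
    if degenerate:
        warnings.warn(
            "degenerate enrichment group(s) with zero hypergeometric sd; "
            "z reported as 0",
            stacklevel=2,
        )
    return EnrichmentResult(
        table=pd.DataFrame(rows), n_nodes=total, n_labeled=n_labeled
    )


def permutation_enrichment(
    mcd_table: Mapping[str, int],
    labels: Mapping[str, object],
    n_permutations: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Permutation cross-check of :func:`mcd_enrichment`.

    Shuffles the labels over the scored nodes and recomputes each group's
    labeled count, reporting the empirical mean/sd and the resulting z.
    """
    nodes = list(mcd_table)
    flags = np.array([_as_bool(labels[v]) for v in nodes])
    groups = np.array([mcd_table[v] for v in nodes])
    rng = np.random.default_rng(seed)
    values = sorted(set(mcd_table.values()))
    observed = {g: int(flags[groups == g].sum()) for g in values}
    perm_counts = {g: np.empty(n_permutations) for g in values}
    shuffled = flags.copy()
    for i in range(n_permutations):
        rng.shuffle(shuffled)
        for g in values:
            perm_counts[g][i] = shuffled[groups == g].sum()
    rows = []
    for g in values:
        mean = float(perm_counts[g].mean())
        sd = float(perm_counts[g].std(ddof=1))
        z = (observed[g] - mean) / sd if sd else 0.0
        rows.append(
            {"mcd": g, "labeled": observed[g], "perm_mean": mean, "perm_sd": sd, "z": z}
        )
    return pd.DataFrame(rows)


def node_metrics(
    network: nx.DiGraph,
    patterns: Sequence[MotifPattern],
    labels: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Per-node MCD, total degree, betweenness and (optionally) label.

    Degree is in+out; betweenness is the standard directed, unweighted,
    normalized centrality.
    """
    mcd_table = compute_mcd(network, patterns)
    betweenness = nx.betweenness_centrality(network, normalized=True)
    rows = []
    for node in network.nodes:
        row = {
            "node": str(node),
            "mcd": mcd_table[str(node)],
            "degree": network.in_degree(node) + network.out_degree(node),
            "betweenness": betweenness[node],
        }
        if labels is not None:
            row["label"] = _as_bool(labels[node]) if node in labels else False
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TopSetReport:
    """Top-k selection per measure with labeled-hit and Venn counts."""

    k: int
    effective_k: dict[str, int]
    thresholds: dict[str, float]
    top_sets: dict[str, frozenset[str]] = field(repr=False)
    hits: dict[str, int]
    unique_hits: dict[str, int]
    pairwise_overlap: dict[tuple[str, str], int]


def top_set_comparison(
    metrics: pd.DataFrame,
    k: int,
    measures: Sequence[str] = ("mcd", "degree", "betweenness"),
    label_col: str = "label",
) -> TopSetReport:
    """Compare which labeled nodes the top-k of each measure captures.

    Ties at the k-th ranked value are all included (the effective k per
    measure is reported).  ``unique_hits[m]`` counts labeled nodes found
    in measure m's top set and no other's.
    """
    n = len(metrics)
    if k > n:
        raise ValidationError(f"k={k} exceeds node count {n}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    for col in (*measures, label_col, "node"):
        if col not in metrics.columns:
            raise ValidationError(f"metrics table lacks column {col!r}")
    top_sets: dict[str, frozenset[str]] = {}
    thresholds: dict[str, float] = {}
    for m in measures:
        ordered = metrics.sort_values(m, ascending=False, kind="mergesort")
        threshold = float(ordered[m].iloc[k - 1])
        selected = metrics.loc[metrics[m] >= threshold, "node"]
        top_sets[m] = frozenset(selected)
        thresholds[m] = threshold
    labeled = frozenset(metrics.loc[metrics[label_col].astype(bool), "node"])
    hits = {m: len(top_sets[m] & labeled) for m in measures}
    unique_hits = {}
    for m in measures:
        others: set[str] = set()
        for o in measures:
            if o != m:
                others |= top_sets[o]
        unique_hits[m] = len((top_sets[m] - others) & labeled)
    overlap = {
        (a, b): len(top_sets[a] & top_sets[b])
        for i, a in enumerate(measures)
        for b in measures[i + 1 :]
    }
    return TopSetReport(
        k=k,
        effective_k={m: len(top_sets[m]) for m in measures},
        thresholds=thresholds,
        top_sets=top_sets,
        hits=hits,
        unique_hits=unique_hits,
        pairwise_overlap=overlap,
    )
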