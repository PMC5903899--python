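"""Reading, sanitizing and writing directed networks and node label tables.

Networks are plain :class:`networkx.DiGraph` objects whose nodes are opaque
strings.  All downstream analyses assume a *simple* digraph, so loading
removes self-loops (and, for the edge-list dialect, counts duplicate lines);
both removals are logged so the preprocessing can be audited.

Edge-list dialect: whitespace-separated tokens, the first two tokens on a
line are source and target, extra tokens are ignored, lines starting with
``#`` are comments.  This matches the common SNAP-style files distributed
with public network datasets.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from motifclust.errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

_EDGELIST_SUFFIXES = {".txt", ".tsv", ".edgelist", ".edges", ".el"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix == ".gml":
        return "gml"
    if suffix in _EDGELIST_SUFFIXES or suffix == "":
        return "edgelist"
    raise ValidationError(
        f"cannot infer network format from suffix {suffix!r} of {path}; "
        "pass format='edgelist'|'graphml'|'gml'"
    )


def sanitize(graph: nx.DiGraph) -> nx.DiGraph:
    """Remove self-loops in place and log the count.  Idempotent.

    Duplicate edges cannot exist in a ``DiGraph`` (set semantics); formats
    that may contain them report duplicates at parse time instead.
    """
    loops = list(nx.selfloop_edges(graph))
    if loops:
        graph.remove_edges_from(loops)
        logger.info("sanitize: dropped %d self-loop(s)", len(loops))
    return graph


def _read_edgelist(path: Path) -> nx.DiGraph:
    graph = nx.DiGraph()
    n_dupes = 0
    n_loops = 0
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least two tokens, got {line!r}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                n_loops += 1
                continue
            if graph.has_edge(u, v):
                n_dupes += 1
                continue
            graph.add_edge(u, v)
    if n_loops or n_dupes:
        logger.info(
            "read %s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path,
            n_loops,
            n_dupes,
        )
    return graph


def read_network(path: str | Path, format: str | None = None) -> nx.DiGraph:
    """Read a directed network and return a sanitized simple digraph.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``"edgelist"``, ``"graphml"``, ``"gml"``; inferred from the
        file suffix when omitted.

    Node identifiers are coerced to strings and treated as opaque labels
    ("1" and "01" stay distinct).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "edgelist":
        graph = _read_edgelist(path)
    elif fmt == "graphml":
        try:
            loaded = nx.read_graphml(path)
        except Exception as exc:  # nx raises several lxml/expat flavors
            raise ParseError(f"{path}: not valid GraphML: {exc}") from exc
        graph = nx.DiGraph(loaded) if loaded.is_directed() else loaded.to_directed()
        graph = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    elif fmt == "gml":
        try:
            loaded = nx.read_gml(path)
        except Exception as exc:
            raise ParseError(f"{path}: not valid GML: {exc}") from exc
        graph = nx.DiGraph(loaded) if loaded.is_directed() else loaded.to_directed()
        graph = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    else:
        raise ValidationError(f"unknown network format {fmt!r}")
    graph.graph.setdefault("name", path.stem)
    return sanitize(graph)


def write_network(graph: nx.DiGraph, path: str | Path, format: str | None = None) -> None:
    """Write a network as edge list, GraphML, or GML."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edgelist":
        with open(path, "w", encoding="utf-8") as handle:
            for u, v in sorted(graph.edges()):
                handle.write(f"{u} {v}\n")
            # edge lists cannot carry isolated nodes; warn rather than lose silently
            isolated = [n for n in graph.nodes if graph.degree(n) == 0]
            if isolated:
                logger.warning(
                    "write %s: %d isolated node(s) not representable in an edge list",
                    path,
                    len(isolated),
                )
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "gml":
        nx.write_gml(graph, path)
    else:
        raise ValidationError(f"unknown network format {fmt!r}")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``node,label`` CSV into a dict.

    The first row is treated as a header if its second field is not itself
    reused as a label elsewhere; to stay predictable we simply require a
    header row (``node,label`` or similar).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (node,label)")
    nodes = frame.iloc[:, 0].astype(str)
    labels = frame.iloc[:, 1].astype(str)
    table = dict(zip(nodes, labels))
    if len(table) != len(frame):
        raise ParseError(f"{path}: duplicate node keys in label table")
    return table


def match_labels(
    labels: Mapping[str, str], graph: nx.DiGraph
) -> tuple[dict[str, str], list[str]]:
    """Split a label table into (labels on network nodes, unmatched keys).

    Unmatched keys are reported back (and logged), never silently dropped.
    """
    matched = {k: v for k, v in labels.items() if graph.has_node(k)}
    unmatched = sorted(k for k in labels if not graph.has_node(k))
    if unmatched:
        logger.warning(
            "label table: %d key(s) not present in the network: %s%s",
            len(unmatched),
            ", ".join(unmatched[:10]),
            "..." if len(unmatched) > 10 else "",
        )
    return matched, unmatched


def write_table(
    records: Sequence[Mapping[str, object]],
    path: str | Path,
    format: str | None = None,
    columns: Iterable[str] | None = None,
) -> None:
    """Write result records as CSV (with header) or JSON (list of objects).

    ``columns`` fixes the header order and makes an empty record list still
    produce a header-only CSV.
    """
    if records is None:
        raise ValidationError("records must not be None")
    path = Path(path)
    fmt = format or (path.suffix.lower().lstrip(".") or "csv")
    records = list(records)
    if columns is None:
        seen: dict[str, None] = {}
        for rec in records:
            for key in rec:
                seen.setdefault(key, None)
        columns = list(seen)
    else:
        columns = list(columns)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.DictWriter(handle, fieldnames=columns)
            writer.writeheader()
            for rec in records:
                writer.writerow(rec)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(records, handle, indent=2, default=_json_default)
            handle.write("\n")
    else:
        raise ValidationError(f"unknown table format {fmt!r}")


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_table(path: str | Path, format: str | None = None) -> list[dict[str, object]]:
    """Inverse of :func:`write_table`; values come back as strings for CSV."""
    path = Path(path)
    fmt = format or (path.suffix.lower().lstrip(".") or "csv")
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as handle:
            return [dict(row) for row in csv.DictReader(handle)]
    if fmt == "json":
        with open(path, encoding="utf-8") as handle:
            return json.load(handle)
    raise ValidationError(f"unknown table format {fmt!r}")
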