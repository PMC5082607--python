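"""Core network data model and readers/writers.

The in-memory model is a light multigraph: node ids are opaque non-empty
strings, edges form a multiset of (source, target, attrs) triples, and every
node may carry a dictionary of text/numeric attributes plus an optional 2-D
layout position.  Directed input edges keep their direction in storage, but
all cluster/collapse logic treats the graph as undirected and adjacency
queries deduplicate parallel edges.

Supported formats: GraphML (attributes and ``x``/``y`` positions round-trip)
and a plain tab-separated edge list ``source<TAB>target[<TAB>weight]`` with
one optional header line.  Node attribute tables are TSV with a header row
``id<TAB>attr1<TAB>...``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger("netannotate")

#: node/edge attribute keys starting with this prefix are internal bookkeeping
#: (collapse provenance) and are never written to disk.
_PRIVATE_PREFIX = "_"


class GraphFormatError(ValueError):
    """Raised when an input file does not parse in the named dialect."""


@dataclass
class Edge:
    """One edge of the multigraph.

    ``attrs`` may contain an optional numeric ``weight`` plus arbitrary
    text/numeric values; keys starting with ``_`` are internal.
    """

    source: str
    target: str
    attrs: dict = field(default_factory=dict)

    @property
    def weight(self):
        return self.attrs.get("weight")

    def endpoints(self) -> frozenset:
        return frozenset((self.source, self.target))

    def other(self, node_id: str) -> str:
        if node_id == self.source:
            return self.target
        if node_id == self.target:
            return self.source
        raise ValueError(f"{node_id!r} is not an endpoint of this edge")

    def key(self) -> tuple:
        """Hashable identity used for multiset comparison (direction kept)."""
        public = tuple(
            sorted((k, v) for k, v in self.attrs.items() if not k.startswith(_PRIVATE_PREFIX))
        )
        return (self.source, self.target, public)

    def copy(self) -> "Edge":
        return Edge(self.source, self.target, dict(self.attrs))


class Network:
    """Undirected-semantics multigraph with node attributes and positions."""

    def __init__(self) -> None:
        self.nodes: set[str] = set()
        self.edges: list[Edge] = []
        self.node_attrs: dict[str, dict] = {}
        self.positions: dict[str, tuple[float, float]] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str, attrs: Mapping | None = None,
                 position: tuple[float, float] | None = None) -> None:
        if not isinstance(node_id, str) or not node_id:
            raise ValueError("node ids must be non-empty strings")
        self.nodes.add(node_id)
        if attrs:
            self.node_attrs.setdefault(node_id, {}).update(attrs)
        if position is not None:
            x, y = float(position[0]), float(position[1])
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite position for node {node_id!r}")
            self.positions[node_id] = (x, y)

    def add_edge(self, source: str, target: str, attrs: Mapping | None = None) -> Edge:
        for end in (source, target):
            if end not in self.nodes:
                raise ValueError(f"edge endpoint {end!r} is not a node")
        edge = Edge(source, target, dict(attrs) if attrs else {})
        self.edges.append(edge)
        return edge

    def remove_node(self, node_id: str) -> None:
        """Remove a node and all incident edges."""
        self.nodes.discard(node_id)
        self.node_attrs.pop(node_id, None)
        self.positions.pop(node_id, None)
        self.edges = [e for e in self.edges if node_id not in (e.source, e.target)]

    def remove_edge(self, edge: Edge) -> None:
        self.edges.remove(edge)

    # -- queries ----------------------------------------------------------

    def incident_edges(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges if node_id in (e.source, e.target)]

    def neighbors(self, node_id: str) -> set[str]:
        """Undirected, parallel-edge-deduplicated adjacency."""
        out: set[str] = set()
        for e in self.edges:
            if e.source == node_id:
                out.add(e.target)
            elif e.target == node_id:
                out.add(e.source)
        out.discard(node_id)
        return out

    def get_attr(self, node_id: str, name: str):
        return self.node_attrs.get(node_id, {}).get(name)

    def has_attr(self, name: str) -> bool:
        return any(name in a for a in self.node_attrs.values())

    def edge_multiset(self) -> dict:
        counts: dict = {}
        for e in self.edges:
            k = e.key()
            counts[k] = counts.get(k, 0) + 1
        return counts

    def validate(self) -> None:
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge {e.source!r}-{e.target!r} has a missing endpoint")
        for n, (x, y) in self.positions.items():
            if n not in self.nodes:
                raise ValueError(f"position for unknown node {n!r}")
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite position for node {n!r}")

    def copy(self) -> "Network":
        out = Network()
        out.nodes = set(self.nodes)
        out.edges = [e.copy() for e in self.edges]
        out.node_attrs = {n: dict(a) for n, a in self.node_attrs.items()}
        out.positions = dict(self.positions)
        return out

    def structurally_equal(self, other: "Network") -> bool:
        """Equality on node set, edge multiset, public attributes and positions."""
        if self.nodes != other.nodes:
            return False
        if self.edge_multiset() != other.edge_multiset():
            return False
        if _public_attrs(self.node_attrs) != _public_attrs(other.node_attrs):
            return False
        return self.positions == other.positions

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Network |V|={len(self.nodes)} |E|={len(self.edges)}>"


def _public_attrs(node_attrs: dict) -> dict:
    return {
        n: {k: v for k, v in a.items() if not k.startswith(_PRIVATE_PREFIX)}
        for n, a in node_attrs.items()
        if any(not k.startswith(_PRIVATE_PREFIX) for k in a)
    }


# -- attribute tables ------------------------------------------------------


class AttributeTable:
    """Node attribute table keyed by node id; columns are text or numeric."""

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.index.has_duplicates:
            dupes = sorted(frame.index[frame.index.duplicated()].unique())
            raise ValueError(f"duplicate node-id rows in attribute table: {dupes}")
        self.frame = frame

    @classmethod
    def from_rows(cls, rows: Mapping[str, Mapping]) -> "AttributeTable":
        frame = pd.DataFrame.from_dict(dict(rows), orient="index")
        frame.index = frame.index.astype(str)
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def items(self) -> Iterator[tuple[str, dict]]:
        for node_id, row in self.frame.iterrows():
            yield str(node_id), {k: v for k, v in row.items() if pd.notna(v)}


@dataclass
class BindReport:
    """Outcome of merging an attribute table into a network."""

    matched: int
    unmatched_ids: list[str]


def read_attribute_table(path) -> AttributeTable:
    """Read a TSV with header ``id<TAB>attr1<TAB>...`` into an AttributeTable."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 1:
        raise GraphFormatError(f"{path}: attribute table has no columns")
    frame = frame.set_index(frame.columns[0])
    frame.index = frame.index.astype(str)
    return AttributeTable(frame)


def bind_attributes(net: Network, table: AttributeTable) -> tuple[Network, BindReport]:
    """Merge table rows into ``net.node_attrs``.

    Rows whose key matches no node are reported (warning + report object),
    never silently dropped.
    """
    unmatched: list[str] = []
    matched = 0
    for node_id, attrs in table.items():
        if node_id in net.nodes:
            net.node_attrs.setdefault(node_id, {}).update(attrs)
            matched += 1
        else:
            unmatched.append(node_id)
    if unmatched:
        logger.warning(
            "attribute table: %d row(s) match no network node: %s",
            len(unmatched), ", ".join(unmatched[:20]),
        )
    return net, BindReport(matched=matched, unmatched_ids=unmatched)


# -- file formats ----------------------------------------------------------

_EDGELIST_HEADERS = {("source", "target"), ("source", "target", "weight")}


def read_network(path, format: str | None = None) -> Network:
    """Read a network from GraphML or tab-separated edge list.

    ``format`` is ``"graphml"`` or ``"edgelist"``; when omitted it is inferred
    from the file extension (.graphml/.xml → GraphML, otherwise edge list).
    """
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() in (".graphml", ".xml") else "edgelist"
    if format == "graphml":
        return _read_graphml(path)
    if format == "edgelist":
        return _read_edgelist(path)
    raise GraphFormatError(f"unknown network format: {format!r}")


def _read_graphml(path: Path) -> Network:
    try:
        g = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # lxml/expat errors carry line info in their message
        raise GraphFormatError(f"{path}: not valid GraphML: {exc}") from exc
    net = Network()
    for node, data in g.nodes(data=True):
        data = dict(data)
        x, y = data.pop("x", None), data.pop("y", None)
        pos = (float(x), float(y)) if x is not None and y is not None else None
        net.add_node(str(node), attrs=data or None, position=pos)
    for u, v, data in g.edges(data=True):
        net.add_edge(str(u), str(v), attrs=dict(data) or None)
    net.validate()
    return net


def _read_edgelist(path: Path) -> Network:
    net = Network()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and tuple(f.strip().lower() for f in fields) in _EDGELIST_HEADERS:
                continue
            if len(fields) not in (2, 3):
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(fields)}"
                )
            source, target = fields[0].strip(), fields[1].strip()
            if not source or not target:
                raise GraphFormatError(f"{path}:{lineno}: empty node id")
            attrs = {}
            if len(fields) == 3:
                try:
                    attrs["weight"] = float(fields[2])
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not numeric"
                    ) from exc
            net.add_node(source)
            net.add_node(target)
            net.add_edge(source, target, attrs)
    return net


def write_network(net: Network, path, format: str | None = None) -> None:
    """Write GraphML (attributes + positions preserved) or edge-list TSV."""
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() in (".graphml", ".xml") else "edgelist"
    if format == "graphml":
        _write_graphml(net, path)
    elif format == "edgelist":
        _write_edgelist(net, path)
    else:
        raise GraphFormatError(f"unknown network format: {format!r}")


def _write_graphml(net: Network, path: Path) -> None:
    g = nx.MultiGraph()
    for node in sorted(net.nodes):
        data = {
            k: v for k, v in net.node_attrs.get(node, {}).items()
            if not k.startswith(_PRIVATE_PREFIX)
        }
        if node in net.positions:
            data["x"], data["y"] = net.positions[node]
        g.add_node(node, **data)
    for e in net.edges:
        data = {k: v for k, v in e.attrs.items() if not k.startswith(_PRIVATE_PREFIX)}
        g.add_edge(e.source, e.target, **data)
    nx.write_graphml(g, path)


def _write_edgelist(net: Network, path: Path) -> None:
    with open(path, "w") as handle:
        for e in net.edges:
            if e.weight is not None:
                handle.write(f"{e.source}\t{e.target}\t{e.weight}\n")
            else:
                handle.write(f"{e.source}\t{e.target}\n")
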