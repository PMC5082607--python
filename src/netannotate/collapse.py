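"""Collapse clusters into single labeled group nodes with meta-edges.

Collapsing a cluster removes its member nodes (and every incident edge) and
replaces them with one *group node* named by the cluster label and placed at
the members' centroid.  For each external node adjacent to at least one
member, exactly one *meta-edge* is created between the group node and that
node, carrying a ``count`` attribute equal to the number of underlying
boundary edges it summarizes.  Two collapsed clusters that were adjacent
through any boundary edge end up with exactly one meta-edge between their
group nodes, whatever the collapse order.

Every meta-edge privately records the original edges it stands for, and each
group node records its hidden members, so ``expand`` restores the
pre-collapse nodes, attributes, positions and edge multiset exactly — even
when several clusters are collapsed and expanded in arbitrary order: a
restored boundary edge whose far endpoint is still hidden inside another
group is re-routed into that group's meta-edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

from .annotation import AnnotationSet, Cluster
from .graph import Edge, Network

GROUP_PREFIX = "group:"


@dataclass
class CollapseRecord:
    """Everything needed to restore a collapsed cluster exactly."""

    group_id: str
    cluster_id: Hashable
    members: set[str]
    member_attrs: dict[str, dict]
    member_positions: dict[str, tuple[float, float]]
    internal_edges: list[Edge]
    boundary_edges: list[Edge] = field(default_factory=list)


def _is_meta(edge: Edge) -> bool:
    return bool(edge.attrs.get("is_meta"))


def _underlying(edge: Edge) -> list[Edge]:
    """Original edges summarized by an edge (itself, unless it is a meta-edge)."""
    return edge.attrs["_underlying"] if _is_meta(edge) else [edge]


def _containing_group(net: Network, node_id: str) -> str:
    """The group node currently hiding ``node_id``."""
    for gid, attrs in net.node_attrs.items():
        if attrs.get("is_group") and node_id in attrs.get("_members", ()):
            return gid
    raise ValueError(f"node {node_id!r} is neither present nor hidden in a group")


def _add_meta_edges(net: Network, anchor: str, originals_by_rep: dict[str, list[Edge]]) -> None:
    for rep in sorted(originals_by_rep):
        originals = originals_by_rep[rep]
        net.add_edge(anchor, rep, {
            "is_meta": True,
            "count": len(originals),
            "_underlying": originals,
        })


def collapse(net: Network, cluster: Cluster) -> tuple[Network, CollapseRecord]:
    """Collapse ``cluster`` in place; returns the network and a restore record."""
    if cluster.collapsed:
        raise ValueError(f"cluster {cluster.id!r} is already collapsed")
    members = set(cluster.members)
    missing = members - net.nodes
    if missing:
        raise ValueError(f"cluster members not in network: {sorted(missing)}")

    internal: list[Edge] = []
    boundary: list[Edge] = []  # original edges with exactly one endpoint inside
    touched: list[Edge] = []
    for edge in net.edges:
        in_src, in_tgt = edge.source in members, edge.target in members
        if not (in_src or in_tgt):
            continue
        touched.append(edge)
        if in_src and in_tgt:
            internal.append(edge)
        else:
            boundary.extend(_underlying(edge))

    record = CollapseRecord(
        group_id=GROUP_PREFIX + str(cluster.id),
        cluster_id=cluster.id,
        members=members,
        member_attrs={m: dict(net.node_attrs.get(m, {})) for m in members},
        member_positions={m: net.positions[m] for m in members if m in net.positions},
        internal_edges=internal,
        boundary_edges=list(boundary),
    )

    for edge in touched:
        net.remove_edge(edge)
    for m in members:
        net.remove_node(m)

    centroid = None
    if record.member_positions:
        xs = [p[0] for p in record.member_positions.values()]
        ys = [p[1] for p in record.member_positions.values()]
        centroid = (sum(xs) / len(xs), sum(ys) / len(ys))
    net.add_node(record.group_id, attrs={
        "name": cluster.label,
        "is_group": True,
        "_members": sorted(members),
    }, position=centroid)

    # one meta-edge per visible representative of the far endpoints
    by_rep: dict[str, list[Edge]] = {}
    for original in boundary:
        inside = original.source if original.source in members else original.target
        outside = original.other(inside)
        rep = outside if outside in net.nodes else _containing_group(net, outside)
        by_rep.setdefault(rep, []).append(original)
    _add_meta_edges(net, record.group_id, by_rep)

    cluster.collapsed = True
    return net, record


def expand(net: Network, record: CollapseRecord,
           cluster: Cluster | None = None) -> Network:
    """Restore a collapsed cluster exactly; errors if its group node is gone."""
    gid = record.group_id
    if gid not in net.nodes:
        raise ValueError(f"group node {gid!r} not present (already expanded or deleted)")

    # current meta-edges carry the up-to-date boundary provenance
    boundary: list[Edge] = []
    for edge in net.incident_edges(gid):
        boundary.extend(_underlying(edge))
    net.remove_node(gid)

    for m in sorted(record.members):
        net.add_node(m, attrs=record.member_attrs.get(m),
                     position=record.member_positions.get(m))
    for edge in record.internal_edges:
        net.edges.append(edge)

    rerouted: dict[tuple[str, str], list[Edge]] = {}
    for original in boundary:
        inside = original.source if original.source in record.members else original.target
        outside = original.other(inside)
        if outside in net.nodes:
            net.edges.append(original)
        else:
            rep = _containing_group(net, outside)
            rerouted.setdefault((inside, rep), []).append(original)
    for (inside, rep), originals in sorted(rerouted.items()):
        net.add_edge(inside, rep, {
            "is_meta": True,
            "count": len(originals),
            "_underlying": originals,
        })

    if cluster is not None:
        cluster.collapsed = False
    return net


def collapse_all(net: Network, aset: AnnotationSet) -> Network:
    """Collapse every uncollapsed cluster; records kept on the annotation set."""
    for cluster in sorted(aset.clusters, key=lambda c: repr(c.id)):
        if not cluster.collapsed:
            _, record = collapse(net, cluster)
            aset.collapse_records[cluster.id] = record
    return net


def expand_all(net: Network, aset: AnnotationSet) -> Network:
    """Expand every collapsed cluster of the set."""
    for cluster in sorted(aset.clusters, key=lambda c: repr(c.id)):
        if cluster.collapsed:
            record = aset.collapse_records.pop(cluster.id)
            expand(net, record, cluster)
    return net
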