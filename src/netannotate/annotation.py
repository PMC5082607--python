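"""Annotation sets: labeled clusters plus shape/label annotation geometry.

An *annotation set* is a named group of disjoint clusters together with the
cloud and label options that produced their labels; a network holds any
number of sets but at most one is *active* at a time.  Clusters can be
merged, created from node selections and relabeled; geometry (a bounding
shape around the members plus a text label anchored above it) is recomputed
on demand from current node positions, so annotations follow layout changes
for free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

from .clustering import Partition
from .graph import Network
from .labeling import LabelOptions, make_label, select_words
from .wordcloud import CloudOptions, build_cloud, network_counts

DEFAULT_PADDING = 10.0


@dataclass
class Cluster:
    """A disjoint node set summarized by one shape and one label."""

    id: Hashable
    members: set[str]
    label: str = ""
    collapsed: bool = False

    def __post_init__(self) -> None:
        if not self.members and not self.collapsed:
            raise ValueError("a cluster must have members unless collapsed")
        if self.label is None:
            raise ValueError("label may be empty but never None")


@dataclass
class DisplayOptions:
    shape: str = "ellipse"  # or "rectangle"
    border_width: float = 2.0
    fill_opacity: float = 0.2
    shapes_visible: bool = True
    labels_visible: bool = True
    base_font: float = 16.0
    font_scaling: bool = True

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "rectangle"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not 0.0 <= self.fill_opacity <= 1.0:
            raise ValueError("fill_opacity must lie in [0, 1]")
        if self.border_width < 0:
            raise ValueError("border_width must be >= 0")
        if self.base_font <= 0:
            raise ValueError("base_font must be positive")


@dataclass
class ShapeAnnotation:
    """Axis-aligned bounding box (plus shape kind) around a cluster."""

    x: float
    y: float
    w: float
    h: float
    kind: str  # "ellipse" | "rectangle"


@dataclass
class LabelAnnotation:
    """Text anchored horizontally centered at the top edge of its shape."""

    text: str
    anchor_x: float
    anchor_y: float
    font_size: float


@dataclass
class AnnotationSet:
    """Named group of clusters with the options that produced them."""

    name: str
    clusters: list[Cluster] = field(default_factory=list)
    cloud_options: CloudOptions | None = None
    label_options: LabelOptions | None = None
    cluster_source: str = ""
    #: cluster id -> CollapseRecord for currently collapsed clusters
    collapse_records: dict = field(default_factory=dict)

    def cluster(self, cluster_id: Hashable) -> Cluster:
        for c in self.clusters:
            if c.id == cluster_id:
                return c
        raise KeyError(f"no cluster with id {cluster_id!r}")

    def has_collapsed(self) -> bool:
        return any(c.collapsed for c in self.clusters)

    def validate_disjoint(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            overlap = seen & c.members
            if overlap:
                raise ValueError(f"cluster member sets overlap on {sorted(overlap)}")
            seen |= c.members


def compute_label(net: Network, members: Iterable[str], cloud_opts: CloudOptions,
                  label_opts: LabelOptions, n_counts=None) -> str:
    cloud = build_cloud(net, members, cloud_opts, n_counts=n_counts)
    return make_label(select_words(cloud, label_opts))


class AnnotationManager:
    """All annotation sets of one network plus the active-set marker."""

    def __init__(self, net: Network) -> None:
        self.net = net
        self.sets: dict[str, AnnotationSet] = {}
        self.active_name: str | None = None

    # -- set lifecycle ----------------------------------------------------

    def create_annotation_set(self, partition: Partition,
                              cloud_options: CloudOptions,
                              label_options: LabelOptions,
                              name: str,
                              cluster_source: str = "") -> AnnotationSet:
        """Build one labeled Cluster per partition cluster and register the set."""
        if name in self.sets:
            raise ValueError(f"an annotation set named {name!r} already exists")
        partition.validate(self.net)
        n_counts = network_counts(self.net, cloud_options)
        clusters = []
        for cid in sorted(partition.clusters, key=repr):
            members = partition.clusters[cid]
            label = compute_label(self.net, members, cloud_options,
                                  label_options, n_counts=n_counts)
            clusters.append(Cluster(id=cid, members=set(members), label=label))
        aset = AnnotationSet(name=name, clusters=clusters,
                             cloud_options=cloud_options,
                             label_options=label_options,
                             cluster_source=cluster_source)
        self.sets[name] = aset
        if self.active_name is None:
            self.active_name = name
        return aset

    @property
    def active(self) -> AnnotationSet | None:
        return self.sets.get(self.active_name) if self.active_name else None

    def set_active(self, name: str | None) -> None:
        """Switch (or clear) the active set; collapsed clusters block switching."""
        current = self.active
        if current is not None and current.has_collapsed():
            raise ValueError(
                "collapsed clusters present: expand all clusters before "
                "switching annotation sets"
            )
        if name is not None and name not in self.sets:
            raise KeyError(f"no annotation set named {name!r}")
        self.active_name = name

    # -- cluster edits ----------------------------------------------------

    def _relabel_cluster(self, aset: AnnotationSet, cluster: Cluster) -> None:
        cluster.label = compute_label(self.net, cluster.members,
                                      aset.cloud_options, aset.label_options)

    def merge_clusters(self, aset: AnnotationSet,
                       cluster_ids: Sequence[Hashable]) -> Cluster:
        """Union ≥2 clusters into one, recompute its label, drop the originals."""
        if len(cluster_ids) < 2:
            raise ValueError("merge requires at least two clusters")
        if len(set(cluster_ids)) != len(cluster_ids):
            raise ValueError("duplicate cluster id in merge request")
        targets = [aset.cluster(cid) for cid in cluster_ids]
        if any(c.collapsed for c in targets):
            raise ValueError("collapsed clusters cannot be merged; expand first")
        members: set[str] = set()
        for c in targets:
            members |= c.members
        merged = Cluster(id=targets[0].id, members=members)
        aset.clusters = [c for c in aset.clusters if c not in targets]
        aset.clusters.append(merged)
        self._relabel_cluster(aset, merged)
        aset.validate_disjoint()
        return merged

    def create_cluster_from_selection(self, aset: AnnotationSet,
                                      node_ids: Iterable[str]) -> Cluster:
        """New cluster from selected nodes; overlaps move out of old clusters."""
        selection = set(node_ids)
        if not selection:
            raise ValueError("empty selection")
        missing = selection - self.net.nodes
        if missing:
            raise ValueError(f"unknown nodes in selection: {sorted(missing)}")
        for c in aset.clusters:
            c.members -= selection
        aset.clusters = [c for c in aset.clusters if c.members or c.collapsed]
        new_id = self._fresh_cluster_id(aset)
        cluster = Cluster(id=new_id, members=selection)
        aset.clusters.append(cluster)
        self._relabel_cluster(aset, cluster)
        aset.validate_disjoint()
        return cluster

    @staticmethod
    def _fresh_cluster_id(aset: AnnotationSet) -> int:
        taken = {c.id for c in aset.clusters}
        cid = 1
        while cid in taken or str(cid) in taken:
            cid += 1
        return cid

    def relabel(self, aset: AnnotationSet, cluster_id: Hashable,
                manual_text: str | None = None) -> Cluster:
        """Set a label verbatim, or recompute it from the set's options."""
        cluster = aset.cluster(cluster_id)
        if manual_text is not None:
            cluster.label = manual_text
        else:
            self._relabel_cluster(aset, cluster)
        return cluster


def cluster_geometry(net: Network, cluster: Cluster, display: DisplayOptions,
                     padding: float = DEFAULT_PADDING
                     ) -> tuple[ShapeAnnotation, LabelAnnotation]:
    """Bounding shape and label anchor from current member positions.

    The shape is the axis-aligned bounding box of member positions expanded
    by ``padding`` on every side (an ellipse circumscribes the padded box).
    The label is centered at the box top; with ``font_scaling`` on, the font
    grows sublinearly with member count as ``base_font * (1 + log10(n))``.
    """
    missing = [m for m in sorted(cluster.members) if m not in net.positions]
    if missing:
        raise ValueError(f"members without coordinates: {missing}")
    xs = [net.positions[m][0] for m in cluster.members]
    ys = [net.positions[m][1] for m in cluster.members]
    x0, y0 = min(xs) - padding, min(ys) - padding
    w = (max(xs) - min(xs)) + 2 * padding
    h = (max(ys) - min(ys)) + 2 * padding
    shape = ShapeAnnotation(x=x0, y=y0, w=w, h=h, kind=display.shape)
    font = display.base_font
    if display.font_scaling:
        font *= 1.0 + math.log10(len(cluster.members))
    label = LabelAnnotation(text=cluster.label, anchor_x=x0 + w / 2,
                            anchor_y=y0, font_size=font)
    return shape, label
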