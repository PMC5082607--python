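"""Versioned JSON persistence of the annotation model.

A session stores every annotation set (clusters, labels, collapsed flags,
cloud/label options, collapse records) plus the active-set marker.  The
format carries an explicit version tag; loading a file with an unknown
version fails outright — no partial load ever mutates a manager.
"""

from __future__ import annotations

import json
from pathlib import Path

from .annotation import AnnotationManager, AnnotationSet, Cluster
from .collapse import CollapseRecord
from .graph import Edge, Network
from .labeling import LabelOptions
from .wordcloud import DEFAULT_STOPWORDS, CloudOptions

SESSION_FORMAT = "netannotate-session"
SESSION_VERSION = 1


class SessionError(ValueError):
    """Raised for unreadable, truncated or version-incompatible sessions."""


def _edge_to_dict(edge: Edge) -> dict:
    attrs = {k: v for k, v in edge.attrs.items() if k != "_underlying"}
    out = {"source": edge.source, "target": edge.target, "attrs": attrs}
    if "_underlying" in edge.attrs:
        out["underlying"] = [_edge_to_dict(e) for e in edge.attrs["_underlying"]]
    return out


def _edge_from_dict(data: dict) -> Edge:
    attrs = dict(data.get("attrs", {}))
    if "underlying" in data:
        attrs["_underlying"] = [_edge_from_dict(e) for e in data["underlying"]]
    return Edge(data["source"], data["target"], attrs)


def _record_to_dict(record: CollapseRecord) -> dict:
    return {
        "group_id": record.group_id,
        "cluster_id": record.cluster_id,
        "members": sorted(record.members),
        "member_attrs": record.member_attrs,
        "member_positions": {k: list(v) for k, v in record.member_positions.items()},
        "internal_edges": [_edge_to_dict(e) for e in record.internal_edges],
        "boundary_edges": [_edge_to_dict(e) for e in record.boundary_edges],
    }


def _record_from_dict(data: dict) -> CollapseRecord:
    return CollapseRecord(
        group_id=data["group_id"],
        cluster_id=data["cluster_id"],
        members=set(data["members"]),
        member_attrs={k: dict(v) for k, v in data["member_attrs"].items()},
        member_positions={k: tuple(v) for k, v in data["member_positions"].items()},
        internal_edges=[_edge_from_dict(e) for e in data["internal_edges"]],
        boundary_edges=[_edge_from_dict(e) for e in data["boundary_edges"]],
    )


def _cloud_options_to_dict(opts: CloudOptions) -> dict:
    return {
        "attributes": list(opts.attributes),
        "normalization": opts.normalization,
        "extra_stopwords": list(opts.extra_stopwords),
        "min_font": opts.min_font,
        "max_font": opts.max_font,
    }


def _cloud_options_from_dict(data: dict) -> CloudOptions:
    return CloudOptions(
        attributes=tuple(data["attributes"]),
        normalization=data["normalization"],
        stopwords=DEFAULT_STOPWORDS,
        extra_stopwords=tuple(data.get("extra_stopwords", ())),
        min_font=data.get("min_font", 1.0),
        max_font=data.get("max_font", 64.0),
    )


def _set_to_dict(aset: AnnotationSet) -> dict:
    return {
        "name": aset.name,
        "cluster_source": aset.cluster_source,
        "cloud_options": _cloud_options_to_dict(aset.cloud_options)
        if aset.cloud_options else None,
        "label_options": vars(aset.label_options) if aset.label_options else None,
        "clusters": [
            {
                "id": c.id, "members": sorted(c.members),
                "label": c.label, "collapsed": c.collapsed,
            }
            for c in aset.clusters
        ],
        "collapse_records": [
            _record_to_dict(r) for r in aset.collapse_records.values()
        ],
    }


def _set_from_dict(data: dict) -> AnnotationSet:
    aset = AnnotationSet(
        name=data["name"],
        cluster_source=data.get("cluster_source", ""),
        cloud_options=_cloud_options_from_dict(data["cloud_options"])
        if data.get("cloud_options") else None,
        label_options=LabelOptions(**data["label_options"])
        if data.get("label_options") else None,
        clusters=[
            Cluster(id=c["id"], members=set(c["members"]),
                    label=c["label"], collapsed=c["collapsed"])
            for c in data["clusters"]
        ],
    )
    for rec_data in data.get("collapse_records", []):
        record = _record_from_dict(rec_data)
        aset.collapse_records[record.cluster_id] = record
    return aset


def save_session(manager: AnnotationManager, path) -> None:
    """Write all annotation sets, options, records and the active marker."""
    payload = {
        "format": SESSION_FORMAT,
        "version": SESSION_VERSION,
        "active": manager.active_name,
        "annotation_sets": [_set_to_dict(s) for s in manager.sets.values()],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_session(path, net: Network) -> AnnotationManager:
    """Rebuild a manager from a saved session; fails cleanly on bad input."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SessionError(f"{path}: not a valid session file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != SESSION_FORMAT:
        raise SessionError(f"{path}: not a {SESSION_FORMAT} file")
    version = payload.get("version")
    if version != SESSION_VERSION:
        raise SessionError(
            f"{path}: session version {version!r} is not supported "
            f"(this build reads version {SESSION_VERSION})"
        )
    manager = AnnotationManager(net)
    for set_data in payload["annotation_sets"]:
        aset = _set_from_dict(set_data)
        manager.sets[aset.name] = aset
    manager.active_name = payload.get("active")
    return manager
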