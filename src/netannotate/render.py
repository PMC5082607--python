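"""Static SVG rendering of an annotated network.

Layer order bottom→top: cluster shapes, edges, nodes, cluster labels.
Collapsed clusters are not drawn as shapes — their group nodes appear as
ordinary (slightly larger) nodes carrying the cluster label as node name.
Styling is deliberately minimal and deterministic: fixed node radius and
edge stroke, fill colors cycling through a small palette by cluster id.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET

from .annotation import (AnnotationSet, DisplayOptions, cluster_geometry)
from .graph import Network

NODE_RADIUS = 8.0
GROUP_NODE_RADIUS = 14.0
EDGE_STROKE = 1.0
MARGIN = 40.0

PALETTE = (
    "#66c2a5", "#fc8d62", "#8da0cb", "#e78ac3",
    "#a6d854", "#ffd92f", "#e5c494", "#b3b3b3",
)


def _palette_color(index: int) -> str:
    return PALETTE[index % len(PALETTE)]


def render_svg(net: Network, aset: AnnotationSet | None,
               display: DisplayOptions | None = None,
               path=None) -> str:
    """Render the network (plus the annotation set, if given) to SVG 1.1.

    Returns the SVG document as a string and writes it to ``path`` when
    given.  Every node must have a position; offenders are listed in the
    error.
    """
    display = display or DisplayOptions()
    missing = sorted(n for n in net.nodes if n not in net.positions)
    if missing:
        raise ValueError(f"nodes without positions cannot be drawn: {missing}")

    svg = ET.Element("svg", xmlns="http://www.w3.org/2000/svg", version="1.1")
    layers = {
        name: ET.SubElement(svg, "g", id=name)
        for name in ("shapes", "edges", "nodes", "labels")
    }

    xs = [p[0] for p in net.positions.values()] or [0.0]
    ys = [p[1] for p in net.positions.values()] or [0.0]
    bounds = [min(xs) - MARGIN, min(ys) - MARGIN,
              max(xs) + MARGIN, max(ys) + MARGIN]

    drawn_clusters = []
    if aset is not None:
        drawn_clusters = [c for c in aset.clusters if not c.collapsed]
        for index, cluster in enumerate(drawn_clusters):
            shape, label = cluster_geometry(net, cluster, display)
            bounds[0] = min(bounds[0], shape.x - MARGIN)
            bounds[1] = min(bounds[1], shape.y - MARGIN)
            bounds[2] = max(bounds[2], shape.x + shape.w + MARGIN)
            bounds[3] = max(bounds[3], shape.y + shape.h + MARGIN)
            color = _palette_color(index)
            if display.shapes_visible:
                _draw_shape(layers["shapes"], shape, color, display)
            if display.labels_visible and label.text:
                _draw_label(layers["labels"], label)

    member_color: dict[str, str] = {}
    for index, cluster in enumerate(drawn_clusters):
        for m in cluster.members:
            member_color[m] = _palette_color(index)

    for edge in net.edges:
        (x1, y1), (x2, y2) = net.positions[edge.source], net.positions[edge.target]
        ET.SubElement(layers["edges"], "line", {
            "class": "edge", "x1": f"{x1:g}", "y1": f"{y1:g}",
            "x2": f"{x2:g}", "y2": f"{y2:g}",
            "stroke": "#999999", "stroke-width": f"{EDGE_STROKE:g}",
        })

    for node in sorted(net.nodes):
        x, y = net.positions[node]
        is_group = bool(net.node_attrs.get(node, {}).get("is_group"))
        radius = GROUP_NODE_RADIUS if is_group else NODE_RADIUS
        circle = ET.SubElement(layers["nodes"], "circle", {
            "class": "group-node" if is_group else "node",
            "cx": f"{x:g}", "cy": f"{y:g}", "r": f"{radius:g}",
            "fill": member_color.get(node, "#d9d9d9"),
            "stroke": "#333333", "stroke-width": "1",
        })
        if is_group:
            # collapsed cluster drawn as a single node named by its label
            name = str(net.node_attrs[node].get("name", node))
            ET.SubElement(circle, "title").text = name
            text = ET.SubElement(layers["nodes"], "text", {
                "class": "node-name", "x": f"{x:g}",
                "y": f"{y - radius - 4:g}", "text-anchor": "middle",
                "font-size": "12",
            })
            text.text = name

    width, height = bounds[2] - bounds[0], bounds[3] - bounds[1]
    svg.set("viewBox", f"{bounds[0]:g} {bounds[1]:g} {width:g} {height:g}")
    svg.set("width", f"{width:g}")
    svg.set("height", f"{height:g}")

    document = ET.tostring(svg, encoding="unicode")
    if path is not None:
        with open(path, "w") as handle:
            handle.write(document)
    return document


def _draw_shape(layer, shape, color: str, display: DisplayOptions) -> None:
    common = {
        "class": "cluster-shape", "fill": color,
        "fill-opacity": f"{display.fill_opacity:g}",
        "stroke": "#333333", "stroke-width": f"{display.border_width:g}",
    }
    if shape.kind == "rectangle":
        ET.SubElement(layer, "rect", {
            **common, "x": f"{shape.x:g}", "y": f"{shape.y:g}",
            "width": f"{shape.w:g}", "height": f"{shape.h:g}",
        })
    else:
        # circumscribed ellipse of the padded box (passes through its corners)
        rx, ry = shape.w / 2 * math.sqrt(2), shape.h / 2 * math.sqrt(2)
        ET.SubElement(layer, "ellipse", {
            **common,
            "cx": f"{shape.x + shape.w / 2:g}", "cy": f"{shape.y + shape.h / 2:g}",
            "rx": f"{rx:g}", "ry": f"{ry:g}",
        })


def _draw_label(layer, label) -> None:
    text = ET.SubElement(layer, "text", {
        "class": "cluster-label",
        "x": f"{label.anchor_x:g}", "y": f"{label.anchor_y - 6:g}",
        "text-anchor": "middle", "font-size": f"{label.font_size:g}",
        "font-family": "sans-serif",
    })
    text.text = label.text
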