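"""Geometry resolution and figure export.

Turns a D3ARG + Layout + InteractionMap into a :class:`RenderDoc` — an
ordered list of primitives with resolved pixel coordinates and styles — and
serializes it to SVG 1.1 text, or to a self-contained HTML page in which
all hover behavior is driven purely by the precomputed data attributes (a
fixed class-toggling script; no graph logic runs in the page).

Two edge stylizations are supported.  The classic "orthogonal" format
routes each edge as a vertical riser at the child's x followed by a
horizontal shelf at the parent's y — the conventional depiction of full
ARGs with marked recombination nodes.  The "line" format connects parent
and child with a single straight segment and tolerates high-degree nodes.

Output is deterministic: identical inputs produce byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence
from xml.sax.saxutils import escape, quoteattr

from .local_trees import (InteractionMap, build_interaction_map,
                          classify_edges)
from .layout import ForceParams, Layout, Stub, force_layout, subgraph
from .model import ARGError, D3ARG, EdgeRecord, compute_breakpoints, to_json

__all__ = [
    "DrawOptions",
    "Element",
    "BarGeometry",
    "RenderDoc",
    "DrawResult",
    "route_edge",
    "bar_geometry",
    "mutation_fraction",
    "place_mutation",
    "build_render_doc",
    "render_svg",
    "render_html",
    "draw",
    "draw_node",
]

STUB_LENGTH = 0.04       # normalized length of dashed stub segments
MUTATION_MIN_SEP = 0.02  # minimum arc-fraction separation between glyphs
OUT_OF_TREE_DASH = "6,3"
STUB_DASH = "2,3"


@dataclass(frozen=True)
class DrawOptions:
    """Options of the draw pipeline (canvas defaults 750x520 px, 40 px margins)."""

    style: str = "orthogonal"          # "orthogonal" | "line"
    scale: str = "rank"                # time scale: "linear" | "log" | "rank"
    seed: int = 0
    iterations: int = 300
    focus_position: Optional[float] = None  # dash edges outside this local tree
    width: float = 750.0
    height: float = 520.0
    margin: float = 40.0
    bar_height: float = 25.0
    bar_gap: float = 15.0
    layout: Optional[Layout] = None    # reuse a saved layout instead of solving
    params: Optional[ForceParams] = None


@dataclass(frozen=True)
class Element:
    """One drawable primitive, traceable to its source table row."""

    kind: str                 # polyline | circle | rect | text
    source_type: str          # node | edge | stub | mutation | region
    source_id: int
    geometry: dict[str, Any]
    style: dict[str, Any] = field(default_factory=dict)
    classes: tuple[str, ...] = ()
    data: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class BarGeometry:
    """The chromosome bar: pixel span plus one rectangle per breakpoint region."""

    x: float
    y: float
    span: float
    height: float
    rects: tuple[tuple[int, float, float], ...]  # (region index, px left, px width)


@dataclass
class RenderDoc:
    width: float
    height: float
    margin: float
    elements: list[Element]
    bar: BarGeometry


@dataclass
class DrawResult:
    layout: Layout
    doc: RenderDoc
    outputs: dict[str, str]


# ---------------------------------------------------------------------------
# Routing and anchors (normalized coordinates)
# ---------------------------------------------------------------------------

Point = tuple[float, float]


def route_edge(edge: EdgeRecord, layout: Layout,
               style: str = "orthogonal") -> list[Point]:
    """Polyline for one edge, child end first, in normalized coordinates.

    Orthogonal: ``[(x_c, y_c), (x_c, y_p), (x_p, y_p)]`` — riser at the
    child's x, shelf at the parent's y; collapses to a single vertical
    segment when the endpoints share x.  Line: the straight 2-point segment.
    """
    if style not in ("orthogonal", "line"):
        raise ARGError(f"unknown edge stylization {style!r}")
    x_c, y_c = layout.coords[edge.child]
    x_p, y_p = layout.coords[edge.parent]
    if style == "line":
        return [(x_c, y_c), (x_p, y_p)]
    if x_c == x_p:
        return [(x_c, y_c), (x_p, y_p)]
    return [(x_c, y_c), (x_c, y_p), (x_p, y_p)]


def bar_geometry(arg: D3ARG, pixel_span: float, left: float = 0.0,
                 y: float = 0.0, height: float = 25.0) -> BarGeometry:
    """Chromosome-bar rectangles, widths proportional to genomic region lengths.

    Genome coordinate ``g`` maps to pixel ``left + (g / L) * pixel_span``;
    the region rectangles tile the bar exactly.
    """
    L = arg.genome_length
    rects = tuple(
        (b.index, left + (b.left / L) * pixel_span,
         ((b.right - b.left) / L) * pixel_span)
        for b in arg.breakpoints
    )
    return BarGeometry(x=left, y=y, span=pixel_span, height=height, rects=rects)


def mutation_fraction(t_child: float, t_parent: float,
                      t_mut: Optional[float]) -> float:
    """Arc fraction from the parent end: (t_parent - t_mut)/(t_parent - t_child).

    A mutation at the child's time maps to 1.0 (the child end); unknown
    mutation times default to the midpoint 0.5.
    """
    if t_mut is None or t_parent == t_child:
        return 0.5
    return (t_parent - t_mut) / (t_parent - t_child)


def place_mutation(polyline: Sequence[Point], fraction: float) -> Point:
    """Anchor point at arc-length ``fraction`` from the parent end.

    The polyline is ordered child -> parent, so the anchor sits at arc
    distance ``(1 - fraction) * total`` from the child end.
    """
    f = min(max(fraction, 0.0), 1.0)
    lengths = []
    for a, b in zip(polyline, polyline[1:]):
        lengths.append(((b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2) ** 0.5)
    total = sum(lengths)
    if total == 0.0:
        return polyline[0]
    target = (1.0 - f) * total
    acc = 0.0
    for (a, b), seg in zip(zip(polyline, polyline[1:]), lengths):
        if acc + seg >= target or (a, b) == (polyline[-2], polyline[-1]):
            w = 0.0 if seg == 0.0 else (target - acc) / seg
            w = min(max(w, 0.0), 1.0)
            return (a[0] + w * (b[0] - a[0]), a[1] + w * (b[1] - a[1]))
        acc += seg
    return polyline[-1]


def _spread_fractions(fractions: list[float]) -> list[float]:
    """Enforce the minimum glyph separation, preserving stable id order."""
    out = list(fractions)
    for i in range(1, len(out)):
        out[i] = max(out[i], out[i - 1] + MUTATION_MIN_SEP)
    for i in range(len(out) - 2, -1, -1):
        out[i] = min(out[i], out[i + 1] - MUTATION_MIN_SEP)
    return [min(max(f, 0.0), 1.0) for f in out]


# ---------------------------------------------------------------------------
# Document assembly
# ---------------------------------------------------------------------------

def _ids_csv(ids) -> str:
    return ",".join(str(i) for i in sorted(ids))


def build_render_doc(arg: D3ARG, layout: Layout,
                     interaction: Optional[InteractionMap] = None,
                     options: Optional[DrawOptions] = None,
                     stubs: Sequence[Stub] = ()) -> RenderDoc:
    """Resolve all geometry for one figure.

    Every edge yields exactly one polyline, every stub one short dashed
    polyline, every node one glyph, every mutation one glyph, and every
    breakpoint region one bar rectangle.
    """
    opts = options or DrawOptions()
    if interaction is None:
        interaction = build_interaction_map(arg)
    d = arg.defaults

    gx0 = opts.margin
    gx1 = opts.width - opts.margin
    gy0 = opts.margin
    gy1 = opts.height - opts.margin - opts.bar_height - opts.bar_gap

    def to_px(p: Point) -> Point:
        return (gx0 + p[0] * (gx1 - gx0), gy0 + p[1] * (gy1 - gy0))

    dashed_out: set[int] = set()
    if opts.focus_position is not None:
        _, dashed_out = classify_edges(arg, opts.focus_position)

    elements: list[Element] = []

    bar = bar_geometry(arg, pixel_span=gx1 - gx0, left=gx0,
                       y=opts.height - opts.margin - opts.bar_height,
                       height=opts.bar_height)
    for index, px, pw in bar.rects:
        elements.append(Element(
            kind="rect", source_type="region", source_id=index,
            geometry={"x": px, "y": bar.y, "w": pw, "h": bar.height},
            style={"fill": "#e8e8e8" if index % 2 == 0 else "#c9c9c9",
                   "stroke": "#888888", "width": 0.5},
            classes=("region",),
            data={"edges": _ids_csv(interaction.region_to_edges.get(index, ()))},
        ))

    nodes_by_id = arg.nodes_by_id()
    muts_by_id = {m.id: m for m in arg.mutations}
    mutation_anchor: dict[int, Point] = {}
    for e in sorted(arg.edges, key=lambda e: e.id):
        pts = route_edge(e, layout, opts.style)
        dash = e.style.dash if e.style.dash is not None else d.edge_dash
        if e.id in dashed_out:
            dash = OUT_OF_TREE_DASH
        mut_ids = interaction.edge_to_mutations.get(e.id, ())
        elements.append(Element(
            kind="polyline", source_type="edge", source_id=e.id,
            geometry={"points": [to_px(p) for p in pts]},
            style={"stroke": e.style.stroke or d.edge_stroke,
                   "width": e.style.width or d.edge_width,
                   "dash": dash},
            classes=("edge", "dashed") if e.id in dashed_out else ("edge",),
            data={"regions": _ids_csv(interaction.edge_to_regions.get(e.id, ())),
                  "nodes": f"{e.parent},{e.child}",
                  "mutations": _ids_csv(mut_ids)},
        ))
        if mut_ids:
            t_c = nodes_by_id[e.child].time
            t_p = nodes_by_id[e.parent].time
            ordered = sorted(mut_ids)
            fracs = _spread_fractions(
                [mutation_fraction(t_c, t_p, muts_by_id[m].time)
                 for m in ordered])
            for mid, f in zip(ordered, fracs):
                mutation_anchor[mid] = place_mutation(pts, f)

    for s in stubs:
        x, y = layout.coords[s.node]
        dy = -STUB_LENGTH if s.direction == "up" else STUB_LENGTH
        y2 = min(max(y + dy, 0.0), 1.0)
        elements.append(Element(
            kind="polyline", source_type="stub", source_id=s.edge,
            geometry={"points": [to_px((x, y)), to_px((x, y2))]},
            style={"stroke": d.edge_stroke, "width": d.edge_width,
                   "dash": STUB_DASH},
            classes=("edge", "stub"),
            data={"edge": str(s.edge), "excluded": str(s.excluded),
                  "direction": s.direction},
        ))

    for n in sorted(arg.nodes, key=lambda n: n.id):
        cx, cy = to_px(layout.coords[n.id])
        shape = n.style.shape or d.node_shape
        r = n.style.radius or d.node_radius
        style = {"fill": n.style.fill or d.node_fill,
                 "stroke": n.style.stroke or d.node_stroke}
        classes = ("node", "sample") if n.is_sample else ("node",)
        if shape == "square":
            elements.append(Element(
                kind="rect", source_type="node", source_id=n.id,
                geometry={"x": cx - r, "y": cy - r, "w": 2 * r, "h": 2 * r},
                style=style, classes=classes,
                data={"label": n.label, "time": repr(float(n.time))}))
        else:
            elements.append(Element(
                kind="circle", source_type="node", source_id=n.id,
                geometry={"cx": cx, "cy": cy, "r": r},
                style=style, classes=classes,
                data={"label": n.label, "time": repr(float(n.time))}))

    region_lefts = [b.left for b in arg.breakpoints]
    for m in sorted(arg.mutations, key=lambda m: m.id):
        anchor = mutation_anchor.get(m.id)
        if anchor is None:  # unresolvable mutations are never silently drawn
            raise ARGError(f"mutation {m.id} did not resolve to a drawn edge")
        ax, ay = to_px(anchor)
        side = 7.0
        region = 0
        for k in range(len(region_lefts) - 1, -1, -1):
            if region_lefts[k] <= m.position:
                region = k
                break
        elements.append(Element(
            kind="rect", source_type="mutation", source_id=m.id,
            geometry={"x": ax - side / 2, "y": ay - side / 2,
                      "w": side, "h": side},
            style={"fill": m.style.fill or d.mutation_fill,
                   "stroke": m.style.stroke or d.mutation_stroke},
            classes=("mutation",),
            data={"position": repr(float(m.position)), "region": str(region),
                  "label": m.label}))

    return RenderDoc(width=opts.width, height=opts.height, margin=opts.margin,
                     elements=elements, bar=bar)


# ---------------------------------------------------------------------------
# SVG serialization
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    s = f"{v:.3f}".rstrip("0").rstrip(".")
    return s if s != "-0" else "0"


def _attrs(pairs: list[tuple[str, str]]) -> str:
    return "".join(f" {k}={quoteattr(v)}" for k, v in pairs)


def _element_svg(el: Element) -> str:
    pairs: list[tuple[str, str]] = [
        ("id", f"{el.source_type}-{el.source_id}"),
        ("class", " ".join(el.classes)),
    ]
    g = el.geometry
    st = el.style
    if el.kind == "polyline":
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in g["points"])
        pairs += [("points", pts), ("fill", "none"),
                  ("stroke", st.get("stroke", "#000")),
                  ("stroke-width", _fmt(st.get("width", 1.0)))]
        if st.get("dash"):
            pairs.append(("stroke-dasharray", st["dash"]))
        tag = "polyline"
    elif el.kind == "circle":
        pairs += [("cx", _fmt(g["cx"])), ("cy", _fmt(g["cy"])),
                  ("r", _fmt(g["r"])), ("fill", st.get("fill", "#000")),
                  ("stroke", st.get("stroke", "none"))]
        tag = "circle"
    elif el.kind == "rect":
        pairs += [("x", _fmt(g["x"])), ("y", _fmt(g["y"])),
                  ("width", _fmt(g["w"])), ("height", _fmt(g["h"])),
                  ("fill", st.get("fill", "#000")),
                  ("stroke", st.get("stroke", "none"))]
        if "width" in st:
            pairs.append(("stroke-width", _fmt(st["width"])))
        tag = "rect"
    elif el.kind == "text":
        pairs += [("x", _fmt(g["x"])), ("y", _fmt(g["y"]))]
        body = escape(g.get("text", ""))
        pairs += sorted((f"data-{k}", v) for k, v in el.data.items())
        return f"<text{_attrs(pairs)}>{body}</text>"
    else:  # pragma: no cover - no other kinds are emitted
        raise ARGError(f"unknown element kind {el.kind!r}")
    pairs += sorted((f"data-{k}", v) for k, v in el.data.items())
    return f"<{tag}{_attrs(pairs)}/>"


SVG_STYLE = (
    ".hl{stroke:#c49e0a;stroke-width:4px;}"
    "rect.region.hl,rect.mutation.hl{stroke-width:2px;}"
)


def render_svg(doc: RenderDoc) -> str:
    """Serialize to SVG 1.1 text; identical documents yield identical bytes.

    Every element carries ``id="<source>-<row id>"`` plus data attributes —
    an edge lists the breakpoint regions it covers and its mutations, a bar
    region lists its local-tree edges — so the complete hover behavior is
    present as data even in the static file.
    """
    w, h = _fmt(doc.width), _fmt(doc.height)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w}" height="{h}" viewBox="0 0 {w} {h}">',
        f"<style>{SVG_STYLE}</style>",
        f'<rect x="0" y="0" width="{w}" height="{h}" fill="#ffffff"/>',
    ]
    lines += [_element_svg(el) for el in doc.elements]
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


HOVER_SCRIPT = """\
(function () {
  function ids(el, key) {
    var v = el.getAttribute('data-' + key);
    return v ? v.split(',') : [];
  }
  function toggle(sel, on) {
    document.querySelectorAll(sel).forEach(function (el) {
      el.classList.toggle('hl', on);
    });
  }
  function bind(el, handler) {
    el.addEventListener('mouseenter', function () { handler(true); });
    el.addEventListener('mouseleave', function () { handler(false); });
  }
  document.querySelectorAll('.region').forEach(function (el) {
    bind(el, function (on) {
      ids(el, 'edges').forEach(function (e) {
        toggle('#edge-' + e, on);
        var edge = document.getElementById('edge-' + e);
        if (edge) ids(edge, 'nodes').forEach(function (n) {
          toggle('#node-' + n, on);
        });
      });
    });
  });
  document.querySelectorAll('.edge:not(.stub)').forEach(function (el) {
    bind(el, function (on) {
      ids(el, 'regions').forEach(function (r) { toggle('#region-' + r, on); });
      ids(el, 'mutations').forEach(function (m) { toggle('#mutation-' + m, on); });
    });
  });
  document.querySelectorAll('.mutation').forEach(function (el) {
    bind(el, function (on) {
      toggle('#region-' + el.getAttribute('data-region'), on);
    });
  });
})();
"""


def render_html(doc: RenderDoc, interaction: Optional[InteractionMap] = None) -> str:
    """Self-contained HTML embedding the SVG byte-for-byte.

    When an interaction map is supplied the page also embeds a fixed static
    script that toggles highlight classes using the SVG's precomputed data
    attributes; no layout or tree computation happens in the page.  Without
    a map the page is the plain SVG, no script.
    """
    svg = render_svg(doc)
    script = (f"<script>\n{HOVER_SCRIPT}</script>\n"
              if interaction is not None else "")
    return ("<!DOCTYPE html>\n<html>\n<head>\n"
            '<meta charset="utf-8"/>\n<title>ARG figure</title>\n'
            "</head>\n<body>\n" + svg + script + "</body>\n</html>\n")


# ---------------------------------------------------------------------------
# Top-level pipelines
# ---------------------------------------------------------------------------

def _pipeline(arg: D3ARG, opts: DrawOptions,
              stubs: Sequence[Stub] = ()) -> DrawResult:
    if not arg.breakpoints:
        arg.breakpoints = compute_breakpoints(arg)
    interaction = build_interaction_map(arg)
    layout = opts.layout
    if layout is None:
        layout = force_layout(arg, scale=opts.scale, seed=opts.seed,
                              iterations=opts.iterations, params=opts.params)
    doc = build_render_doc(arg, layout, interaction, opts, stubs=stubs)
    outputs = {
        "svg": render_svg(doc),
        "html": render_html(doc, interaction),
        "json": to_json(arg, layout, interaction),
    }
    return DrawResult(layout=layout, doc=doc, outputs=outputs)


def draw(arg: D3ARG, options: Optional[DrawOptions] = None) -> DrawResult:
    """Draw the full graph: breakpoints -> interaction map -> layout -> render."""
    return _pipeline(arg, options or DrawOptions())


def draw_node(arg: D3ARG, focal: int, degree: int = 2,
              options: Optional[DrawOptions] = None) -> DrawResult:
    """Filter to the ``degree``-hop subgraph around ``focal``, then draw it.

    Connections to the excluded remainder of the graph are rendered as short
    dashed stubs pointing up for excluded parents and down for excluded
    children.
    """
    sg = subgraph(arg, focal, degree)
    return _pipeline(sg.arg, options or DrawOptions(), stubs=sg.stubs)
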