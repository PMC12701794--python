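"""Tabular ARG data model.

An ancestral recombination graph (ARG) is held as a collection of tables —
nodes, edges, mutations and breakpoints — plus the genome extent and style
defaults.  The representation mirrors the succinct tree-sequence tabular
format but is figure-oriented: a single edge record may carry several
disjoint genomic intervals (a tree sequence stores one row per contiguous
interval), and every row carries optional styling used by the renderer.

Genomic coordinates are 0-based half-open real intervals ``[left, right)``
over the genome extent ``[0, genome_length)``, the tree-sequence convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence

__all__ = [
    "ARGError",
    "SchemaError",
    "ConversionError",
    "NodeStyle",
    "EdgeStyle",
    "MutationStyle",
    "StyleDefaults",
    "NodeRecord",
    "EdgeRecord",
    "MutationRecord",
    "BreakpointRecord",
    "D3ARG",
    "Violation",
    "validate",
    "compute_breakpoints",
    "from_ts_tables",
    "from_tree_sequence",
    "to_json",
    "from_json",
    "set_styles",
    "write_tsv_dump",
    "read_tsv_dump",
    "merge_intervals",
]

SCHEMA_VERSION = "1"


class ARGError(Exception):
    """Base class for data errors in this package."""


class SchemaError(ARGError):
    """A serialized document does not conform to the figure-JSON dialect."""


class ConversionError(ARGError):
    """Input tables cannot be converted into a valid ARG."""


# ---------------------------------------------------------------------------
# Styles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeStyle:
    fill: Optional[str] = None
    stroke: Optional[str] = None
    radius: Optional[float] = None
    shape: Optional[str] = None  # "circle" or "square"


@dataclass(frozen=True)
class EdgeStyle:
    stroke: Optional[str] = None
    width: Optional[float] = None
    dash: Optional[str] = None  # SVG stroke-dasharray, "" = solid


@dataclass(frozen=True)
class MutationStyle:
    fill: Optional[str] = None
    stroke: Optional[str] = None


@dataclass(frozen=True)
class StyleDefaults:
    """Fallback styling applied where a row's own style field is unset."""

    node_fill: str = "#1f77b4"
    node_stroke: str = "#053e4e"
    node_radius: float = 5.0
    node_shape: str = "circle"
    edge_stroke: str = "#053e4e"
    edge_width: float = 2.0
    edge_dash: str = ""
    mutation_fill: str = "#d62728"
    mutation_stroke: str = "#053e4e"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

Interval = tuple[float, float]


@dataclass(frozen=True)
class NodeRecord:
    id: int
    time: float
    is_sample: bool = False
    label: str = ""
    pinned_x: Optional[float] = None  # manual drag override, normalized [0, 1]
    style: NodeStyle = field(default_factory=NodeStyle)


@dataclass(frozen=True)
class EdgeRecord:
    """Parent-child link carrying an ordered list of disjoint half-open intervals."""

    id: int
    parent: int
    child: int
    intervals: tuple[Interval, ...]
    style: EdgeStyle = field(default_factory=EdgeStyle)

    @property
    def covered_length(self) -> float:
        return sum(r - l for l, r in self.intervals)


@dataclass(frozen=True)
class MutationRecord:
    """Mutation anchored by (node, position); the owning edge is resolved, not stored."""

    id: int
    node: int
    position: float
    time: Optional[float] = None
    label: str = ""
    style: MutationStyle = field(default_factory=MutationStyle)


@dataclass(frozen=True)
class BreakpointRecord:
    index: int
    left: float
    right: float


@dataclass
class D3ARG:
    """The full tabular ARG: node/edge/mutation/breakpoint tables + extent."""

    nodes: list[NodeRecord]
    edges: list[EdgeRecord]
    mutations: list[MutationRecord]
    breakpoints: list[BreakpointRecord]
    genome_length: float
    defaults: StyleDefaults = field(default_factory=StyleDefaults)

    # -- convenience indexes (rebuilt on demand; records are immutable) ----

    def nodes_by_id(self) -> dict[int, NodeRecord]:
        return {n.id: n for n in self.nodes}

    def edges_by_id(self) -> dict[int, EdgeRecord]:
        return {e.id: e for e in self.edges}

    def parent_edges_of(self, node_id: int) -> list[EdgeRecord]:
        """Edges in which ``node_id`` is the child (its links to parents)."""
        return [e for e in self.edges if e.child == node_id]

    def child_edges_of(self, node_id: int) -> list[EdgeRecord]:
        return [e for e in self.edges if e.parent == node_id]

    def sample_ids(self) -> list[int]:
        return sorted(n.id for n in self.nodes if n.is_sample)

    def recombination_node_ids(self) -> list[int]:
        """Nodes with >= 2 parent edges, the structural recombination criterion."""
        counts: dict[int, int] = {}
        for e in self.edges:
            counts[e.child] = counts.get(e.child, 0) + 1
        return sorted(k for k, v in counts.items() if v >= 2)


# ---------------------------------------------------------------------------
# Interval helpers
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Sort and coalesce intervals, merging overlapping *and* adjacent ones.

    The result is the canonical interval list for an edge: sorted by left,
    pairwise disjoint, no two touching.
    """
    ivs = sorted(intervals)
    merged: list[list[float]] = []
    for l, r in ivs:
        if merged and l <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], r)
        else:
            merged.append([l, r])
    return tuple((l, r) for l, r in merged)


def _intervals_disjoint(a: Sequence[Interval], b: Sequence[Interval]) -> bool:
    """True if no interval of ``a`` overlaps an interval of ``b`` (half-open)."""
    i = j = 0
    while i < len(a) and j < len(b):
        al, ar = a[i]
        bl, br = b[j]
        if ar <= bl:
            i += 1
        elif br <= al:
            j += 1
        else:
            return False
    return True


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One broken invariant; violations are data, not exceptions."""

    table: str
    row: Optional[int]
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.table}:{self.row}] {self.rule}: {self.message}"


def validate(arg: D3ARG) -> list[Violation]:
    """Check every model invariant; return the (possibly empty) violation list."""
    out: list[Violation] = []
    L = arg.genome_length
    if not (L > 0):
        out.append(Violation("arg", None, "genome-length-positive",
                             f"genome_length must be > 0, got {L}"))
        return out

    seen_nodes: set[int] = set()
    for n in arg.nodes:
        if n.id in seen_nodes:
            out.append(Violation("nodes", n.id, "unique-id", "duplicate node id"))
        seen_nodes.add(n.id)
        if n.time < 0:
            out.append(Violation("nodes", n.id, "nonnegative-time",
                                 f"time {n.time} < 0"))
        if n.pinned_x is not None and not (0.0 <= n.pinned_x <= 1.0):
            out.append(Violation("nodes", n.id, "pinned-x-range",
                                 f"pinned_x {n.pinned_x} outside [0, 1]"))
    node_time = {n.id: n.time for n in arg.nodes}

    seen_edges: set[int] = set()
    seen_pairs: dict[tuple[int, int], int] = {}
    for e in arg.edges:
        if e.id in seen_edges:
            out.append(Violation("edges", e.id, "unique-id", "duplicate edge id"))
        seen_edges.add(e.id)
        for endpoint, role in ((e.parent, "parent"), (e.child, "child")):
            if endpoint not in node_time:
                out.append(Violation("edges", e.id, "dangling-node-ref",
                                     f"{role} node {endpoint} does not exist"))
        if e.parent in node_time and e.child in node_time:
            if not node_time[e.parent] > node_time[e.child]:
                out.append(Violation(
                    "edges", e.id, "strict-time-order",
                    f"time(parent {e.parent})={node_time[e.parent]} must exceed "
                    f"time(child {e.child})={node_time[e.child]}"))
        pair = (e.parent, e.child)
        if pair in seen_pairs:
            out.append(Violation("edges", e.id, "duplicate-parent-child-pair",
                                 f"pair {pair} already used by edge {seen_pairs[pair]}"))
        else:
            seen_pairs[pair] = e.id
        if not e.intervals:
            out.append(Violation("edges", e.id, "nonempty-intervals",
                                 "edge has no intervals"))
        prev_right: Optional[float] = None
        for l, r in e.intervals:
            if not l < r:
                out.append(Violation("edges", e.id, "interval-order",
                                     f"interval ({l}, {r}) has left >= right"))
            if l < 0 or r > L:
                out.append(Violation("edges", e.id, "interval-in-genome",
                                     f"interval ({l}, {r}) outside [0, {L})"))
            if prev_right is not None:
                if l < prev_right:
                    out.append(Violation("edges", e.id, "intervals-disjoint-sorted",
                                         f"interval ({l}, {r}) overlaps or precedes "
                                         f"previous (right={prev_right})"))
                elif l == prev_right:
                    out.append(Violation("edges", e.id, "intervals-not-adjacent",
                                         f"interval starting at {l} touches previous; "
                                         "adjacent intervals must be merged"))
            prev_right = r

    # Per-position forest: a node's parent edges must never overlap genomically.
    by_child: dict[int, list[EdgeRecord]] = {}
    for e in arg.edges:
        by_child.setdefault(e.child, []).append(e)
    for child, pes in sorted(by_child.items()):
        pes = sorted(pes, key=lambda e: e.id)
        for i in range(len(pes)):
            for j in range(i + 1, len(pes)):
                if not _intervals_disjoint(pes[i].intervals, pes[j].intervals):
                    out.append(Violation(
                        "edges", pes[j].id, "forest-at-position",
                        f"node {child} has overlapping parent edges "
                        f"{pes[i].id} and {pes[j].id}"))

    seen_muts: set[int] = set()
    for m in arg.mutations:
        if m.id in seen_muts:
            out.append(Violation("mutations", m.id, "unique-id",
                                 "duplicate mutation id"))
        seen_muts.add(m.id)
        if m.node not in node_time:
            out.append(Violation("mutations", m.id, "dangling-node-ref",
                                 f"node {m.node} does not exist"))
            continue
        if not (0 <= m.position < L):
            out.append(Violation("mutations", m.id, "position-in-genome",
                                 f"position {m.position} outside [0, {L})"))
            continue
        owners = [e for e in by_child.get(m.node, [])
                  if any(l <= m.position < r for l, r in e.intervals)]
        if len(owners) != 1:
            out.append(Violation(
                "mutations", m.id, "resolvable-to-one-edge",
                f"{len(owners)} parent edges of node {m.node} span "
                f"position {m.position}; need exactly 1"))
        elif m.time is not None:
            e = owners[0]
            lo, hi = node_time[e.child], node_time[e.parent]
            if not (lo <= m.time <= hi):
                out.append(Violation(
                    "mutations", m.id, "time-within-branch",
                    f"time {m.time} outside [{lo}, {hi}] of edge {e.id}"))

    expected = compute_breakpoints(arg)
    got = [(b.left, b.right) for b in arg.breakpoints]
    want = [(b.left, b.right) for b in expected]
    if got != want:
        out.append(Violation("breakpoints", None, "breakpoints-consistent",
                             f"stored regions {got} != recomputed {want}"))
    else:
        for k, b in enumerate(arg.breakpoints):
            if b.index != k:
                out.append(Violation("breakpoints", b.index, "index-rank",
                                     f"record at rank {k} has index {b.index}"))
    return out


# ---------------------------------------------------------------------------
# Breakpoints
# ---------------------------------------------------------------------------

def compute_breakpoints(arg: D3ARG) -> list[BreakpointRecord]:
    """Recompute the breakpoint-region table from the edge intervals.

    Region boundaries are exactly the sorted distinct interval endpoints of
    all edges, together with 0 and the genome length; consecutive boundaries
    delimit the regions, which tile ``[0, genome_length)``.  Within a region
    the set of edges spanning any position is constant (no edge endpoint
    falls in a region interior), and across a boundary it always changes,
    because an edge whose intervals were coalesced cannot both end and
    restart at the same point.
    """
    pts = {0.0, float(arg.genome_length)}
    for e in arg.edges:
        for l, r in e.intervals:
            if 0.0 < l < arg.genome_length:
                pts.add(float(l))
            if 0.0 < r < arg.genome_length:
                pts.add(float(r))
    bounds = sorted(pts)
    return [BreakpointRecord(index=i, left=bounds[i], right=bounds[i + 1])
            for i in range(len(bounds) - 1)]


# ---------------------------------------------------------------------------
# Conversion from per-interval (tree-sequence style) tables
# ---------------------------------------------------------------------------

def _rows(table: Any) -> list[Mapping[str, Any]]:
    """Accept a pandas DataFrame or any iterable of mappings."""
    if table is None:
        return []
    if hasattr(table, "to_dict") and hasattr(table, "columns"):
        return table.to_dict("records")
    return list(table)


def from_ts_tables(
    node_rows: Any,
    edge_rows: Any,
    site_rows: Any = None,
    mutation_rows: Any = None,
    genome_length: Optional[float] = None,
) -> D3ARG:
    """Build a D3ARG from tree-sequence-style per-interval tables.

    ``node_rows``: mappings with ``id``, ``time``, ``is_sample`` (+ optional
    ``label``).  ``edge_rows``: one row per contiguous inherited interval with
    ``parent``, ``child``, ``left``, ``right``.  Rows sharing (parent, child)
    are merged into a single edge whose interval list is the coalesced union,
    so total covered length per pair is conserved.  ``site_rows`` (``id``,
    ``position``) and ``mutation_rows`` (``site`` or ``position``, ``node``,
    optional ``time``/``label``) become mutation records anchored by
    (node, position).

    Tables may be pandas DataFrames or iterables of dicts.  The conversion is
    a single pass per table plus one sort of the merged edges, so it handles
    very large inputs.
    """
    nrows = _rows(node_rows)
    nodes = []
    for i, row in enumerate(nrows):
        if "id" not in row or "time" not in row:
            raise ConversionError(f"node row {i}: needs 'id' and 'time'")
        nodes.append(NodeRecord(
            id=int(row["id"]),
            time=float(row["time"]),
            is_sample=bool(row.get("is_sample", False)),
            label=str(row.get("label", "") or ""),
        ))
    node_time = {n.id: n.time for n in nodes}
    if genome_length is None:
        raise ConversionError("genome_length is required")
    L = float(genome_length)

    groups: dict[tuple[int, int], list[Interval]] = {}
    for i, row in enumerate(_rows(edge_rows)):
        p, c = int(row["parent"]), int(row["child"])
        l, r = float(row["left"]), float(row["right"])
        for endpoint, role in ((p, "parent"), (c, "child")):
            if endpoint not in node_time:
                raise ConversionError(
                    f"edge row {i}: unknown {role} node {endpoint}")
        if not (0.0 <= l < r <= L):
            raise ConversionError(
                f"edge row {i}: interval ({l}, {r}) outside [0, {L})")
        if not node_time[p] > node_time[c]:
            raise ConversionError(
                f"edge row {i}: parent {p} (t={node_time[p]}) not older "
                f"than child {c} (t={node_time[c]})")
        groups.setdefault((p, c), []).append((l, r))

    merged = [(p, c, merge_intervals(ivs)) for (p, c), ivs in groups.items()]
    # Deterministic ids independent of input row order: youngest parents first.
    merged.sort(key=lambda t: (node_time[t[0]], t[0], t[1]))
    edges = [EdgeRecord(id=i, parent=p, child=c, intervals=ivs)
             for i, (p, c, ivs) in enumerate(merged)]

    site_pos: dict[int, float] = {}
    for i, row in enumerate(_rows(site_rows)):
        site_pos[int(row["id"])] = float(row["position"])
    mutations = []
    for i, row in enumerate(_rows(mutation_rows)):
        node = int(row["node"])
        if node not in node_time:
            raise ConversionError(f"mutation row {i}: unknown node {node}")
        if "position" in row and row["position"] is not None:
            pos = float(row["position"])
        else:
            site = int(row["site"])
            if site not in site_pos:
                raise ConversionError(f"mutation row {i}: unknown site {site}")
            pos = site_pos[site]
        if not (0.0 <= pos < L):
            raise ConversionError(
                f"mutation row {i}: position {pos} outside [0, {L})")
        t = row.get("time")
        if t is not None:
            t = float(t)
            if math.isnan(t):
                t = None
        mutations.append(MutationRecord(
            id=int(row.get("id", i)), node=node, position=pos, time=t,
            label=str(row.get("label", "") or "")))
    mutations.sort(key=lambda m: m.id)

    arg = D3ARG(nodes=sorted(nodes, key=lambda n: n.id), edges=edges,
                mutations=mutations, breakpoints=[], genome_length=L)
    arg.breakpoints = compute_breakpoints(arg)
    return arg


def from_tree_sequence(ts: Any) -> D3ARG:
    """Convert a ``tskit.TreeSequence`` (or path to one) into a D3ARG."""
    if isinstance(ts, (str, Path)):
        import tskit
        ts = tskit.load(str(ts))
    tables = ts.tables
    node_rows = [
        {"id": i, "time": float(t), "is_sample": bool(f & 1)}
        for i, (t, f) in enumerate(zip(tables.nodes.time, tables.nodes.flags))
    ]
    edge_rows = [
        {"parent": int(p), "child": int(c), "left": float(l), "right": float(r)}
        for p, c, l, r in zip(tables.edges.parent, tables.edges.child,
                              tables.edges.left, tables.edges.right)
    ]
    site_rows = [{"id": i, "position": float(p)}
                 for i, p in enumerate(tables.sites.position)]
    mutation_rows = []
    for i, mut in enumerate(ts.mutations()):
        t = None if mut.time is None or math.isnan(mut.time) else float(mut.time)
        mutation_rows.append({
            "id": i, "site": int(mut.site), "node": int(mut.node),
            "time": t, "label": mut.derived_state,
        })
    return from_ts_tables(node_rows, edge_rows, site_rows, mutation_rows,
                          genome_length=float(ts.sequence_length))


# ---------------------------------------------------------------------------
# Figure JSON (schema_version "1")
# ---------------------------------------------------------------------------

def _style_dict(style: Any) -> dict[str, Any]:
    return {k: getattr(style, k) for k in style.__dataclass_fields__}


def to_json(arg: D3ARG, layout: Any = None, interaction: Any = None) -> str:
    """Serialize to the canonical figure-JSON text.

    Canonical means: sorted object keys, rows sorted by id, compact
    separators, full-precision floats — so serializing twice yields
    byte-identical text and the round trip is exact.
    """
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "genome_length": float(arg.genome_length),
        "defaults": _style_dict(arg.defaults),
        "nodes": [
            {"id": n.id, "time": n.time, "is_sample": n.is_sample,
             "label": n.label, "pinned_x": n.pinned_x,
             "style": _style_dict(n.style)}
            for n in sorted(arg.nodes, key=lambda n: n.id)
        ],
        "edges": [
            {"id": e.id, "parent": e.parent, "child": e.child,
             "intervals": [[l, r] for l, r in e.intervals],
             "style": _style_dict(e.style)}
            for e in sorted(arg.edges, key=lambda e: e.id)
        ],
        "mutations": [
            {"id": m.id, "node": m.node, "position": m.position,
             "time": m.time, "label": m.label, "style": _style_dict(m.style)}
            for m in sorted(arg.mutations, key=lambda m: m.id)
        ],
        "breakpoints": [
            {"index": b.index, "left": b.left, "right": b.right}
            for b in arg.breakpoints
        ],
        "layout": None,
    }
    if layout is not None:
        doc["layout"] = {
            "scale": layout.scale,
            "seed": layout.seed,
            "iterations": layout.iterations,
            "coords": [{"id": i, "x": x, "y": y}
                       for i, (x, y) in sorted(layout.coords.items())],
        }
    if interaction is not None:
        doc["interaction"] = interaction.to_dict()
    return json.dumps(doc, sort_keys=True, separators=(",", ":"),
                      allow_nan=False)


def _require(obj: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in obj:
        raise SchemaError(f"missing required field at {path}.{key}")
    return obj[key]


def _load_style(d: Optional[Mapping[str, Any]], cls: type, path: str) -> Any:
    if d is None:
        return cls()
    try:
        return cls(**dict(d))
    except TypeError as exc:
        raise SchemaError(f"bad style object at {path}: {exc}") from None


def from_json(text: str) -> tuple[D3ARG, Any]:
    """Parse figure JSON back into ``(D3ARG, Layout or None)``.

    Raises :class:`SchemaError` naming the offending field path for malformed
    documents, unknown schema versions, and dangling references.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON document: {exc}") from None
    if not isinstance(doc, dict):
        raise SchemaError("top level must be an object")
    version = _require(doc, "schema_version", "$")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unknown schema_version {version!r} at $.schema_version")
    L = float(_require(doc, "genome_length", "$"))

    defaults = _load_style(doc.get("defaults"), StyleDefaults, "$.defaults")

    nodes = []
    for i, row in enumerate(_require(doc, "nodes", "$")):
        path = f"$.nodes[{i}]"
        nodes.append(NodeRecord(
            id=int(_require(row, "id", path)),
            time=float(_require(row, "time", path)),
            is_sample=bool(row.get("is_sample", False)),
            label=str(row.get("label", "")),
            pinned_x=row.get("pinned_x"),
            style=_load_style(row.get("style"), NodeStyle, path),
        ))
    node_ids = {n.id for n in nodes}

    edges = []
    for i, row in enumerate(_require(doc, "edges", "$")):
        path = f"$.edges[{i}]"
        parent = int(_require(row, "parent", path))
        child = int(_require(row, "child", path))
        if parent not in node_ids:
            raise SchemaError(f"dangling node reference at {path}.parent: {parent}")
        if child not in node_ids:
            raise SchemaError(f"dangling node reference at {path}.child: {child}")
        ivs = _require(row, "intervals", path)
        edges.append(EdgeRecord(
            id=int(_require(row, "id", path)), parent=parent, child=child,
            intervals=tuple((float(l), float(r)) for l, r in ivs),
            style=_load_style(row.get("style"), EdgeStyle, path),
        ))
    edge_count = len(edges)

    mutations = []
    for i, row in enumerate(doc.get("mutations", [])):
        path = f"$.mutations[{i}]"
        node = int(_require(row, "node", path))
        if node not in node_ids:
            raise SchemaError(f"dangling node reference at {path}.node: {node}")
        t = row.get("time")
        mutations.append(MutationRecord(
            id=int(_require(row, "id", path)), node=node,
            position=float(_require(row, "position", path)),
            time=None if t is None else float(t),
            label=str(row.get("label", "")),
            style=_load_style(row.get("style"), MutationStyle, path),
        ))

    breakpoints = [
        BreakpointRecord(index=int(row["index"]), left=float(row["left"]),
                         right=float(row["right"]))
        for row in doc.get("breakpoints", [])
    ]

    arg = D3ARG(nodes=nodes, edges=edges, mutations=mutations,
                breakpoints=breakpoints, genome_length=L, defaults=defaults)
    if not arg.breakpoints:
        arg.breakpoints = compute_breakpoints(arg)

    layout = None
    lay = doc.get("layout")
    if lay is not None:
        from .layout import Layout  # local import avoids a module cycle
        coords = {}
        for i, row in enumerate(_require(lay, "coords", "$.layout")):
            nid = int(row["id"])
            if nid not in node_ids:
                raise SchemaError(
                    f"dangling node reference at $.layout.coords[{i}].id: {nid}")
            coords[nid] = (float(row["x"]), float(row["y"]))
        layout = Layout(coords=coords,
                        scale=str(_require(lay, "scale", "$.layout")),
                        seed=int(_require(lay, "seed", "$.layout")),
                        iterations=int(_require(lay, "iterations", "$.layout")))
    del edge_count
    return arg, layout


# ---------------------------------------------------------------------------
# Styling
# ---------------------------------------------------------------------------

_STYLE_KINDS = {
    "nodes": (NodeStyle, {"radius"}),
    "edges": (EdgeStyle, {"width"}),
    "mutations": (MutationStyle, set()),
}


def set_styles(arg: D3ARG, selector: Mapping[str, Iterable[int]],
               style_patch: Mapping[str, Any]) -> D3ARG:
    """Return a copy of ``arg`` with styles patched on the addressed rows.

    ``selector`` maps table names ("nodes", "edges", "mutations") to ids;
    ``style_patch`` maps style field names to new values.  Only addressed
    rows change and only their style field.  Unknown ids raise, listing them.
    """
    unknown_tables = set(selector) - set(_STYLE_KINDS)
    if unknown_tables:
        raise ARGError(f"unknown tables in selector: {sorted(unknown_tables)}")

    new = replace_tables(arg)
    for table, ids in selector.items():
        ids = set(int(i) for i in ids)
        if not ids:
            continue
        cls, numeric = _STYLE_KINDS[table]
        fields = set(cls.__dataclass_fields__)
        bad = set(style_patch) - fields
        applicable = {k: v for k, v in style_patch.items() if k in fields}
        if bad and not applicable:
            raise ARGError(f"style fields {sorted(bad)} do not apply to {table}")
        for k, v in applicable.items():
            if k in numeric:
                if not isinstance(v, (int, float)) or v <= 0:
                    raise ARGError(f"style field {k!r} must be a positive "
                                   f"number, got {v!r}")
            elif v is not None and not isinstance(v, str):
                raise ARGError(f"style field {k!r} must be a string, got {v!r}")
        rows = {"nodes": new.nodes, "edges": new.edges,
                "mutations": new.mutations}[table]
        present = {r.id for r in rows}
        missing = ids - present
        if missing:
            raise ARGError(f"unknown {table} ids in selector: {sorted(missing)}")
        for i, row in enumerate(rows):
            if row.id in ids:
                rows[i] = replace(row, style=replace(row.style, **applicable))
    return new


def replace_tables(arg: D3ARG) -> D3ARG:
    """Shallow structural copy (records are frozen, so lists suffice)."""
    return D3ARG(nodes=list(arg.nodes), edges=list(arg.edges),
                 mutations=list(arg.mutations),
                 breakpoints=list(arg.breakpoints),
                 genome_length=arg.genome_length, defaults=arg.defaults)


# ---------------------------------------------------------------------------
# Portable TSV dump dialect
# ---------------------------------------------------------------------------

def write_tsv_dump(arg: D3ARG, directory: str | Path) -> None:
    """Write the portable tab-separated dump: one file per table.

    Edge intervals are written one row per interval (the tree-sequence
    convention); reading merges them back.  ``arg.tsv`` holds the genome
    extent.  Styling is not dumped — the TSV dialect carries topology only;
    use figure JSON to preserve styles.
    """
    import pandas as pd

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{"genome_length": arg.genome_length}]).to_csv(
        d / "arg.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame([
        {"id": n.id, "time": n.time, "is_sample": int(n.is_sample),
         "label": n.label}
        for n in sorted(arg.nodes, key=lambda n: n.id)
    ]).to_csv(d / "nodes.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame([
        {"parent": e.parent, "child": e.child, "left": l, "right": r}
        for e in sorted(arg.edges, key=lambda e: e.id)
        for l, r in e.intervals
    ]).to_csv(d / "edges.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame([
        {"id": m.id, "node": m.node, "position": m.position,
         "time": "" if m.time is None else m.time, "label": m.label}
        for m in sorted(arg.mutations, key=lambda m: m.id)
    ], columns=["id", "node", "position", "time", "label"]).to_csv(
        d / "mutations.tsv", sep="\t", index=False, float_format="%.17g")


def read_tsv_dump(directory: str | Path) -> D3ARG:
    """Read a dump written by :func:`write_tsv_dump` (or built by hand)."""
    import pandas as pd

    d = Path(directory)
    meta = pd.read_csv(d / "arg.tsv", sep="\t", float_precision="round_trip")
    L = float(meta["genome_length"].iloc[0])
    nodes = pd.read_csv(d / "nodes.tsv", sep="\t", dtype={"label": str},
                        keep_default_na=False, float_precision="round_trip")
    nodes["label"] = nodes.get("label", "")
    edges = pd.read_csv(d / "edges.tsv", sep="\t", float_precision="round_trip")
    mut_path = d / "mutations.tsv"
    muts = None
    if mut_path.exists():
        mm = pd.read_csv(mut_path, sep="\t", dtype={"label": str},
                         keep_default_na=False, float_precision="round_trip")
        muts = [
            {"id": int(r["id"]), "node": int(r["node"]),
             "position": float(r["position"]),
             "time": None if str(r.get("time", "")).strip() == ""
             else float(r["time"]),
             "label": r.get("label", "")}
            for r in mm.to_dict("records")
        ]
    return from_ts_tables(nodes, edges, None, muts, genome_length=L)
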