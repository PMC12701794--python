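"""Node positioning.

The vertical coordinate encodes node age and is never touched by the
untangling simulation: y is a pure function of node time under one of three
scales (linear, log, rank), with y = 0 the top of the canvas (oldest node)
and y = 1 the bottom (youngest).  Only the horizontal coordinate is relaxed,
by a small custom force-directed simulation in which edges act as springs
and nodes at similar heights repel — restricting repulsion to near-equal
heights is what keeps the fixed-y layout from spreading without bound.

Everything here is deterministic: iteration order is fixed (nodes sorted by
id), exact x-ties are broken by a jitter derived from the ordered id pair
and the seed, and repeated calls with identical inputs produce bit-identical
layouts.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import (ARGError, D3ARG, EdgeRecord, compute_breakpoints,
                    replace_tables)

__all__ = [
    "Layout",
    "ForceParams",
    "Subgraph",
    "Stub",
    "time_to_y",
    "initial_x",
    "force_layout",
    "count_crossings",
    "segments_for_style",
    "pin_x",
    "subgraph",
]

SCALES = ("linear", "log", "rank")


@dataclass(frozen=True)
class Layout:
    """Per-node normalized coordinates plus the recipe that produced them.

    ``coords`` maps node id to (x, y) in [0, 1] x [0, 1].  The scale, seed
    and iteration budget are carried (and serialized into figure JSON) so a
    saved figure re-renders identically.
    """

    coords: dict[int, tuple[float, float]]
    scale: str
    seed: int
    iterations: int


@dataclass(frozen=True)
class ForceParams:
    """Constants of the untangling simulation.

    spring: per-edge stiffness pulling endpoint x positions together.
    repulsion: 1-D repulsion strength between near-equal-height node pairs.
    y_window: |dy| below which two nodes repel.
    epsilon: softening constant in the repulsion denominator.
    alpha_start/alpha_end: geometric cooling of the step size over the
    iteration budget.
    """

    spring: float = 0.06
    repulsion: float = 0.002
    y_window: float = 0.08
    epsilon: float = 1e-4
    alpha_start: float = 1.0
    alpha_end: float = 0.001
    # The force equilibrium is not a crossing minimum, so the relaxed state
    # can occasionally cross more than the tree-informed initial placement.
    # The guard compares straight-segment crossings of the final vs initial
    # configuration and keeps the better one (ties prefer the relaxed
    # state), making "relaxation never tangles further" a contract rather
    # than a tendency.  Exact counting is quadratic, so the guard only runs
    # up to ``guard_max_edges`` edges.
    untangle_guard: bool = True
    guard_max_edges: int = 1000


# ---------------------------------------------------------------------------
# Time -> y
# ---------------------------------------------------------------------------

def time_to_y(times: Sequence[float], scale: str = "rank") -> list[float]:
    """Map node times to normalized y with the oldest at 0, youngest at 1.

    linear: affine in time; log: affine in log(1 + t) so t = 0 samples are
    admitted; rank: distinct times, sorted ascending, get equally spaced y
    from 1 down to 0 (the nonlinear, ranked timescale that spaces nodes
    efficiently when times span orders of magnitude).  Equal times always
    map to equal y.  If all times coincide every node sits at y = 0.5.
    """
    if scale not in SCALES:
        raise ARGError(f"unknown time scale {scale!r}; expected one of {SCALES}")
    times = list(times)
    if not times:
        return []
    if min(times) < 0:
        raise ARGError("node times must be non-negative")
    t_min, t_max = min(times), max(times)
    if t_min == t_max:
        return [0.5] * len(times)
    if scale == "linear":
        return [1.0 - (t - t_min) / (t_max - t_min) for t in times]
    if scale == "log":
        lo, hi = np.log1p(t_min), np.log1p(t_max)
        return [float(1.0 - (np.log1p(t) - lo) / (hi - lo)) for t in times]
    distinct = sorted(set(times))
    rank = {t: i for i, t in enumerate(distinct)}
    top = len(distinct) - 1
    return [1.0 - rank[t] / top for t in times]


# ---------------------------------------------------------------------------
# Initial x
# ---------------------------------------------------------------------------

def initial_x(arg: D3ARG) -> dict[int, float]:
    """Deterministic starting x positions, independent of table row order.

    Samples are spread equally across [0, 1] in id order.  Each internal
    node starts at the mean x of its children in the leftmost local tree
    (the tree at position 0); a node that is not a parent in that tree falls
    back to the mean over all its graph children, and a childless non-sample
    node to 0.5.  Processing nodes young-to-old guarantees children are
    placed before their parents.
    """
    samples = arg.sample_ids()
    x: dict[int, float] = {}
    for k, sid in enumerate(samples):
        x[sid] = (k + 0.5) / len(samples) if samples else 0.5

    left_children: dict[int, set[int]] = {}
    all_children: dict[int, set[int]] = {}
    for e in sorted(arg.edges, key=lambda e: e.id):
        all_children.setdefault(e.parent, set()).add(e.child)
        if any(l <= 0 < r for l, r in e.intervals):
            left_children.setdefault(e.parent, set()).add(e.child)

    for n in sorted(arg.nodes, key=lambda n: (n.time, n.id)):
        if n.id in x:
            continue
        kids = left_children.get(n.id) or all_children.get(n.id)
        if kids:
            placed = [x[c] for c in sorted(kids) if c in x]
            x[n.id] = sum(placed) / len(placed) if placed else 0.5
        else:
            x[n.id] = 0.5
    return x


# ---------------------------------------------------------------------------
# Force-directed horizontal relaxation
# ---------------------------------------------------------------------------

def _pair_jitter(ids_a: np.ndarray, ids_b: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic tiny offsets (one per pair) used to break exact x ties."""
    a = ids_a.astype(np.uint64)
    b = ids_b.astype(np.uint64)
    h = (a * np.uint64(2654435761) ^ b * np.uint64(40503)
         ^ np.uint64(seed & 0x7FFFFFFF) * np.uint64(83492791))
    h ^= h >> np.uint64(13)
    sign = np.where((h & np.uint64(1)) == 0, 1.0, -1.0)
    mag = 1e-6 * (1.0 + ((h >> np.uint64(1)) % np.uint64(1000)).astype(float) / 1000.0)
    return sign * mag


def _repulsion_pairs(ids: np.ndarray, y: np.ndarray,
                     window: float) -> tuple[np.ndarray, np.ndarray]:
    """All index pairs (i, j), i<j in y-sorted order, with |y_i - y_j| < window."""
    order = np.argsort(y, kind="stable")
    ys = y[order]
    ai: list[int] = []
    bi: list[int] = []
    j = 0
    n = len(ys)
    for i in range(n):
        if j <= i:
            j = i + 1
        while j < n and ys[j] - ys[i] < window:
            j += 1
        for k in range(i + 1, j):
            ai.append(order[i])
            bi.append(order[k])
    return (np.asarray(ai, dtype=np.intp), np.asarray(bi, dtype=np.intp))


def force_layout(arg: D3ARG, scale: str = "rank", seed: int = 0,
                 iterations: int = 300,
                 params: Optional[ForceParams] = None) -> Layout:
    """Relax horizontal positions while holding each node's y fixed.

    Per iteration: (1) a spring along every edge pulls each endpoint's x
    toward the other's; (2) every pair of nodes closer in y than
    ``params.y_window`` repels with magnitude ``k_r * dx / (dx**2 + eps)``;
    (3) the resulting step is scaled by a geometrically cooling factor; (4)
    x is clamped to [0, 1].  Afterwards the untangle guard (see
    :class:`ForceParams`) keeps whichever of the initial and relaxed
    configurations has fewer straight-segment crossings.  Nodes with
    ``pinned_x`` set never move; y comes from :func:`time_to_y` and is never
    modified.  With ``iterations=0`` the result is exactly the initial
    placement (plus pins).
    """
    if params is None:
        params = ForceParams()
    ids = np.array(sorted(n.id for n in arg.nodes), dtype=np.int64)
    index = {int(i): k for k, i in enumerate(ids)}
    nodes = sorted(arg.nodes, key=lambda n: n.id)
    y = np.array(time_to_y([n.time for n in nodes], scale))
    x0 = initial_x(arg)
    x = np.array([x0[int(i)] for i in ids], dtype=float)

    pinned = np.zeros(len(ids), dtype=bool)
    pins = np.zeros(len(ids), dtype=float)
    for n in nodes:
        if n.pinned_x is not None:
            k = index[n.id]
            pinned[k] = True
            pins[k] = float(n.pinned_x)
    x[pinned] = pins[pinned]
    np.clip(x, 0.0, 1.0, out=x)
    x_init = x.copy()

    if iterations > 0 and len(ids) > 1:
        edges = sorted(arg.edges, key=lambda e: e.id)
        ci = np.array([index[e.child] for e in edges], dtype=np.intp)
        pi = np.array([index[e.parent] for e in edges], dtype=np.intp)
        ra, rb = _repulsion_pairs(ids, y, params.y_window)
        jitter = _pair_jitter(ids[ra], ids[rb], seed) if len(ra) else np.empty(0)

        ratio = params.alpha_end / params.alpha_start
        denom = max(iterations - 1, 1)
        for t in range(iterations):
            alpha = params.alpha_start * ratio ** (t / denom)
            f = np.zeros_like(x)
            if len(ci):
                d = x[pi] - x[ci]
                np.add.at(f, ci, params.spring * d)
                np.add.at(f, pi, -params.spring * d)
            if len(ra):
                dx = x[ra] - x[rb]
                dx = np.where(dx == 0.0, jitter, dx)
                mag = params.repulsion * dx / (dx * dx + params.epsilon)
                np.add.at(f, ra, mag)
                np.add.at(f, rb, -mag)
            x += alpha * f
            x[pinned] = pins[pinned]
            np.clip(x, 0.0, 1.0, out=x)

        if params.untangle_guard and len(edges) <= params.guard_max_edges:
            def line_segs(xs: np.ndarray) -> list[Segment]:
                return [((xs[c], y[c]), (xs[p], y[p]))
                        for c, p in zip(ci, pi) if (xs[c], y[c]) != (xs[p], y[p])]

            if (_count_segment_crossings(line_segs(x))
                    > _count_segment_crossings(line_segs(x_init))):
                x = x_init

    coords = {int(i): (float(x[k]), float(y[k])) for k, i in enumerate(ids)}
    return Layout(coords=coords, scale=scale, seed=int(seed),
                  iterations=int(iterations))


# ---------------------------------------------------------------------------
# Crossing count
# ---------------------------------------------------------------------------

Point = tuple[float, float]
Segment = tuple[Point, Point]


def segments_for_style(arg: D3ARG, layout: Layout,
                       style: str = "line") -> list[Segment]:
    """The routed line segments of every edge under a stylization.

    Line style yields one segment per edge; orthogonal yields the vertical
    riser and horizontal shelf (one segment when degenerate).  Zero-length
    segments are dropped.
    """
    from .render import route_edge  # render depends on layout; import lazily

    segs: list[Segment] = []
    for e in sorted(arg.edges, key=lambda e: e.id):
        pts = route_edge(e, layout, style)
        for a, b in zip(pts, pts[1:]):
            if a != b:
                segs.append((a, b))
    return segs


def _orient(p: Point, q: Point, r: Point) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _segments_cross(s1: Segment, s2: Segment) -> bool:
    """True iff the segments meet at a point interior to both.

    Proper crossings count; contacts at an endpoint of either segment do
    not (shared nodes are not crossings); collinear segments count when
    their overlap has positive length.
    """
    p1, q1 = s1
    p2, q2 = s2
    o1 = _orient(p1, q1, p2)
    o2 = _orient(p1, q1, q2)
    o3 = _orient(p2, q2, p1)
    o4 = _orient(p2, q2, q1)
    if o1 * o2 < 0 and o3 * o4 < 0:
        return True
    if o1 == 0 and o2 == 0 and o3 == 0 and o4 == 0:
        # Collinear: project on the dominant axis and require interior overlap.
        axis = 0 if abs(q1[0] - p1[0]) >= abs(q1[1] - p1[1]) else 1
        a0, a1 = sorted((p1[axis], q1[axis]))
        b0, b1 = sorted((p2[axis], q2[axis]))
        return max(a0, b0) < min(a1, b1)
    return False


def _count_segment_crossings(segs: Sequence[Segment]) -> int:
    n = 0
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if _segments_cross(segs[i], segs[j]):
                n += 1
    return n


def count_crossings(arg: D3ARG, layout: Layout, style: str = "line") -> int:
    """Number of unordered routed-segment pairs that cross interior-to-both."""
    return _count_segment_crossings(segments_for_style(arg, layout, style))


# ---------------------------------------------------------------------------
# Manual pinning
# ---------------------------------------------------------------------------

def pin_x(arg: D3ARG, node_id: int, x: Optional[float]) -> D3ARG:
    """Pin a node's horizontal position (the drag operation), or unpin with None.

    Subsequent :func:`force_layout` calls hold the node at exactly ``x``;
    the pin is a node-table field and so survives the JSON round trip.
    """
    if x is not None and not (0.0 <= x <= 1.0):
        raise ARGError(f"pinned x {x} outside [0, 1]")
    new = replace_tables(arg)
    for i, n in enumerate(new.nodes):
        if n.id == node_id:
            new.nodes[i] = replace(n, pinned_x=None if x is None else float(x))
            return new
    raise ARGError(f"unknown node id {node_id}")


# ---------------------------------------------------------------------------
# Focal-node subgraph extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stub:
    """A connection from a kept node to an excluded part of the full graph."""

    node: int        # the kept endpoint
    direction: str   # "up" if the excluded endpoint is the parent else "down"
    excluded: int    # the excluded endpoint
    edge: int        # the original edge id


@dataclass
class Subgraph:
    """The restriction of an ARG to a focal node's neighborhood.

    Every input edge is accounted for: intact (both endpoints kept), a stub
    (exactly one endpoint kept), or listed in ``excluded_edges`` (neither
    endpoint within range) — nothing is dropped silently.
    """

    arg: D3ARG
    focal: int
    degree: int
    stubs: list[Stub] = field(default_factory=list)
    excluded_edges: list[int] = field(default_factory=list)


def subgraph(arg: D3ARG, focal: int, degree: int) -> Subgraph:
    """Breadth-first neighborhood of ``focal`` within ``degree`` undirected hops.

    Edges with both endpoints kept are retained with intervals intact and
    breakpoints recomputed; edges with one endpoint kept become stubs.
    Mutations resolving to a retained edge are kept.
    """
    node_ids = {n.id for n in arg.nodes}
    if focal not in node_ids:
        raise ARGError(f"unknown focal node id {focal}")
    if degree < 1:
        raise ARGError(f"degree must be >= 1, got {degree}")

    adj: dict[int, set[int]] = {}
    for e in arg.edges:
        adj.setdefault(e.parent, set()).add(e.child)
        adj.setdefault(e.child, set()).add(e.parent)
    kept = {focal}
    frontier = deque([(focal, 0)])
    while frontier:
        u, d = frontier.popleft()
        if d == degree:
            continue
        for v in sorted(adj.get(u, ())):
            if v not in kept:
                kept.add(v)
                frontier.append((v, d + 1))

    intact: list[EdgeRecord] = []
    stubs: list[Stub] = []
    excluded: list[int] = []
    for e in sorted(arg.edges, key=lambda e: e.id):
        pk, ck = e.parent in kept, e.child in kept
        if pk and ck:
            intact.append(e)
        elif pk or ck:
            if ck:
                stubs.append(Stub(node=e.child, direction="up",
                                  excluded=e.parent, edge=e.id))
            else:
                stubs.append(Stub(node=e.parent, direction="down",
                                  excluded=e.child, edge=e.id))
        else:
            excluded.append(e.id)

    kept_edge_ids = {e.id for e in intact}
    sub_nodes = [n for n in sorted(arg.nodes, key=lambda n: n.id)
                 if n.id in kept]
    sub = D3ARG(nodes=sub_nodes, edges=intact, mutations=[], breakpoints=[],
                genome_length=arg.genome_length, defaults=arg.defaults)
    sub.breakpoints = compute_breakpoints(sub)
    if arg.mutations:
        from .local_trees import resolve_mutation_edge
        for m in arg.mutations:
            if m.node in kept:
                try:
                    eid = resolve_mutation_edge(arg, m)
                except ARGError:
                    continue
                if eid in kept_edge_ids:
                    sub.mutations.append(m)
    return Subgraph(arg=sub, focal=focal, degree=degree, stubs=stubs,
                    excluded_edges=excluded)
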