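"""Test-ARG generation: a hand-built toy fixture and a small back-in-time
coalescent-with-recombination simulator.

The simulator follows the classic Hudson construction.  Going backwards in
time, each of ``k`` live lineages carries a set of ancestral-material
segments; coalescence happens at rate ``k(k-1)/2`` and recombination at
``recombination_rate`` times the total ancestral material length summed
over lineages.  A recombination splits one lineage at a position drawn
uniformly within its ancestral material (so every event is visible in the
output); a coalescence merges two lineages into a new node, emitting edges
for all transferred material — including regions that do not coalesce at
that node — which is the full-ARG recording convention the orthogonal
stylization targets.  Material that has become ancestral to every sample is
retired, and the process runs until every position has fully coalesced.

Randomness comes from a single ``numpy.random.Generator`` (PCG64) seeded by
``SimParams.seed``; the draw order is fixed and documented in the methods
note, so a given seed always yields the same ARG.

This is a fixture generator, not a research simulator: no demography, no
gene conversion, no selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (D3ARG, EdgeRecord, MutationRecord, NodeRecord,
                    compute_breakpoints, from_ts_tables, replace_tables)

__all__ = [
    "SimParams",
    "toy_T1",
    "simulate_arg",
    "sprinkle_mutations",
    "curated_layout_fixtures",
    "CURATED_SEEDS",
    "CURATED_N_SAMPLES",
    "CURATED_GENOME_LENGTH",
    "CURATED_RECOMB_RATE",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the back-in-time simulation.

    ``recombination_rate`` is per unit genome length, per lineage, per unit
    (coalescent-scaled) time.
    """

    n_samples: int
    genome_length: float
    recombination_rate: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be non-negative")


def toy_T1() -> D3ARG:
    """The fixed 5-node, 5-edge toy ARG used throughout the test suite.

    Samples 0 and 1 at time 0; node 2 is a recombination node (time 1) with
    breakpoint 40; node 3 (time 2) and the root 4 (time 3).  Breakpoint
    regions are [0, 40) and [40, 100).
    """
    nodes = [
        NodeRecord(id=0, time=0.0, is_sample=True),
        NodeRecord(id=1, time=0.0, is_sample=True),
        NodeRecord(id=2, time=1.0),
        NodeRecord(id=3, time=2.0),
        NodeRecord(id=4, time=3.0),
    ]
    edges = [
        EdgeRecord(id=0, parent=2, child=0, intervals=((0.0, 100.0),)),
        EdgeRecord(id=1, parent=3, child=2, intervals=((0.0, 40.0),)),
        EdgeRecord(id=2, parent=4, child=2, intervals=((40.0, 100.0),)),
        EdgeRecord(id=3, parent=3, child=1, intervals=((0.0, 100.0),)),
        EdgeRecord(id=4, parent=4, child=3, intervals=((0.0, 100.0),)),
    ]
    arg = D3ARG(nodes=nodes, edges=edges, mutations=[], breakpoints=[],
                genome_length=100.0)
    arg.breakpoints = compute_breakpoints(arg)
    return arg


# ---------------------------------------------------------------------------
# Hudson-style back-in-time simulation
# ---------------------------------------------------------------------------

# A lineage is (node_id, segments); segments is a sorted disjoint list of
# (left, right, n_descendant_samples).
Segment = tuple[float, float, int]


def _seg_length(segments: list[Segment]) -> float:
    return sum(r - l for l, r, _ in segments)


def _merge_segment_lists(a: list[Segment], b: list[Segment],
                         n_samples: int) -> list[Segment]:
    """Sum descendant counts over the union; drop fully coalesced material."""
    bounds = sorted({x for l, r, _ in a + b for x in (l, r)})
    out: list[Segment] = []
    for lo, hi in zip(bounds, bounds[1:]):
        cnt = 0
        for segs in (a, b):
            for l, r, c in segs:
                if l <= lo and hi <= r:
                    cnt += c
                    break
        if cnt == 0 or cnt >= n_samples:
            continue
        if out and out[-1][1] == lo and out[-1][2] == cnt:
            out[-1] = (out[-1][0], hi, cnt)
        else:
            out.append((lo, hi, cnt))
    return out


def _intervals_of(segments: list[Segment]) -> list[tuple[float, float]]:
    """Coalesce a segment list into plain intervals (counts dropped)."""
    out: list[list[float]] = []
    for l, r, _ in segments:
        if out and l <= out[-1][1]:
            out[-1][1] = max(out[-1][1], r)
        else:
            out.append([l, r])
    return [(l, r) for l, r in out]


def simulate_arg(params: SimParams) -> D3ARG:
    """Simulate a full ARG for ``params.n_samples`` haploid samples.

    The output is assembled through :func:`argdraw.model.from_ts_tables`
    (one edge row per transferred interval), so duplicate (parent, child)
    pairs arising when both halves of a recombination coalesce together are
    merged, breakpoints are computed, and the result always validates.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    L = float(params.genome_length)

    node_rows = [{"id": i, "time": 0.0, "is_sample": True} for i in range(n)]
    edge_rows: list[dict] = []
    lineages: list[tuple[int, list[Segment]]] = [
        (i, [(0.0, L, 1)]) for i in range(n)
    ]
    next_id = n
    t = 0.0

    while len(lineages) >= 2:
        k = len(lineages)
        lens = [_seg_length(segs) for _, segs in lineages]
        total_len = sum(lens)
        rate_coal = k * (k - 1) / 2.0
        rate_rec = params.recombination_rate * total_len
        total = rate_coal + rate_rec
        t += rng.exponential(1.0 / total)

        if rng.random() < rate_coal / total:
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            i, j = min(i, j), max(i, j)
            (na, sa) = lineages[i]
            (nb, sb) = lineages[j]
            nid = next_id
            next_id += 1
            node_rows.append({"id": nid, "time": t, "is_sample": False})
            for child, segs in ((na, sa), (nb, sb)):
                for l, r in _intervals_of(segs):
                    edge_rows.append({"parent": nid, "child": child,
                                      "left": l, "right": r})
            merged = _merge_segment_lists(sa, sb, n)
            del lineages[j]
            del lineages[i]
            if merged:
                lineages.append((nid, merged))
        else:
            # Recombination: lineage chosen in proportion to material length,
            # split position uniform within its ancestral material.
            u = rng.random() * total_len
            idx = 0
            acc = 0.0
            for idx in range(k):
                acc += lens[idx]
                if u < acc:
                    break
            node, segs = lineages[idx]
            w = rng.random() * lens[idx]
            pos: Optional[float] = None
            run = 0.0
            for l, r, _ in segs:
                if w < run + (r - l):
                    pos = l + (w - run)
                    break
                run += r - l
            if pos is None:
                pos = segs[-1][1]
            left = [(l, min(r, pos), c) for l, r, c in segs if l < pos]
            right = [(max(l, pos), r, c) for l, r, c in segs if r > pos]
            if not left or not right:
                continue  # split fell on a material boundary; event invisible
            nid = next_id
            next_id += 1
            node_rows.append({"id": nid, "time": t, "is_sample": False})
            for l, r in _intervals_of(segs):
                edge_rows.append({"parent": nid, "child": node,
                                  "left": l, "right": r})
            del lineages[idx]
            lineages.append((nid, left))
            lineages.append((nid, right))

    return from_ts_tables(node_rows, edge_rows, genome_length=L)


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def sprinkle_mutations(arg: D3ARG, rate_per_length_per_time: float,
                       seed: int) -> D3ARG:
    """Scatter neutral mutations over the edges of an ARG.

    For every edge, for every interval, the count is Poisson with mean
    ``rate * interval_length * (t_parent - t_child)``; positions are uniform
    in the interval and times uniform in the branch span, so every mutation
    resolves back to its generating edge.  Edges are visited in id order and
    counts drawn before positions before times, making the result a pure
    function of (arg, rate, seed).
    """
    if rate_per_length_per_time < 0:
        raise ValueError("mutation rate must be non-negative")
    rng = np.random.default_rng(seed)
    new = replace_tables(arg)
    times = {n.id: n.time for n in arg.nodes}
    mid = max((m.id for m in arg.mutations), default=-1) + 1
    for e in sorted(arg.edges, key=lambda e: e.id):
        t_c, t_p = times[e.child], times[e.parent]
        for l, r in e.intervals:
            mean = rate_per_length_per_time * (r - l) * (t_p - t_c)
            count = int(rng.poisson(mean)) if mean > 0 else 0
            if count == 0:
                continue
            positions = rng.uniform(l, r, size=count)
            mtimes = rng.uniform(t_c, t_p, size=count)
            for p, mt in zip(positions, mtimes):
                new.mutations.append(MutationRecord(
                    id=mid, node=e.child, position=float(p), time=float(mt)))
                mid += 1
    return new


# ---------------------------------------------------------------------------
# Curated layout fixtures
# ---------------------------------------------------------------------------

# Ten small ARGs used to exercise the untangling simulation: 8 samples with
# the recombination rate chosen so that each seed yields a handful (2-6) of
# recombination nodes — enough reticulation to tangle, small enough to
# count crossings exhaustively.
CURATED_SEEDS = tuple(range(1, 11))
CURATED_N_SAMPLES = 8
CURATED_GENOME_LENGTH = 2000.0
CURATED_RECOMB_RATE = 3e-4


def curated_layout_fixtures() -> list[D3ARG]:
    return [
        simulate_arg(SimParams(n_samples=CURATED_N_SAMPLES,
                               genome_length=CURATED_GENOME_LENGTH,
                               recombination_rate=CURATED_RECOMB_RATE,
                               seed=s))
        for s in CURATED_SEEDS
    ]
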