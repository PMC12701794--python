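"""Local trees and genomic-extent mappings.

Each genomic position induces a local tree: the subgraph formed by the
edges whose intervals span that position.  These queries power all of the
hover-style interactions — highlighting the local tree for a region of the
chromosome bar, the genomic regions an edge covers, and the mutations on an
edge — which are precomputed here as pure data (:class:`InteractionMap`),
with no event system in the core.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Any

from .model import ARGError, D3ARG, MutationRecord

__all__ = [
    "LocalTree",
    "InteractionMap",
    "edges_at_position",
    "local_tree",
    "classify_edges",
    "resolve_mutation_edge",
    "build_interaction_map",
]


@dataclass(frozen=True)
class LocalTree:
    """The genealogy at one genomic position.

    ``parent_of`` maps each non-root node in the tree to its parent;
    ``roots`` are the tree nodes with no spanning parent edge.  Unary nodes
    (one child at this position) are retained, not collapsed, matching the
    full-ARG drawing convention.
    """

    position: float
    edge_ids: frozenset[int]
    parent_of: dict[int, int]
    roots: frozenset[int]

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(self.parent_of) | self.roots


@dataclass
class InteractionMap:
    """Region<->edge and mutation->position mappings, hover behavior as data."""

    region_to_edges: dict[int, frozenset[int]]
    edge_to_regions: dict[int, frozenset[int]]
    edge_to_mutations: dict[int, tuple[int, ...]] = field(default_factory=dict)
    mutation_to_position: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "region_to_edges": {str(k): sorted(v)
                                for k, v in sorted(self.region_to_edges.items())},
            "edge_to_regions": {str(k): sorted(v)
                                for k, v in sorted(self.edge_to_regions.items())},
            "edge_to_mutations": {str(k): list(v)
                                  for k, v in sorted(self.edge_to_mutations.items())},
            "mutation_to_position": {str(k): v
                                     for k, v in sorted(self.mutation_to_position.items())},
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "InteractionMap":
        return cls(
            region_to_edges={int(k): frozenset(v)
                             for k, v in d.get("region_to_edges", {}).items()},
            edge_to_regions={int(k): frozenset(v)
                             for k, v in d.get("edge_to_regions", {}).items()},
            edge_to_mutations={int(k): tuple(v)
                               for k, v in d.get("edge_to_mutations", {}).items()},
            mutation_to_position={int(k): float(v)
                                  for k, v in d.get("mutation_to_position", {}).items()},
        )


def _check_position(arg: D3ARG, p: float) -> None:
    if not (0 <= p < arg.genome_length):
        raise ARGError(
            f"position {p} outside the genome extent [0, {arg.genome_length})")


def edges_at_position(arg: D3ARG, p: float) -> set[int]:
    """Ids of edges with some interval [left, right) satisfying left <= p < right.

    This linear interval scan is the reference semantics; positions exactly
    at a breakpoint belong to the right-hand region (half-open convention).
    """
    _check_position(arg, p)
    return {e.id for e in arg.edges
            if any(l <= p < r for l, r in e.intervals)}


def local_tree(arg: D3ARG, p: float) -> LocalTree:
    """Extract the local tree at position ``p``.

    Raises if some node has two or more spanning parent edges, which would
    violate the one-parent-per-position forest invariant.
    """
    spanning = edges_at_position(arg, p)
    by_id = arg.edges_by_id()
    parent_of: dict[int, int] = {}
    nodes: set[int] = set()
    for eid in sorted(spanning):
        e = by_id[eid]
        if e.child in parent_of:
            raise ARGError(
                f"node {e.child} has multiple parent edges spanning {p}: "
                f"the ARG is not a forest at this position")
        parent_of[e.child] = e.parent
        nodes.add(e.child)
        nodes.add(e.parent)
    roots = frozenset(nodes - set(parent_of))
    return LocalTree(position=float(p), edge_ids=frozenset(spanning),
                     parent_of=parent_of, roots=roots)


def classify_edges(arg: D3ARG, p: float) -> tuple[set[int], set[int]]:
    """Partition all edge ids into (in the local tree at p, out of it).

    Out-of-tree edges are the ones a renderer draws dashed when a focus
    position is set.
    """
    in_tree = edges_at_position(arg, p)
    out_of_tree = {e.id for e in arg.edges} - in_tree
    return in_tree, out_of_tree


def resolve_mutation_edge(arg: D3ARG, m: MutationRecord) -> int:
    """The unique parent edge of ``m.node`` spanning ``m.position``."""
    _check_position(arg, m.position)
    candidates = [e for e in arg.edges if e.child == m.node
                  and any(l <= m.position < r for l, r in e.intervals)]
    if len(candidates) != 1:
        raise ARGError(
            f"mutation {m.id}: {len(candidates)} parent edges of node "
            f"{m.node} span position {m.position}; need exactly 1")
    e = candidates[0]
    if m.time is not None:
        nt = arg.nodes_by_id()
        lo, hi = nt[e.child].time, nt[e.parent].time
        if not (lo <= m.time <= hi):
            raise ARGError(
                f"mutation {m.id}: time {m.time} outside branch span "
                f"[{lo}, {hi}] of edge {e.id}")
    return e.id


def build_interaction_map(arg: D3ARG) -> InteractionMap:
    """Precompute every hover mapping for a valid ARG with breakpoints.

    Because breakpoint boundaries include every edge-interval endpoint, each
    interval is an exact union of whole regions, so each (edge, region)
    incidence is visited once via binary search on the region boundaries.
    """
    lefts = [b.left for b in arg.breakpoints]
    region_to_edges: dict[int, set[int]] = {b.index: set()
                                            for b in arg.breakpoints}
    edge_to_regions: dict[int, frozenset[int]] = {}
    for e in arg.edges:
        regions: set[int] = set()
        for l, r in e.intervals:
            k0 = bisect.bisect_left(lefts, l)
            k1 = bisect.bisect_left(lefts, r, lo=k0)
            if k1 == k0:  # interval inside one region (defensive; cannot
                k1 = k0 + 1  # happen when breakpoints are consistent)
            for k in range(k0, min(k1, len(lefts))):
                regions.add(k)
                region_to_edges[k].add(e.id)
        edge_to_regions[e.id] = frozenset(regions)

    edge_to_mutations: dict[int, list[int]] = {}
    mutation_to_position: dict[int, float] = {}
    for m in sorted(arg.mutations, key=lambda m: m.id):
        eid = resolve_mutation_edge(arg, m)
        edge_to_mutations.setdefault(eid, []).append(m.id)
        mutation_to_position[m.id] = m.position
    return InteractionMap(
        region_to_edges={k: frozenset(v) for k, v in region_to_edges.items()},
        edge_to_regions=edge_to_regions,
        edge_to_mutations={k: tuple(v) for k, v in edge_to_mutations.items()},
        mutation_to_position=mutation_to_position,
    )
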