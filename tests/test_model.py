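"""Data model: validation, conversion/merging, breakpoints, JSON, styling."""

import dataclasses
import math

import pytest
from hypothesis import given, strategies as st

import argdraw as ad
from argdraw.model import merge_intervals, replace_tables

from conftest import args_equivalent, naive_edges_at


# ---------------------------------------------------------------------------
# merge_intervals
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw, expected", [
    ([(0.0, 10.0), (10.0, 30.0)], ((0.0, 30.0),)),          # adjacency
    ([(0.0, 10.0), (20.0, 30.0)], ((0.0, 10.0), (20.0, 30.0))),  # disjoint
    ([(20.0, 30.0), (0.0, 15.0), (10.0, 25.0)], ((0.0, 30.0),)),  # overlap
])
def test_merge_intervals_coalesces(raw, expected):
    assert merge_intervals(raw) == expected


@given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 50))
                .map(lambda t: (float(t[0]), float(t[0] + t[1]))),
                min_size=1, max_size=12))
def test_merge_intervals_canonical_and_conserves_union(ivs):
    merged = merge_intervals(ivs)
    # canonical: sorted, disjoint, never touching
    for (l1, r1), (l2, r2) in zip(merged, merged[1:]):
        assert r1 < l2
    # the union of points covered is preserved (check on a fine grid)
    hi = max(r for _, r in ivs)
    for k in range(int(2 * hi) + 1):
        p = k / 2
        assert any(l <= p < r for l, r in ivs) == \
            any(l <= p < r for l, r in merged)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def test_toy_fixture_is_valid(t1):
    assert ad.validate(t1) == []


def _corrupt_time_inversion(arg):
    arg.nodes[2] = dataclasses.replace(arg.nodes[2], time=0.0)  # node 2 = e0 parent
    return "strict-time-order"


def _corrupt_overlapping_intervals(arg):
    arg.edges[1] = dataclasses.replace(arg.edges[1],
                                       intervals=((0.0, 40.0), (30.0, 60.0)))
    return "intervals-disjoint-sorted"


def _corrupt_dangling_ref(arg):
    arg.edges[0] = dataclasses.replace(arg.edges[0], parent=99)
    return "dangling-node-ref"


def _corrupt_duplicate_pair(arg):
    e = arg.edges[1]
    arg.edges.append(dataclasses.replace(e, id=99))
    return "duplicate-parent-child-pair"


def _corrupt_out_of_range(arg):
    arg.edges[4] = dataclasses.replace(arg.edges[4],
                                       intervals=((0.0, 150.0),))
    return "interval-in-genome"


def _corrupt_unresolvable_mutation(arg):
    arg.mutations.append(ad.MutationRecord(id=0, node=2, position=150.0))
    return "position-in-genome"


@pytest.mark.parametrize("corruption", [
    _corrupt_time_inversion,
    _corrupt_overlapping_intervals,
    _corrupt_dangling_ref,
    _corrupt_duplicate_pair,
    _corrupt_out_of_range,
    _corrupt_unresolvable_mutation,
])
def test_validation_catches_each_scripted_corruption(t1, corruption):
    broken = replace_tables(t1)
    rule = corruption(broken)
    violations = ad.validate(broken)
    assert violations, f"corruption {rule} went undetected"
    assert any(v.rule == rule for v in violations), \
        [str(v) for v in violations]


def test_validation_names_the_offending_row(t1):
    broken = replace_tables(t1)
    # make e1's parent (node 3) as old as its child (node 2)
    broken.nodes[3] = dataclasses.replace(broken.nodes[3], time=1.0)
    rows = {v.row for v in ad.validate(broken) if v.rule == "strict-time-order"}
    assert 1 in rows  # edge e1 = (3, 2)


def test_mutation_must_resolve_to_exactly_one_edge(t1):
    broken = replace_tables(t1)
    # node 4 (the root) has no parent edge at all
    broken.mutations.append(ad.MutationRecord(id=0, node=4, position=10.0))
    assert any(v.rule == "resolvable-to-one-edge" and v.row == 0
               for v in ad.validate(broken))


# ---------------------------------------------------------------------------
# Conversion from per-interval tables
# ---------------------------------------------------------------------------

NODES_73 = [{"id": 3, "time": 0.0, "is_sample": True},
            {"id": 7, "time": 1.0, "is_sample": False}]


def test_adjacent_rows_coalesce_into_one_interval():
    arg = ad.from_ts_tables(
        NODES_73,
        [{"parent": 7, "child": 3, "left": 0.0, "right": 10.0},
         {"parent": 7, "child": 3, "left": 10.0, "right": 30.0}],
        genome_length=30.0)
    assert len(arg.edges) == 1
    assert arg.edges[0].intervals == ((0.0, 30.0),)


def test_disjoint_rows_become_multi_interval_edge():
    arg = ad.from_ts_tables(
        NODES_73,
        [{"parent": 7, "child": 3, "left": 0.0, "right": 10.0},
         {"parent": 7, "child": 3, "left": 20.0, "right": 30.0}],
        genome_length=30.0)
    assert len(arg.edges) == 1
    assert arg.edges[0].intervals == ((0.0, 10.0), (20.0, 30.0))


def test_per_interval_dump_of_t1_rebuilds_it(t1):
    node_rows = [{"id": n.id, "time": n.time, "is_sample": n.is_sample}
                 for n in t1.nodes]
    edge_rows = [{"parent": e.parent, "child": e.child, "left": l, "right": r}
                 for e in t1.edges for l, r in e.intervals]
    # split e3 = (3, 1, [0,100)) into two abutting rows: 6 rows total
    edge_rows.remove({"parent": 3, "child": 1, "left": 0.0, "right": 100.0})
    edge_rows += [{"parent": 3, "child": 1, "left": 0.0, "right": 40.0},
                  {"parent": 3, "child": 1, "left": 40.0, "right": 100.0}]
    assert len(edge_rows) == 6
    rebuilt = ad.from_ts_tables(node_rows, edge_rows, genome_length=100.0)
    assert args_equivalent(rebuilt, t1)
    assert ad.validate(rebuilt) == []


def test_conversion_conserves_covered_length_per_pair(sim_family):
    rng_split = 0
    for arg in sim_family:
        rows = []
        for e in arg.edges:
            for l, r in e.intervals:
                mid = (l + r) / 2  # split every interval to exercise merging
                rows.append({"parent": e.parent, "child": e.child,
                             "left": l, "right": mid})
                rows.append({"parent": e.parent, "child": e.child,
                             "left": mid, "right": r})
                rng_split += 1
        node_rows = [{"id": n.id, "time": n.time, "is_sample": n.is_sample}
                     for n in arg.nodes]
        back = ad.from_ts_tables(node_rows, rows,
                                 genome_length=arg.genome_length)
        want = {(e.parent, e.child): e.covered_length for e in arg.edges}
        got = {(e.parent, e.child): e.covered_length for e in back.edges}
        assert got.keys() == want.keys()
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9)
        for e in back.edges:  # merging must re-coalesce the split rows
            for (l1, r1), (l2, r2) in zip(e.intervals, e.intervals[1:]):
                assert r1 < l2


def test_conversion_rejects_unknown_node_and_bad_interval():
    with pytest.raises(ad.ConversionError, match="unknown parent node 9"):
        ad.from_ts_tables(NODES_73,
                          [{"parent": 9, "child": 3, "left": 0, "right": 1}],
                          genome_length=30.0)
    with pytest.raises(ad.ConversionError, match="outside"):
        ad.from_ts_tables(NODES_73,
                          [{"parent": 7, "child": 3, "left": 0, "right": 31}],
                          genome_length=30.0)


def test_conversion_from_tskit_tree_sequence():
    msprime = pytest.importorskip("msprime")
    ts = msprime.sim_ancestry(8, sequence_length=1e4, recombination_rate=1e-4,
                              ploidy=1, random_seed=7)
    ts = msprime.sim_mutations(ts, rate=1e-5, random_seed=7)
    arg = ad.from_tree_sequence(ts)
    assert ad.validate(arg) == []
    # covered length per (parent, child) matches the raw edge table
    want: dict = {}
    for e in ts.edges():
        key = (e.parent, e.child)
        want[key] = want.get(key, 0.0) + (e.right - e.left)
    got = {(e.parent, e.child): e.covered_length for e in arg.edges}
    assert got == pytest.approx(want)
    assert len(arg.mutations) == ts.num_mutations


# ---------------------------------------------------------------------------
# Breakpoints
# ---------------------------------------------------------------------------

def test_breakpoints_of_toy(t1):
    bps = ad.compute_breakpoints(t1)
    assert [(b.index, b.left, b.right) for b in bps] == \
        [(0, 0.0, 40.0), (1, 40.0, 100.0)]


def test_single_tree_arg_has_one_region():
    arg = ad.simulate_arg(ad.SimParams(5, 500.0, 0.0, seed=2))
    assert [(b.left, b.right) for b in ad.compute_breakpoints(arg)] == \
        [(0.0, 500.0)]


def test_breakpoints_are_edge_endpoint_union():
    nodes = [{"id": 0, "time": 0.0, "is_sample": True},
             {"id": 1, "time": 0.0, "is_sample": True},
             {"id": 2, "time": 1.0}, {"id": 3, "time": 2.0}]
    edges = [{"parent": 2, "child": 0, "left": 0.0, "right": 10.0},
             {"parent": 3, "child": 1, "left": 0.0, "right": 20.0}]
    arg = ad.from_ts_tables(nodes, edges, genome_length=50.0)
    assert [(b.left, b.right) for b in arg.breakpoints] == \
        [(0.0, 10.0), (10.0, 20.0), (20.0, 50.0)]


def test_adjacent_regions_have_distinct_edge_sets(sim_family):
    for arg in sim_family[:8]:
        sets = []
        for b in arg.breakpoints:
            mids = [b.left + f * (b.right - b.left)
                    for f in (0.1, 0.35, 0.5, 0.77, 0.93)]
            at = [naive_edges_at(arg, p) for p in mids]
            assert all(s == at[0] for s in at), "edge set varies inside region"
            sets.append(at[0])
        for s1, s2 in zip(sets, sets[1:]):
            assert s1 != s2


# ---------------------------------------------------------------------------
# Figure JSON
# ---------------------------------------------------------------------------

def test_json_round_trip_is_identity_with_layout(t1):
    styled = ad.set_styles(t1, {"edges": [2]}, {"stroke": "gold"})
    styled = ad.pin_x(styled, 4, 0.625)
    layout = ad.force_layout(styled, scale="rank", seed=11, iterations=40)
    text = ad.to_json(styled, layout)
    arg2, layout2 = ad.from_json(text)
    assert arg2 == styled
    assert layout2 == layout
    assert arg2.nodes_by_id()[4].pinned_x == 0.625


def test_double_serialization_is_byte_identical(t1):
    layout = ad.force_layout(t1, seed=3, iterations=10)
    text = ad.to_json(t1, layout)
    arg2, layout2 = ad.from_json(text)
    assert ad.to_json(arg2, layout2) == text


def test_numeric_fields_survive_bit_exactly():
    nodes = [{"id": 0, "time": 0.0, "is_sample": True},
             {"id": 1, "time": 0.0, "is_sample": True},
             {"id": 2, "time": 0.1 + 0.2}]  # deliberately non-representable
    edges = [{"parent": 2, "child": 0, "left": 1 / 3, "right": 2 / 3},
             {"parent": 2, "child": 1, "left": 0.0, "right": 1.0}]
    arg = ad.from_ts_tables(nodes, edges, genome_length=1.0)
    arg2, _ = ad.from_json(ad.to_json(arg))
    assert arg2.nodes_by_id()[2].time == 0.30000000000000004
    (e,) = [e for e in arg2.edges if e.child == 0]
    assert e.intervals == ((1 / 3, 2 / 3),)


def test_missing_edges_table_is_named():
    with pytest.raises(ad.SchemaError, match="edges"):
        ad.from_json('{"schema_version": "1", "genome_length": 10, "nodes": []}')


def test_unknown_schema_version_rejected():
    with pytest.raises(ad.SchemaError, match="schema_version"):
        ad.from_json('{"schema_version": "99", "genome_length": 10, '
                     '"nodes": [], "edges": []}')


def test_dangling_reference_names_the_path():
    doc = ('{"schema_version": "1", "genome_length": 10, '
           '"nodes": [{"id": 0, "time": 0}], '
           '"edges": [{"id": 0, "parent": 5, "child": 0, '
           '"intervals": [[0, 10]]}]}')
    with pytest.raises(ad.SchemaError, match=r"\$\.edges\[0\]\.parent"):
        ad.from_json(doc)


def test_malformed_document_rejected():
    with pytest.raises(ad.SchemaError, match="malformed"):
        ad.from_json("{not json")


# ---------------------------------------------------------------------------
# Styling
# ---------------------------------------------------------------------------

def test_set_styles_changes_only_addressed_rows(t1):
    out = ad.set_styles(t1, {"edges": [2]}, {"stroke": "gold"})
    assert out.edges_by_id()[2].style.stroke == "gold"
    for e in out.edges:
        if e.id != 2:
            assert e.style == ad.EdgeStyle()
        assert e.intervals == t1.edges_by_id()[e.id].intervals
    assert out.nodes == t1.nodes


def test_set_styles_empty_selector_is_identity(t1):
    assert ad.set_styles(t1, {}, {"stroke": "gold"}) == t1
    assert ad.set_styles(t1, {"nodes": []}, {"fill": "red"}) == t1


def test_set_styles_reports_unknown_ids(t1):
    with pytest.raises(ad.ARGError, match="999"):
        ad.set_styles(t1, {"nodes": [999]}, {"fill": "red"})


def test_set_styles_rejects_bad_values(t1):
    with pytest.raises(ad.ARGError, match="width"):
        ad.set_styles(t1, {"edges": [0]}, {"width": -2})
    with pytest.raises(ad.ARGError, match="radius"):
        ad.set_styles(t1, {"nodes": [0]}, {"radius": 0})


# ---------------------------------------------------------------------------
# TSV dump dialect
# ---------------------------------------------------------------------------

def test_tsv_dump_round_trip(tmp_path, t1):
    with_muts = ad.sprinkle_mutations(t1, 5e-3, seed=4)
    assert with_muts.mutations
    ad.write_tsv_dump(with_muts, tmp_path)
    back = ad.read_tsv_dump(tmp_path)
    assert args_equivalent(back, with_muts)
    assert [(m.node, m.position, m.time) for m in back.mutations] == \
        [(m.node, m.position, m.time) for m in with_muts.mutations]


def test_tsv_edges_are_one_row_per_interval(tmp_path, t1):
    ad.write_tsv_dump(t1, tmp_path)
    rows = (tmp_path / "edges.tsv").read_text().strip().splitlines()
    assert rows[0].split("\t") == ["parent", "child", "left", "right"]
    assert len(rows) - 1 == sum(len(e.intervals) for e in t1.edges)
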