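"""Representation conversions: n-ary expansion counts, weights, round trips."""

import itertools

import pytest

import irefkit as ik
from irefkit.errors import IrefkitError
from irefkit.representations import ComplexList, ComplexRow
from conftest import make_single_complex_table


@pytest.mark.parametrize("m", range(3, 13))
def test_expansion_edge_counts(m):
    t, _ = make_single_complex_table(m)
    assert len(ik.mitab_to_edgelist(t, "spoke")) == m - 1
    assert len(ik.mitab_to_edgelist(t, "matrix")) == m * (m - 1) // 2
    assert len(ik.mitab_to_edgelist(t, "bipartite")) == m
    assert len(ik.mitab_to_edgelist(t, "exclude")) == 0


@pytest.mark.parametrize("m", [3, 5, 8])
def test_spoke_edges_subset_of_matrix_edges(m):
    t, _ = make_single_complex_table(m, seed=m)
    spoke = ik.mitab_to_edgelist(t, "spoke").pairs()
    matrix = ik.mitab_to_edgelist(t, "matrix").pairs()
    assert spoke <= matrix


def test_spoke_hub_is_bait_when_unique(table, manifest):
    for entry in manifest.reported_complexes:
        if entry["bait_rogid"] is None:
            continue
        idx = [i for i, r in enumerate(table)
               if r.edgetype == "C" and r.rigid == entry["rigid"]]
        sub = table.subset(idx)
        e = ik.mitab_to_edgelist(sub, "spoke", directed=True)
        sources = set(e.df["node_a"])
        assert sources == {entry["bait_rogid"]}


def test_spoke_hub_fallback_is_smallest_member(table, manifest):
    entry = next(e for e in manifest.reported_complexes if e["bait_rogid"] is None)
    idx = [i for i, r in enumerate(table)
           if r.edgetype == "C" and r.rigid == entry["rigid"]]
    e = ik.mitab_to_edgelist(table.subset(idx), "spoke", directed=True)
    assert set(e.df["node_a"]) == {min(entry["members_rogid"])}


def test_binary_edge_count_equals_pair_enumeration(table):
    binary = ik.select_interaction_type(table, {"binary"})
    e = ik.mitab_to_edgelist(binary, "exclude")
    pairs = {tuple(sorted((r.rogid_a, r.rogid_b))) for r in binary}
    assert len(e) == len(pairs)
    assert e.pairs() == pairs


def test_weights_count_supporting_records_brute_force(table):
    e = ik.mitab_to_edgelist(table, "matrix")
    # oracle: re-count incidences record-by-record
    support = {}
    for i, r in enumerate(table):
        if r.edgetype == "X" and r.rogid_a != r.rogid_b:
            support.setdefault(tuple(sorted((r.rogid_a, r.rogid_b))), set()).add(i)
    for rigid, idx in table.complex_groups("rigid").items():
        members = sorted({table[i].rogid_b for i in idx})
        for pair in itertools.combinations(members, 2):
            support.setdefault(pair, set()).add(("C", rigid))
    expected = {k: len(v) for k, v in support.items()}
    got = {(a, b): w for a, b, w in e.df.itertuples(index=False)}
    assert got == expected
    assert int(e.df["weight"].sum()) == sum(expected.values())


def test_duplicate_records_raise_edge_weight(table, manifest):
    dup = next(e for e in manifest.records if e["class"] == "duplicate_binary")
    a, b = sorted(dup["rogids"])
    e = ik.mitab_to_edgelist(table, "exclude")
    row = e.df[(e.df["node_a"] == a) & (e.df["node_b"] == b)]
    assert int(row["weight"].iloc[0]) >= 2


def test_directed_orients_bait_to_prey(table, manifest):
    e = ik.mitab_to_edgelist(table, "exclude", directed=True, drop_undirected=True)
    screens = [x for x in manifest.records if x["class"] == "ht_screen"]
    directed_pairs = set(zip(e.df["node_a"], e.df["node_b"]))
    for s in screens:
        hub, prey = s["rogids"]
        assert (hub, prey) in directed_pairs or (prey, hub) in directed_pairs
        # bait is always the source
        assert (s["rogids"][0] if s["bait_side"] == "a" else s["rogids"][1],
                s["rogids"][1] if s["bait_side"] == "a" else s["rogids"][0]) \
            in directed_pairs


def test_directed_matrix_is_an_error(table):
    with pytest.raises(IrefkitError):
        ik.mitab_to_edgelist(table, "matrix", directed=True)


def test_bipartite_pseudo_node_naming(table):
    e = ik.mitab_to_edgelist(ik.select_interaction_type(table, {"complex"}),
                             "bipartite")
    pseudo = {n for n in set(e.df["node_a"]) | set(e.df["node_b"])
              if n.startswith("complex:")}
    assert pseudo == {f"complex:{rigid}" for rigid in table.complex_groups("rigid")}


def test_edgelist_roundtrip_recovers_binary_subset(table):
    e = ik.mitab_to_edgelist(table, "exclude", "rogid")
    back = ik.edgelist_to_mitab(e, table)
    assert back == ik.select_interaction_type(table, {"binary"})
    empty = ik.EdgeList(e.df.iloc[0:0], "rogid", "exclude", False)
    assert len(ik.edgelist_to_mitab(empty, table)) == 0


def test_edgelist_to_mitab_can_pull_complexes_whole(table):
    e = ik.mitab_to_edgelist(table, "bipartite", "rogid")
    back = ik.edgelist_to_mitab(e, table, include_complexes=True)
    c_rows = ik.select_interaction_type(table, {"complex"})
    assert set(id(r) for r in c_rows) <= set(id(r) for r in back)


def test_complexlist_roundtrip_recovers_c_rows(table, manifest):
    c = ik.mitab_to_complexlist(table, "rogid", include_regenerated="no")
    assert len(c) == len(manifest.reported_complexes)
    by_rigid = {e["rigid"]: e for e in manifest.reported_complexes}
    for row in c:
        assert row.origin == "reported"
        assert list(row.members) == by_rigid[row.complex_id]["members_rogid"]
    back = ik.complexlist_to_mitab(c, table)
    assert back == ik.select_interaction_type(table, {"complex"})
    assert len(ik.complexlist_to_mitab(ComplexList([], "rogid"), table)) == 0


def test_complexlist_with_regenerated_rows(table, manifest):
    c = ik.mitab_to_complexlist(table, "rogid", include_regenerated="yes")
    regen = [r for r in c if r.origin == "regenerated"]
    assert len(regen) == len(manifest.spoke_complexes)
    planted = {tuple(s["members_rogid"]): s for s in manifest.spoke_complexes}
    for row in regen:
        assert row.members in planted
        # supporting records are exactly the planted spoke rows
        assert sorted(row.support) == planted[row.members]["record_indices"]
    back = ik.complexlist_to_mitab(c, table, include_regenerated=True)
    spoke_idx = {i for s in manifest.spoke_complexes for i in s["record_indices"]}
    c_idx = {i for i, r in enumerate(table) if r.edgetype == "C"}
    assert {id(r) for r in back} == {id(table[i]) for i in spoke_idx | c_idx}


def test_merge_complex_lists_dedups_on_member_set():
    rows_a = [ComplexRow("c1", ("A", "B", "C"), "reported", 3),
              ComplexRow("c2", ("B", "C", "D"), "reported", 3)]
    rows_b = [ComplexRow("x1", ("B", "C", "D"), "regenerated", 3),
              ComplexRow("x2", ("D", "E", "F"), "regenerated", 3)]
    a, b = ComplexList(rows_a), ComplexList(rows_b)
    merged = ik.merge_complex_lists(a, b)
    assert len(merged) == 3  # one shared member set
    assert merged.rows[1].complex_id == "c2"  # first occurrence kept
    assert ik.merge_complex_lists(a, a).rows == a.rows
    ab = {r.members for r in ik.merge_complex_lists(a, b)}
    ba = {r.members for r in ik.merge_complex_lists(b, a)}
    assert ab == ba


def test_graph_roundtrip_identity(table):
    for policy, directed in [("spoke", False), ("exclude", True), ("matrix", False)]:
        e = ik.mitab_to_edgelist(table, policy, directed=directed)
        g = ik.edgelist_to_graph(e)
        back = ik.graph_to_edgelist(g)
        assert back.df.equals(e.df)
        assert (back.id_level, back.nary_policy, back.directed) == \
            (e.id_level, e.nary_policy, e.directed)
        assert g.number_of_nodes() == len(set(e.df["node_a"]) | set(e.df["node_b"]))
        assert g.number_of_edges() == len(e)


def test_canonical_level_never_larger(table):
    for policy in ("exclude", "spoke", "matrix"):
        er = ik.mitab_to_edgelist(table, policy, "rogid")
        ec = ik.mitab_to_edgelist(table, policy, "crogid")
        nodes = lambda e: set(e.df["node_a"]) | set(e.df["node_b"])
        assert len(nodes(ec)) <= len(nodes(er))
        assert len(ec) <= len(er)


def test_merge_rejects_mixed_id_levels():
    a = ComplexList([], "rogid")
    b = ComplexList([], "crogid")
    with pytest.raises(IrefkitError):
        ik.merge_complex_lists(a, b)
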