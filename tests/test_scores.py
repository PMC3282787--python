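"""Bibliometric scores (np/lpr/hpr), throughput partition, summaries."""

import networkx as nx
import numpy as np
import pytest

import irefkit as ik
from irefkit.fixtures import FixtureConfig
from irefkit.mitab import MitabTable
from conftest import small_config


def brute_force_scores(t):
    """Oracle: double loop over records and publications."""
    rigids = sorted({r.rigid for r in t if r.rigid and r.pmids})
    out = {}
    for rigid in rigids:
        pmids = set()
        for r in t:
            if r.rigid == rigid:
                pmids.update(r.pmids)
        reuse = []
        for p in pmids:
            supported = set()
            for r in t:
                if p in r.pmids and r.rigid is not None:
                    supported.add(r.rigid)
            reuse.append(len(supported))
        out[rigid] = (len(pmids), min(reuse), max(reuse))
    return out


def test_single_unique_record_scores_one_one_one(table):
    import dataclasses
    rec = dataclasses.replace(table[0], pmids=(123,))
    st = ik.compute_bibliometric_scores(MitabTable([rec]))
    assert st.as_dict() == {rec.rigid: (1, 1, 1)}


def test_scores_equal_brute_force_oracle(table):
    assert ik.compute_bibliometric_scores(table).as_dict() == brute_force_scores(table)


@pytest.mark.parametrize("i", range(6))
def test_scores_oracle_on_random_fixtures(i):
    t, man = ik.generate_mitab(small_config(i), seed=300 + i)
    got = ik.compute_bibliometric_scores(t).as_dict()
    assert got == brute_force_scores(t)
    assert got == man.scores


def test_score_invariants(table):
    for rigid, (np_, lpr, hpr) in ik.compute_bibliometric_scores(table).as_dict().items():
        assert np_ >= 1 and 1 <= lpr <= hpr
        if np_ == 1:
            assert lpr == hpr


def test_unsupported_records_get_no_score_row(table):
    import dataclasses
    rec = dataclasses.replace(table[0], pmids=())
    st = ik.compute_bibliometric_scores(MitabTable([rec]))
    assert len(st) == 0


def test_fresh_pmid_does_not_raise_other_lpr(table):
    """Adding a record citing a fresh pmid never increases lpr elsewhere."""
    import dataclasses
    before = ik.compute_bibliometric_scores(table).as_dict()
    extra = dataclasses.replace(table[0], pmids=(99999999,),
                                interaction_ids=(("rigid", "NEW-RIGID"),))
    after = ik.compute_bibliometric_scores(
        MitabTable(list(table.records) + [extra])).as_dict()
    for rigid, (_, lpr, _) in before.items():
        assert after[rigid][1] <= lpr


def test_throughput_partition(table):
    part = ik.classify_throughput(table)
    assert len(part.low) + len(part.high) + len(part.unscored) == len(table)
    assert len(ik.classify_throughput(table, threshold=10**9).high) == 0


def test_planted_screen_is_high_throughput():
    cfg = FixtureConfig(n_binary=0, n_ht_screens=1, ht_screen_size=30,
                        n_reported_complexes=0, n_spoke_complexes=0,
                        n_polymers=0, isoform_group_sizes=(),
                        n_proteins=40, duplicate_fraction=0.0)
    t, _ = ik.generate_mitab(cfg, seed=11)
    part = ik.classify_throughput(t)
    assert len(part.high) == len(t) == 30
    assert len(part.low) == 0


def test_file_score_mode_agrees_with_recomputation(table):
    # the generator writes recomputed scores into the confidence column
    a = ik.classify_throughput(table, use_file_scores=False)
    b = ik.classify_throughput(table, use_file_scores=True)
    assert a.low.records == b.low.records
    assert a.high.records == b.high.records


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summary_empty_table_is_all_zero():
    rep = ik.summary_table(MitabTable())
    assert rep["n_records"] == 0
    assert rep["distinct_rogids"] == rep["distinct_rigids"] == 0
    assert sum(rep["records_by_type"].values()) == 0


def test_summary_table_matches_manifest(table, manifest):
    rep = ik.summary_table(table, taxid=4932)
    assert rep["n_records"] == manifest.counts["records"]
    assert rep["records_by_type"]["binary"] == manifest.counts["binary"]
    assert rep["records_by_type"]["complex"] == manifest.counts["complex_rows"]
    assert sum(rep["records_by_db"].values()) == rep["n_records"]
    n_inter = sum(1 for e in manifest.records
                  if e["edgetype"] != "C" and 4932 in e["taxa"]
                  and set(e["taxa"]) != {4932})
    assert rep["records_interspecies"] == n_inter
    assert rep["distinct_rogids"] >= rep["distinct_crogids"]


def test_summary_protein(table, manifest):
    absent = ik.summary_protein(table, "no-such-id")
    assert absent["n_records"] == absent["n_partners"] == 0
    screen = next(e for e in manifest.records if e["class"] == "ht_screen")
    hub = screen["rogids"][0]
    rep = ik.summary_protein(table, hub)
    hub_records = [e for e in manifest.records
                   if hub in e["rogids"] and e["edgetype"] != "C"]
    partners = {r for e in hub_records for r in e["rogids"] if r != hub}
    assert rep["n_partners"] == len(partners)
    assert rep["n_partners"] <= rep["n_records"]


def test_summary_graph_closed_forms():
    path = nx.path_graph(["a", "b", "c"])
    s = ik.summary_graph(path)
    assert (s.n, s.dmax) == (3, 2)
    assert s.dav == pytest.approx(4 / 3)
    assert s.dvar == pytest.approx(np.var([1, 2, 1]))
    star = nx.star_graph(4)  # hub + 4 leaves
    s = ik.summary_graph(star)
    assert (s.n, s.dmax) == (5, 4)
    assert s.dav == pytest.approx(8 / 5)


@pytest.mark.parametrize("seed", range(5))
def test_summary_graph_matches_hand_recomputation(seed):
    g = nx.gnp_random_graph(40, 0.12, seed=seed)
    s = ik.summary_graph(g)
    deg = {v: 0 for v in g.nodes}
    for a, b in g.edges:
        deg[a] += 1
        deg[b] += 1
    vals = np.array(list(deg.values()), float)
    assert s.n == len(vals)
    assert s.dav == pytest.approx(vals.mean())
    assert s.dvar == pytest.approx(vals.var())
    assert s.dmax == vals.max()
    assert s.dav == pytest.approx(2 * g.number_of_edges() / g.number_of_nodes())


def test_summary_graph_fills_counts_from_table(table, manifest):
    g = ik.edgelist_to_graph(ik.mitab_to_edgelist(table, "spoke"))
    s = ik.summary_graph(g, table=table)
    assert s.C == len(manifest.reported_complexes)
    assert s.I == len(ik.distinct_interactions(table, "rigid"))
    assert s.X == len(ik.distinct_interactions(
        ik.select_interaction_type(table, {"binary"}), "rigid"))


def test_spoke_mean_degree_not_above_matrix(table):
    g_s = ik.edgelist_to_graph(ik.mitab_to_edgelist(table, "spoke"))
    g_m = ik.edgelist_to_graph(ik.mitab_to_edgelist(table, "matrix"))
    assert ik.summary_graph(g_s).dav <= ik.summary_graph(g_m).dav
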