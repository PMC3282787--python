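"""Regeneration of spoke-represented complexes and size-distribution comparison."""

import subprocess
import textwrap

import numpy as np
import pytest

import irefkit as ik
from irefkit.errors import IrefkitError
from irefkit.mitab import MI_BAIT, MitabTable, classify_record
from irefkit.regeneration import DEFAULT_NARY_METHODS
from conftest import small_config


def brute_force_bait_grouping(t, allowed_methods, min_members=3):
    """Independent oracle: enumerate (db, pmid, method, bait) groups directly."""
    allowed = {c.upper() for c in allowed_methods}
    groups = {}
    for i, r in enumerate(t):
        if classify_record(r) != "binary" or r.method is None:
            continue
        if r.method.code.upper() not in allowed or len(r.pmids) != 1:
            continue
        if r.role_a is not None and r.role_a.code == MI_BAIT:
            bait, prey = r.rogid_a, r.rogid_b
        elif r.role_b is not None and r.role_b.code == MI_BAIT:
            bait, prey = r.rogid_b, r.rogid_a
        else:
            continue
        db = r.source_db.code.upper()
        groups.setdefault((db, r.pmids[0], r.method.code.upper(), bait),
                          set()).add(prey)
    out = set()
    for (db, pmid, method, bait), preys in groups.items():
        members = tuple(sorted({bait} | preys))
        if len(members) >= min_members:
            out.add(members)
    return out


def test_planted_spoke_complexes_are_recovered_exactly(table, manifest):
    found = ik.regenerate_complexes(table, DEFAULT_NARY_METHODS, require_bait=True)
    planted = {tuple(s["members_rogid"]) for s in manifest.spoke_complexes}
    assert {c.members for c in found} == planted
    by_members = {tuple(s["members_rogid"]): s for s in manifest.spoke_complexes}
    for c in found:
        s = by_members[c.members]
        assert c.hub == s["hub_rogid"]
        assert c.pmid == s["pmid"]
        assert c.method == s["method"]
        assert list(c.support) == s["record_indices"]
        # star property: every supporting record contains the hub
        for i in c.support:
            assert c.hub in (table[i].rogid_a, table[i].rogid_b)


def test_oracle_equivalence_on_random_fixtures():
    for i in range(25):
        t, man = ik.generate_mitab(small_config(i), seed=100 + i)
        found = {c.members for c in
                 ik.regenerate_complexes(t, DEFAULT_NARY_METHODS, require_bait=True)}
        oracle = brute_force_bait_grouping(t, DEFAULT_NARY_METHODS)
        planted = {tuple(s["members_rogid"]) for s in man.spoke_complexes}
        assert found == oracle == planted


def test_output_invariant_under_row_permutation(table):
    base = ik.regenerate_complexes(table, DEFAULT_NARY_METHODS, require_bait=True)
    rng = np.random.default_rng(9)
    perm = rng.permutation(len(table))
    shuffled = MitabTable([table[int(i)] for i in perm], dict(table.meta))
    again = ik.regenerate_complexes(shuffled, DEFAULT_NARY_METHODS, require_bait=True)
    assert {(c.members, c.hub, c.pmid) for c in base} == \
        {(c.members, c.hub, c.pmid) for c in again}


def test_conservative_preset_is_a_restriction(table, manifest):
    permissive = {c.members for c in
                  ik.regenerate_complexes(table, DEFAULT_NARY_METHODS)}
    cons = ik.conservative_preset(table)
    assert {c.members for c in cons} <= permissive
    expected = {tuple(s["members_rogid"]) for s in manifest.spoke_complexes
                if s["db"] == "biogrid" and s["method"] == "MI:0004"}
    assert {c.members for c in cons} == expected
    assert all(c.source_db == "MI:0463" for c in cons)


def test_conservative_preset_empty_without_biogrid(table):
    no_biogrid = ik.select_database(table, ["biogrid"], exclude=True)
    assert ik.conservative_preset(no_biogrid) == []


def test_unshared_binary_records_yield_no_complex(table):
    # three records, same (db, pmid, method), but no common protein
    recs = []
    binaries = [r for r in table if r.edgetype == "X"]
    seen = set()
    for r in binaries:
        if r.rogid_a in seen or r.rogid_b in seen:
            continue
        seen.update((r.rogid_a, r.rogid_b))
        import dataclasses
        recs.append(dataclasses.replace(
            r, pmids=(7777,), method=ik.MITerm("MI:0004", "affinity chromatography"),
            source_db=ik.MITerm("MI:0463", "biogrid")))
        if len(recs) == 3:
            break
    t = MitabTable(recs)
    assert ik.regenerate_complexes(t, ["MI:0004"], require_bait="auto") == []


def test_greedy_mode_matches_bait_mode_on_clean_stars(table, manifest):
    """Without role information the greedy hub search finds the same stars."""
    import dataclasses
    stripped = MitabTable(
        [dataclasses.replace(r, role_a=None, role_b=None) for r in table],
        dict(table.meta))
    greedy = ik.regenerate_complexes(stripped, DEFAULT_NARY_METHODS,
                                     require_bait=False)
    planted = {tuple(s["members_rogid"]) for s in manifest.spoke_complexes}
    assert {c.members for c in greedy} == planted


def test_multi_pmid_records_are_excluded(table):
    import dataclasses
    spoke_like = [r for r in table if r.edgetype == "X"
                  and r.method.code in DEFAULT_NARY_METHODS]
    doctored = MitabTable(
        [dataclasses.replace(r, pmids=r.pmids + (1,)) for r in spoke_like])
    assert ik.regenerate_complexes(doctored, DEFAULT_NARY_METHODS) == []


def test_empty_method_list_is_an_error(table):
    with pytest.raises(IrefkitError):
        ik.regenerate_complexes(table, [])


def test_throughput_classification_of_regenerated(table):
    # planted spoke groups come from single-paper pulldowns: low-throughput
    for c in ik.regenerate_complexes(table, DEFAULT_NARY_METHODS):
        assert c.throughput == "low"


# ---------------------------------------------------------------------------
# size distributions
# ---------------------------------------------------------------------------

def _ks_oracle(xs, ys):
    """Brute-force two-sample KS D: scan all observed values."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    best = 0.0
    for v in np.unique(np.concatenate([xs, ys])):
        d = abs(np.mean(xs <= v) - np.mean(ys <= v))
        best = max(best, d)
    return best


class _Fake:
    def __init__(self, n):
        self.members = tuple(f"m{i}" for i in range(n))


def test_size_distribution_histogram(table):
    regen = ik.regenerate_complexes(table, DEFAULT_NARY_METHODS)
    hist = ik.size_distribution(regen)
    assert sum(hist.values()) == len(regen)
    assert all(k >= 3 for k in hist)


def test_compare_identical_samples_gives_zero_D():
    a = [_Fake(n) for n in (3, 4, 4, 5, 9)]
    D, p = ik.compare_size_distributions(a, a)
    assert D == 0.0
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_compare_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    a = [_Fake(int(n)) for n in rng.integers(3, 30, size=40)]
    b = [_Fake(int(n)) for n in rng.integers(3, 15, size=55)]
    D, p = ik.compare_size_distributions(a, b)
    assert 0.0 <= D <= 1.0 and 0.0 <= p <= 1.0
    assert D == pytest.approx(_ks_oracle([len(x.members) for x in a],
                                         [len(x.members) for x in b]))


def test_compare_matches_r_ks_test():
    """Cross-check D and p against R's ks.test on a fixed tie-free pair
    (with ties, R and scipy use different tie corrections for p, so the exact
    comparison is made where the null distribution is unambiguous)."""
    xs = [3, 5, 9, 13, 17, 21, 25, 29, 33, 41]
    ys = [4, 6, 8, 12, 20, 28, 36, 44]
    a, b = [_Fake(n) for n in xs], [_Fake(n) for n in ys]
    D, p = ik.compare_size_distributions(a, b)
    script = textwrap.dedent(f"""
        r <- ks.test(c({",".join(map(str, xs))}), c({",".join(map(str, ys))}))
        cat(r$statistic, format(r$p.value, digits = 15))
    """)
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    r_D, r_p = map(float, out.stdout.split()[-2:])
    assert D == pytest.approx(r_D, abs=1e-12)
    assert p == pytest.approx(r_p, rel=1e-9)


def test_compare_empty_sample_is_an_error():
    with pytest.raises(IrefkitError):
        ik.compare_size_distributions([], [_Fake(3)])
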