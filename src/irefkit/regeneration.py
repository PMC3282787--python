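"""Detection of spoke-represented complexes hidden in binary records.

Some source databases (BioGrid in particular) curate co-purification
experiments — which observe a whole protein group at once — as lists of
binary records radiating from the bait.  Such a group can be recognised and
the n-ary record regenerated: its binary records all (1) come from the same
database and the same publication, (2) carry an experimental method known to
produce n-ary data (e.g. affinity chromatography), and (3) share one protein,
the hub of the spoke model, which is the bait when role information exists.

Small regenerated complexes can be false positives (independent binary
observations that happen to share a protein and method); confirming them
requires reading the original paper, which is out of scope here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from scipy import stats

from .errors import IrefkitError
from .mitab import MI_BAIT, MitabTable, classify_record
from .representations import regen_complex_id
from .scores import compute_bibliometric_scores

#: detection-method codes that produce n-ary (co-complex) evidence
DEFAULT_NARY_METHODS = (
    "MI:0004",  # affinity chromatography technology
    "MI:0006",  # anti bait coimmunoprecipitation
    "MI:0007",  # anti tag coimmunoprecipitation
    "MI:0019",  # coimmunoprecipitation
    "MI:0027",  # cosedimentation
    "MI:0096",  # pull down
    "MI:0676",  # tandem affinity purification
)


@dataclass(frozen=True)
class RegeneratedComplex:
    complex_id: str
    hub: str
    members: tuple[str, ...]  # sorted, hub included
    source_db: str  # MI code of the curating database
    pmid: int
    method: str  # MI code
    support: tuple[int, ...]  # record indices in the source table
    throughput: str  # "low" | "high" | "unknown"


def _throughput(lprs: list[float | None], threshold: int) -> str:
    known = [v for v in lprs if v is not None]
    if not known or len(known) < len(lprs):
        return "unknown"
    if max(known) <= threshold:
        return "low"
    if min(known) > threshold:
        return "high"
    return "unknown"


def regenerate_complexes(t: MitabTable, allowed_methods,
                         require_bait="auto", min_members: int = 3,
                         id_level: str = "rogid", dbs=None,
                         lpr_threshold: int = 21,
                         overlapping: bool = False) -> list[RegeneratedComplex]:
    """Regenerate candidate n-ary records from binary records.

    Binary records with a method in ``allowed_methods`` and exactly one
    supporting publication are grouped by (source db, pmid, method).  Within a
    group, ``require_bait=True`` forms one complex per bait ({bait} ∪ its
    preys); ``False`` greedily picks the most frequent protein as hub
    (lexicographic tie-break), assigns and removes its records, and repeats;
    ``"auto"`` uses the bait path when any record of the group carries bait
    information, else the greedy path.  Complexes smaller than ``min_members``
    are discarded.  ``overlapping=True`` lets greedy hubs share records
    instead of consuming them.
    """
    allowed = {c.strip().upper() for c in allowed_methods}
    if not allowed:
        raise IrefkitError("allowed_methods must be nonempty")
    if require_bait not in (True, False, "auto"):
        raise IrefkitError(f"require_bait must be True/False/'auto', got {require_bait!r}")
    db_filter = None
    if dbs is not None:
        from .selection import DB_CODES, _canon_db
        db_filter = set()
        for d in dbs:
            d = d.strip()
            if d.upper().startswith("MI:"):
                db_filter.add(d.upper())
            else:
                label = _canon_db(d)
                db_filter.add(DB_CODES.get(label, label))

    scores = compute_bibliometric_scores(t)
    lpr_of = dict(zip(scores.df["rigid"], scores.df["lpr"])) if len(scores.df) else {}

    groups: dict[tuple[str, int, str], list[int]] = {}
    for i, r in enumerate(t):
        if classify_record(r) != "binary":
            continue
        if r.method is None or r.method.code.upper() not in allowed:
            continue
        if len(r.pmids) != 1:
            continue  # multi-paper records would double-count per-paper groups
        if r.source_db is None:
            continue
        db = r.source_db.code.upper() if r.source_db.code else r.source_db.label.lower()
        if db_filter is not None and db not in db_filter:
            continue
        a = r.interactor_key("a", id_level)
        b = r.interactor_key("b", id_level)
        if a is None or b is None:
            continue
        groups.setdefault((db, r.pmids[0], r.method.code.upper()), []).append(i)

    out: list[RegeneratedComplex] = []
    for (db, pmid, method), indices in groups.items():
        indices = sorted(indices)

        def keys(i: int) -> tuple[str, str]:
            r = t[i]
            return (r.interactor_key("a", id_level), r.interactor_key("b", id_level))

        def bait_of(i: int) -> str | None:
            r = t[i]
            if r.role_a is not None and r.role_a.code == MI_BAIT:
                return keys(i)[0]
            if r.role_b is not None and r.role_b.code == MI_BAIT:
                return keys(i)[1]
            return None

        has_bait = any(bait_of(i) is not None for i in indices)
        use_bait = require_bait is True or (require_bait == "auto" and has_bait)

        stars: list[tuple[str, list[int]]] = []
        if use_bait:
            by_bait: dict[str, list[int]] = {}
            for i in indices:
                bait = bait_of(i)
                if bait is not None:
                    by_bait.setdefault(bait, []).append(i)
            stars = sorted(by_bait.items())
        elif overlapping:
            counts: Counter[str] = Counter()
            for i in indices:
                a, b = keys(i)
                counts[a] += 1
                if b != a:
                    counts[b] += 1
            stars = [
                (hub, [i for i in indices if hub in keys(i)])
                for hub in sorted(counts)
                if counts[hub] >= 2
            ]
        else:
            remaining = list(indices)
            while remaining:
                counts = Counter()
                for i in remaining:
                    a, b = keys(i)
                    counts[a] += 1
                    if b != a:
                        counts[b] += 1
                hub = min(counts, key=lambda p: (-counts[p], p))
                assigned = [i for i in remaining if hub in keys(i)]
                stars.append((hub, assigned))
                remaining = [i for i in remaining if i not in set(assigned)]

        for hub, rec_indices in stars:
            members = {hub}
            for i in rec_indices:
                members.update(keys(i))
            if len(members) < min_members:
                continue
            members_t = tuple(sorted(members))
            lprs = [lpr_of.get(t[i].rigid) for i in rec_indices]
            out.append(RegeneratedComplex(
                complex_id=regen_complex_id(db, pmid, method, members_t),
                hub=hub,
                members=members_t,
                source_db=db,
                pmid=pmid,
                method=method,
                support=tuple(sorted(rec_indices)),
                throughput=_throughput(lprs, lpr_threshold),
            ))
    out.sort(key=lambda c: (c.source_db, c.pmid, c.method, c.hub))
    return out


def conservative_preset(t: MitabTable, id_level: str = "rogid",
                        min_members: int = 3) -> list[RegeneratedComplex]:
    """The conservative regeneration setting: BioGrid records with affinity
    chromatography (MI:0004) only, bait-driven where bait roles exist."""
    return regenerate_complexes(
        t, ["MI:0004"], require_bait="auto", min_members=min_members,
        id_level=id_level, dbs=["biogrid"],
    )


def _sizes(complexes) -> list[int]:
    return [len(c.members) for c in complexes]


def size_distribution(complexes) -> dict[int, int]:
    """Histogram of complex sizes (member counts)."""
    return dict(sorted(Counter(_sizes(complexes)).items()))


def compare_size_distributions(a, b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on member-count samples.

    Accepts lists of complexes (anything with ``.members``); returns (D, p).
    """
    xs, ys = _sizes(a), _sizes(b)
    if not xs or not ys:
        raise IrefkitError("both samples must be nonempty")
    res = stats.ks_2samp(xs, ys, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


__all__ = [
    "RegeneratedComplex", "DEFAULT_NARY_METHODS",
    "regenerate_complexes", "conservative_preset",
    "size_distribution", "compare_size_distributions",
]
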