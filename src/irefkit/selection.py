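"""Pure filtering operators over a :class:`~irefkit.mitab.MitabTable`.

Every selector returns a new sub-table without mutating the input and
preserves the original record order, so selectors are idempotent and commute
with one another.  Complex (edgetype ``C``) records are treated as units:
whenever a member line matches (or fails) a protein or taxon criterion, all
lines sharing that RIGID are included (or excluded) together — a partial
complex is meaningless downstream.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable

from .errors import IrefkitError
from .mitab import MitabRecord, MitabTable, classify_record

log = logging.getLogger(__name__)

INTERACTION_KINDS = frozenset({"binary", "complex", "polymer"})

#: source-database label aliases seen across releases, lower-cased
DB_ALIASES = {
    "grid": "biogrid",
    "mpact": "mpact",
    "intact": "intact",
}

#: label -> MI code for the primary databases consolidated by iRefIndex
DB_CODES = {
    "bind": "MI:0462",
    "biogrid": "MI:0463",
    "dip": "MI:0465",
    "hprd": "MI:0468",
    "intact": "MI:0469",
    "mint": "MI:0471",
    "mpact": "MI:0903",
}

_MI_CODE_RE = re.compile(r"^MI:\d{4}$", re.IGNORECASE)


def _subset(t: MitabTable, keep: Iterable[bool]) -> MitabTable:
    return t.subset([i for i, k in enumerate(keep) if k])


def _whole_complexes(t: MitabTable, keep: list[bool]) -> list[bool]:
    """Promote per-line marks so every C group is kept or dropped whole."""
    groups = t.complex_groups("rigid")
    for indices in groups.values():
        if any(keep[i] for i in indices):
            for i in indices:
                keep[i] = True
    return keep


def select_interaction_type(t: MitabTable, kinds) -> MitabTable:
    """Keep records of the requested kinds (binary / complex / polymer)."""
    kinds = set(kinds)
    if not kinds:
        raise IrefkitError("kinds must be a nonempty subset of binary/complex/polymer")
    unknown = kinds - INTERACTION_KINDS
    if unknown:
        raise IrefkitError(f"unknown interaction kinds: {sorted(unknown)}")
    return _subset(t, (classify_record(r) in kinds for r in t))


def _canon_db(token: str) -> str:
    token = token.strip().lower()
    return DB_ALIASES.get(token, token)


def _record_matches_db(r: MitabRecord, codes: set[str], labels: set[str]) -> bool:
    if r.source_db is None:
        return False
    if r.source_db.code and r.source_db.code.upper() in codes:
        return True
    return _canon_db(r.source_db.label) in labels


def select_database(t: MitabTable, dbs, exclude: bool = False) -> MitabTable:
    """Keep (or, with ``exclude``, drop) records from the named source databases.

    Entries may be MI codes (``MI:0463``) or case-insensitive labels
    (``biogrid``, alias ``grid``).  Unknown names simply match nothing.
    """
    dbs = list(dbs)
    if not dbs:
        raise IrefkitError("dbs must be nonempty")
    codes: set[str] = set()
    labels: set[str] = set()
    for d in dbs:
        if _MI_CODE_RE.match(d.strip()):
            codes.add(d.strip().upper())
        else:
            label = _canon_db(d)
            labels.add(label)
            if label in DB_CODES:
                codes.add(DB_CODES[label])
    # resolve codes back to labels too, so "MI:0463" matches a label-only record
    for label, code in DB_CODES.items():
        if code in codes:
            labels.add(label)
    keep = [_record_matches_db(r, codes, labels) != exclude for r in t]
    if not exclude and not any(keep):
        log.info("select_database: no records matched %r", dbs)
    return _subset(t, keep)


def select_protein(t: MitabTable, ids, id_level: str = "rogid") -> MitabTable:
    """Keep records that involve any of the given protein ids at the id level.

    Complex member lines match via the member side and pull in their whole
    complex.
    """
    ids = set(ids)
    if not ids:
        raise IrefkitError("ids must be nonempty")
    keep = []
    for r in t:
        ka = r.interactor_key("a", id_level)
        kb = r.interactor_key("b", id_level)
        keep.append((ka in ids) or (kb in ids))
    return _subset(t, _whole_complexes(t, keep))


def select_publication(t: MitabTable, pmids) -> MitabTable:
    """Keep records whose PubMed id list intersects the query."""
    query = set(int(p) for p in pmids)
    return _subset(t, (bool(query.intersection(r.pmids)) for r in t))


def select_method(t: MitabTable, mi_codes) -> MitabTable:
    """Keep records whose interaction-detection method code is listed.

    Records with an absent method never match.
    """
    codes = {c.strip().upper() for c in mi_codes}
    return _subset(
        t,
        (r.method is not None and r.method.code.upper() in codes for r in t),
    )


def select_confidence(t: MitabTable, score: str, lo: float, hi: float) -> MitabTable:
    """Keep records whose stored ``score`` (np/lpr/hpr) lies in [lo, hi]."""
    if score not in ("np", "lpr", "hpr"):
        raise IrefkitError(f"unknown score type: {score!r}")
    if lo > hi:
        raise IrefkitError(f"empty score range: lo={lo} > hi={hi}")

    def ok(r: MitabRecord) -> bool:
        v = r.confidence.get(score)
        return v is not None and lo <= v <= hi

    return _subset(t, (ok(r) for r in t))


def select_taxon(t: MitabTable, taxid: int, mode: str = "at_least_one") -> MitabTable:
    """Keep records by interactor taxon.

    ``at_least_one``
        either side is from ``taxid`` (the complex pseudo-node side carries no
        taxon and is ignored; a complex is kept whole if any member matches).
    ``all_interactors``
        every interactor is from ``taxid``; a complex is kept only when every
        member line matches.
    """
    if mode not in ("at_least_one", "all_interactors"):
        raise IrefkitError(f"unknown taxon mode: {mode!r}")
    taxid = int(taxid)
    if mode == "at_least_one":
        keep = [r.taxon_a == taxid or r.taxon_b == taxid for r in t]
        return _subset(t, _whole_complexes(t, keep))
    keep = []
    for r in t:
        if classify_record(r) == "complex":
            keep.append(r.taxon_b == taxid)  # pseudo-node side has no taxon
        else:
            keep.append(r.taxon_a == taxid and r.taxon_b == taxid)
    # a complex is all-from-taxid only if every member line is
    groups = t.complex_groups("rigid")
    for indices in groups.values():
        ok = all(keep[i] for i in indices)
        for i in indices:
            keep[i] = ok
    return _subset(t, keep)


__all__ = [
    "select_interaction_type", "select_database", "select_protein",
    "select_publication", "select_method", "select_confidence", "select_taxon",
    "DB_CODES", "DB_ALIASES", "INTERACTION_KINDS",
]
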