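"""Accession lookup tables, identifier translation and distinct-entity counts.

iRefIndex resolves redundancy at two levels.  A ROGID digests a protein's
primary sequence plus taxon, so identical sequence records from different
source databases collapse to one key; a cROGID additionally collapses related
records (e.g. splice isoforms of one gene) to the ROGID of one chosen group
representative.  RIGIDs/cRIGIDs do the same for whole interactions.  Counting
at the canonical level therefore never yields more entities than at the
sequence-specific level.
"""

from __future__ import annotations

import base64
import hashlib
import re

import pandas as pd

from .errors import IntegrityError, IrefkitError
from .mitab import MitabRecord, MitabTable
from .selection import select_taxon

#: namespaces that are themselves redundancy keys, not external accessions
_KEY_NAMESPACES = frozenset({"rogid", "crogid", "irogid", "icrogid", "complex"})

#: accepted aliases for the gene-identifier namespace used in release files
GENEID_ALIASES = {"geneid": "entrezgene/locuslink"}


class IdMapping:
    """Rows of (rogid, crogid, namespace, accession), deduplicated and sorted."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def namespaces(self) -> set[str]:
        return set(self.df["namespace"]) | {"rogid", "crogid"}


def _harvest_side(r: MitabRecord, side: str):
    uid = r.uid_a if side == "a" else r.uid_b
    if uid.namespace == "complex":
        return None
    rogid = r.rogid_a if side == "a" else r.rogid_b
    crogid = r.crogid_a if side == "a" else r.crogid_b
    if rogid is None:
        return None
    if crogid is None:
        crogid = rogid
    refs = (uid,) + (r.alt_a + r.alias_a if side == "a" else r.alt_b + r.alias_b)
    rows = []
    for ref in refs:
        ns = GENEID_ALIASES.get(ref.namespace, ref.namespace)
        if ns in _KEY_NAMESPACES:
            continue
        rows.append((rogid, crogid, ns, ref.accession))
    return rows


def build_id_table(t: MitabTable) -> IdMapping:
    """Harvest every (rogid, crogid, namespace, accession) row from a table.

    Raises :class:`IntegrityError` if one ROGID is paired with two different
    cROGIDs anywhere in the table (the rogid→crogid relation must be a
    function).
    """
    rows: set[tuple[str, str, str, str]] = set()
    crogid_of: dict[str, str] = {}
    for r in t:
        for side in ("a", "b"):
            harvested = _harvest_side(r, side)
            if harvested is None:
                continue
            for rogid, crogid, ns, acc in harvested:
                seen = crogid_of.setdefault(rogid, crogid)
                if seen != crogid:
                    raise IntegrityError(
                        f"rogid {rogid} maps to both crogid {seen} and {crogid}")
                rows.add((rogid, crogid, ns, acc))
    df = pd.DataFrame(
        sorted(rows), columns=["rogid", "crogid", "namespace", "accession"]
    )
    return IdMapping(df)


def convert_protein_id(m: IdMapping, values, from_ns: str, to_ns: str) -> dict[str, list[str]]:
    """Translate identifiers between namespaces through the ROGID backbone.

    Every input value is keyed in the result; unmapped values map to an empty
    list; one-to-many translations return all targets sorted.
    """
    from_ns = GENEID_ALIASES.get(from_ns, from_ns)
    to_ns = GENEID_ALIASES.get(to_ns, to_ns)
    known = m.namespaces()
    for ns in (from_ns, to_ns):
        if ns not in known:
            raise IrefkitError(f"unknown namespace {ns!r}; known: {sorted(known)}")
    df = m.df
    out: dict[str, list[str]] = {}
    for value in values:
        value = str(value)
        if from_ns == "rogid":
            rogids = set(df.loc[df["rogid"] == value, "rogid"])
        elif from_ns == "crogid":
            rogids = set(df.loc[df["crogid"] == value, "rogid"])
        else:
            hit = (df["namespace"] == from_ns) & (df["accession"] == value)
            rogids = set(df.loc[hit, "rogid"])
        if not rogids:
            out[value] = []
            continue
        sub = df[df["rogid"].isin(rogids)]
        if to_ns == "rogid":
            targets = set(sub["rogid"])
        elif to_ns == "crogid":
            targets = set(sub["crogid"])
        else:
            targets = set(sub.loc[sub["namespace"] == to_ns, "accession"])
        out[value] = sorted(targets)
    return out


def distinct_proteins(t: MitabTable, level: str = "rogid",
                      scope: str = "any", taxid: int | None = None) -> set[str]:
    """Distinct interactor keys at the given redundancy level.

    ``scope="intra"`` restricts to records where all interactors are from
    ``taxid`` (complexes counted whole).  Complex pseudo-nodes are never
    counted as proteins.
    """
    if scope == "intra":
        if taxid is None:
            raise IrefkitError("intra-species scope requires a taxid")
        t = select_taxon(t, taxid, "all_interactors")
    elif scope != "any":
        raise IrefkitError(f"unknown scope: {scope!r}")
    keys: set[str] = set()
    for r in t:
        for side in ("a", "b"):
            k = r.interactor_key(side, level)
            if k is not None:
                keys.add(k)
    return keys


def distinct_interactions(t: MitabTable, level: str = "rigid") -> set[str]:
    """Distinct interaction keys (complexes counted once regardless of rows)."""
    keys: set[str] = set()
    for r in t:
        k = r.interaction_key(level)
        if k is not None:
            keys.add(k)
    return keys


# ---------------------------------------------------------------------------
# key computation (verification only; file-supplied keys are never replaced)
# ---------------------------------------------------------------------------

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYBJOUXZ]+$", re.IGNORECASE)


def compute_rogid(sequence: str, taxid: int) -> str:
    """ROGID of a protein: base64(SHA-1(uppercased sequence + taxid))."""
    if not sequence:
        raise IrefkitError("empty sequence")
    if not _AA_RE.match(sequence):
        raise IrefkitError("sequence contains non-amino-acid characters")
    digest = hashlib.sha1((sequence.upper() + str(int(taxid))).encode()).digest()
    return base64.b64encode(digest).decode()


def compute_rigid(rogids) -> str:
    """RIGID of an interaction: digest of the ascii-sorted concatenated ROGIDs.

    Sorting makes the key invariant under participant order.
    """
    rogids = list(rogids)
    if not rogids:
        raise IrefkitError("empty rogid list")
    digest = hashlib.sha1("".join(sorted(rogids)).encode()).digest()
    return base64.b64encode(digest).decode()


__all__ = [
    "IdMapping", "build_id_table", "convert_protein_id",
    "distinct_proteins", "distinct_interactions",
    "compute_rogid", "compute_rigid",
]
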