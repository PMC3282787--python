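"""Reading, writing and fetching interaction tables in the iRefIndex MITAB 2.6 dialect.

MITAB is the tab-delimited exchange format of HUPO PSI-MI: one interaction (or,
for n-ary records, one complex member) per line, ``|``-separated multi-values
and ``key:value`` tokens within fields, ``-`` for an absent value.  The
iRefIndex dialect adds consolidation keys: per-interactor ROGIDs (sequence +
taxon digest) and cROGIDs (canonical/isoform-group key), and per-record RIGIDs
and cRIGIDs derived from them.

Three record classes occur:

``X``
    ordinary binary interaction between two proteins;
``C``
    one member line of an n-ary (complex) record, bipartite-represented: the
    ``A`` slot holds a pseudo-node (``complex:<rigid>``) and the ``B`` slot one
    member; a complex with *m* members occupies *m* consecutive-keyed lines;
``Y``
    polymer record (a single interactor type, e.g. a homodimer).
"""

from __future__ import annotations

import gzip
import io
import logging
import re
import time
import urllib.request
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd

from .errors import DialectError, FetchError, MitabParseError

log = logging.getLogger(__name__)

ABSENT = "-"

# Experimental-role controlled-vocabulary codes used for directed graphs.
MI_BAIT = "MI:0496"
MI_PREY = "MI:0498"


# ---------------------------------------------------------------------------
# small value types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class InteractorRef:
    """A ``namespace:accession`` pair (e.g. ``uniprotkb:P38903``)."""

    namespace: str
    accession: str

    def __post_init__(self) -> None:
        if not self.namespace or not self.accession:
            raise ValueError("namespace and accession must be nonempty")

    def __str__(self) -> str:
        return f"{self.namespace}:{self.accession}"

    @classmethod
    def parse(cls, text: str) -> "InteractorRef":
        ns, sep, acc = text.partition(":")
        if not sep:
            raise ValueError(f"not a namespace:accession token: {text!r}")
        return cls(ns, acc)


_MI_RE = re.compile(r'^(?:psi-mi:)?"?(MI:\d{4})"?(?:\((.*)\))?$')


@dataclass(frozen=True, order=True)
class MITerm:
    """A PSI-MI controlled-vocabulary term: code plus free-text label."""

    code: str
    label: str = ""

    def __str__(self) -> str:
        return f"{self.code}({self.label})" if self.label else self.code

    @classmethod
    def parse(cls, text: str) -> "MITerm":
        m = _MI_RE.match(text.strip())
        if m:
            return cls(m.group(1), m.group(2) or "")
        # tolerate bare labels from lenient sources
        return cls("", text.strip())


# ---------------------------------------------------------------------------
# record / table
# ---------------------------------------------------------------------------

@dataclass
class MitabRecord:
    """One parsed MITAB line.

    ``interaction_ids`` is the ordered ``key:value`` list of the
    interactionIdentifier column and must contain a ``rigid`` entry for any
    record produced by iRefIndex; ``confidence`` holds the bibliometric scores
    (np/lpr/hpr) when supplied by the file.  ``extras`` preserves untyped
    dialect columns verbatim so that serialisation is lossless.
    """

    uid_a: InteractorRef
    uid_b: InteractorRef
    alt_a: tuple[InteractorRef, ...] = ()
    alt_b: tuple[InteractorRef, ...] = ()
    alias_a: tuple[InteractorRef, ...] = ()
    alias_b: tuple[InteractorRef, ...] = ()
    method: MITerm | None = None
    pmids: tuple[int, ...] = ()
    taxon_a: int | None = None
    taxon_b: int | None = None
    interaction_type: MITerm | None = None
    source_db: MITerm | None = None
    interaction_ids: tuple[tuple[str, str], ...] = ()
    confidence: dict[str, float] = field(default_factory=dict)
    expansion: str = "none"  # none | bipartite
    role_a: MITerm | None = None  # experimental role (bait/prey) of A
    role_b: MITerm | None = None
    edgetype: str | None = None  # X | C | Y
    num_participants: int = 2
    crogid_a: str | None = None
    crogid_b: str | None = None
    crigid: str | None = None
    extras: dict[str, str] = field(default_factory=dict)

    # -- derived keys ------------------------------------------------------

    def _rogid(self, uid: InteractorRef, aliases: tuple[InteractorRef, ...]) -> str | None:
        if uid.namespace == "rogid":
            return uid.accession
        if uid.namespace == "complex":
            return None
        for ref in aliases:
            if ref.namespace == "rogid":
                return ref.accession
        return None

    @property
    def rogid_a(self) -> str | None:
        return self._rogid(self.uid_a, self.alias_a)

    @property
    def rogid_b(self) -> str | None:
        return self._rogid(self.uid_b, self.alias_b)

    @property
    def rigid(self) -> str | None:
        for k, v in self.interaction_ids:
            if k == "rigid":
                return v
        return None

    def interactor_key(self, side: str, id_level: str) -> str | None:
        """ROGID or cROGID of side 'a' or 'b' (None for the complex pseudo-node)."""
        if id_level == "rogid":
            return self.rogid_a if side == "a" else self.rogid_b
        if id_level == "crogid":
            if side == "a":
                return self.crogid_a if self.uid_a.namespace != "complex" else None
            return self.crogid_b
        raise ValueError(f"unknown id level: {id_level!r}")

    def interaction_key(self, id_level: str) -> str | None:
        """RIGID or cRIGID of the record."""
        if id_level in ("rigid", "rogid"):
            return self.rigid
        if id_level in ("crigid", "crogid"):
            return self.crigid if self.crigid is not None else self.rigid
        raise ValueError(f"unknown id level: {id_level!r}")


def classify_record(record: MitabRecord) -> str:
    """Classify a record as ``binary``, ``complex`` or ``polymer``.

    Uses the edgetype column when present; otherwise falls back to structural
    rules (complex pseudo-node in slot A; identical ROGIDs on both sides).
    Total: never raises.
    """
    if record.edgetype == "C":
        return "complex"
    if record.edgetype == "Y":
        return "polymer"
    if record.edgetype == "X":
        return "binary"
    if record.uid_a.namespace == "complex":
        return "complex"
    if record.rogid_a is not None and record.rogid_a == record.rogid_b:
        return "polymer"
    return "binary"


class MitabTable:
    """An ordered collection of :class:`MitabRecord` with provenance metadata."""

    def __init__(self, records: Iterable[MitabRecord] = (), meta: dict | None = None):
        self.records: list[MitabRecord] = list(records)
        self.meta: dict = dict(meta or {})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MitabRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MitabRecord:
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MitabTable):
            return NotImplemented
        return self.records == other.records

    def __repr__(self) -> str:
        return f"MitabTable({len(self.records)} records, meta={self.meta!r})"

    def subset(self, indices: Iterable[int]) -> "MitabTable":
        """New table with the given record indices, order preserved, meta shared."""
        return MitabTable([self.records[i] for i in indices], dict(self.meta))

    def complex_groups(self, id_level: str = "rigid") -> dict[str, list[int]]:
        """Map (c)RIGID -> indices of edgetype-C member rows, in table order."""
        groups: dict[str, list[int]] = {}
        for i, r in enumerate(self.records):
            if classify_record(r) == "complex":
                key = r.interaction_key(id_level)
                if key is not None:
                    groups.setdefault(key, []).append(i)
        return groups

    def to_dataframe(self) -> pd.DataFrame:
        """Serialised view of the table as a pandas DataFrame (dialect columns)."""
        cols = self.meta.get("columns", DIALECTS[DEFAULT_DIALECT])
        rows = [_serialize_record(r, cols) for r in self.records]
        return pd.DataFrame(rows, columns=list(cols))


# ---------------------------------------------------------------------------
# column dialect registry
# ---------------------------------------------------------------------------

#: iRefIndex MITAB 2.6 column layout (releases 7.0 and 8.0 distribute the
#: same 41-column 2.6 layout).  Unknown extra columns in a real header are
#: carried through ``extras`` untouched.
IREFINDEX_26_COLUMNS: tuple[str, ...] = (
    "uidA", "uidB", "altA", "altB", "aliasA", "aliasB",
    "method", "author", "pmids", "taxa", "taxb",
    "interactionType", "sourcedb", "interactionIdentifier", "confidence",
    "expansion",
    "biological_role_A", "biological_role_B",
    "experimental_role_A", "experimental_role_B",
    "interactor_type_A", "interactor_type_B",
    "hostOrganismTaxid",
    "originalReferenceA", "originalReferenceB",
    "FinalReferenceA", "FinalReferenceB",
    "MappingScoreA", "MappingScoreB",
    "irogida", "irogidb", "irigid",
    "crogida", "crogidb", "crigid",
    "icrogida", "icrogidb", "icrigid",
    "imex_id", "edgetype", "numParticipants",
)

DIALECTS: dict[str, tuple[str, ...]] = {
    "irefindex-7.0": IREFINDEX_26_COLUMNS,
    "irefindex-8.0": IREFINDEX_26_COLUMNS,
}
DEFAULT_DIALECT = "irefindex-8.0"

#: minimum column set any recognisable header must provide
CORE_COLUMNS = frozenset({
    "uidA", "uidB", "method", "pmids", "taxa", "taxb",
    "sourcedb", "interactionIdentifier", "edgetype",
})

_TYPED_COLUMNS = frozenset({
    "uidA", "uidB", "altA", "altB", "aliasA", "aliasB", "method", "pmids",
    "taxa", "taxb", "interactionType", "sourcedb", "interactionIdentifier",
    "confidence", "expansion", "experimental_role_A", "experimental_role_B",
    "crogida", "crogidb", "crigid", "edgetype", "numParticipants",
})


# ---------------------------------------------------------------------------
# field parsing / serialisation helpers
# ---------------------------------------------------------------------------

def _absent(value: str | None) -> bool:
    return value is None or value == "" or value == ABSENT


def _split_multi(value: str) -> list[str]:
    if _absent(value):
        return []
    return [tok for tok in value.split("|") if not _absent(tok)]


_TAXID_RE = re.compile(r"^(?:taxid:)?(-?\d+)")


def _parse_taxid(value: str) -> int | None:
    if _absent(value):
        return None
    m = _TAXID_RE.match(value.strip())
    if not m:
        raise ValueError(f"unparseable taxon field: {value!r}")
    return int(m.group(1))


def _parse_pmids(value: str) -> tuple[int, ...]:
    out = []
    for tok in _split_multi(value):
        if ":" in tok:
            tok = tok.rsplit(":", 1)[1]
        out.append(int(tok))
    return tuple(out)


def _parse_confidence(value: str) -> dict[str, float]:
    scores: dict[str, float] = {}
    for tok in _split_multi(value):
        name, sep, num = tok.partition(":")
        if not sep:
            raise ValueError(f"confidence token without ':': {tok!r}")
        scores[name] = float(num)
    return scores


def _parse_kv_pairs(value: str) -> tuple[tuple[str, str], ...]:
    pairs = []
    for tok in _split_multi(value):
        k, sep, v = tok.partition(":")
        if not sep:
            raise ValueError(f"key:value token without ':': {tok!r}")
        pairs.append((k, v))
    return tuple(pairs)


def _parse_record(fields: dict[str, str]) -> MitabRecord:
    def get(col: str) -> str:
        return fields.get(col, ABSENT)

    def refs(col: str) -> tuple[InteractorRef, ...]:
        return tuple(InteractorRef.parse(t) for t in _split_multi(get(col)))

    def term(col: str) -> MITerm | None:
        v = get(col)
        return None if _absent(v) else MITerm.parse(v)

    def scalar(col: str) -> str | None:
        v = get(col)
        return None if _absent(v) else v

    npart_raw = get("numParticipants")
    edgetype = scalar("edgetype")
    if edgetype is not None and edgetype not in ("X", "C", "Y"):
        raise ValueError(f"unknown edgetype: {edgetype!r}")
    expansion_raw = scalar("expansion")
    expansion = "none" if expansion_raw in (None, "none") else expansion_raw
    if expansion not in ("none", "bipartite"):
        raise ValueError(f"unknown expansion model: {expansion!r}")

    extras = {
        col: val
        for col, val in fields.items()
        if col not in _TYPED_COLUMNS and not _absent(val)
    }
    return MitabRecord(
        uid_a=InteractorRef.parse(get("uidA")),
        uid_b=InteractorRef.parse(get("uidB")),
        alt_a=refs("altA"), alt_b=refs("altB"),
        alias_a=refs("aliasA"), alias_b=refs("aliasB"),
        method=term("method"),
        pmids=_parse_pmids(get("pmids")),
        taxon_a=_parse_taxid(get("taxa")),
        taxon_b=_parse_taxid(get("taxb")),
        interaction_type=term("interactionType"),
        source_db=term("sourcedb"),
        interaction_ids=_parse_kv_pairs(get("interactionIdentifier")),
        confidence=_parse_confidence(get("confidence")),
        expansion=expansion,
        role_a=term("experimental_role_A"),
        role_b=term("experimental_role_B"),
        edgetype=edgetype,
        num_participants=2 if _absent(npart_raw) else int(npart_raw),
        crogid_a=scalar("crogida"),
        crogid_b=scalar("crogidb"),
        crigid=scalar("crigid"),
        extras=extras,
    )


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _serialize_record(r: MitabRecord, columns: tuple[str, ...]) -> list[str]:
    def join(items: Iterable[object]) -> str:
        out = "|".join(str(i) for i in items)
        return out if out else ABSENT

    typed: dict[str, str] = {
        "uidA": str(r.uid_a),
        "uidB": str(r.uid_b),
        "altA": join(r.alt_a),
        "altB": join(r.alt_b),
        "aliasA": join(r.alias_a),
        "aliasB": join(r.alias_b),
        "method": str(r.method) if r.method else ABSENT,
        "pmids": join(f"pubmed:{p}" for p in r.pmids),
        "taxa": f"taxid:{r.taxon_a}" if r.taxon_a is not None else ABSENT,
        "taxb": f"taxid:{r.taxon_b}" if r.taxon_b is not None else ABSENT,
        "interactionType": str(r.interaction_type) if r.interaction_type else ABSENT,
        "sourcedb": str(r.source_db) if r.source_db else ABSENT,
        "interactionIdentifier": join(f"{k}:{v}" for k, v in r.interaction_ids),
        "confidence": join(f"{k}:{_fmt_number(v)}" for k, v in r.confidence.items()),
        "expansion": r.expansion if r.expansion != "none" else "none",
        "experimental_role_A": str(r.role_a) if r.role_a else ABSENT,
        "experimental_role_B": str(r.role_b) if r.role_b else ABSENT,
        "crogida": r.crogid_a if r.crogid_a is not None else ABSENT,
        "crogidb": r.crogid_b if r.crogid_b is not None else ABSENT,
        "crigid": r.crigid if r.crigid is not None else ABSENT,
        "edgetype": r.edgetype if r.edgetype is not None else ABSENT,
        "numParticipants": str(r.num_participants),
    }
    row = []
    for col in columns:
        if col in typed:
            row.append(typed[col])
        else:
            row.append(r.extras.get(col, ABSENT))
    return row


# ---------------------------------------------------------------------------
# stream plumbing (gzip / zip transparent)
# ---------------------------------------------------------------------------

def _open_text(source, mode: str = "rt"):
    """Open a path (gzip/zip-aware by extension) or pass through a file object."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    path = Path(source)
    name = path.name.lower()
    if name.endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8"), True
    if name.endswith(".zip"):
        if "r" not in mode:
            raise ValueError("zip output is not supported; use .gz")
        zf = zipfile.ZipFile(path)
        inner = zf.namelist()[0]
        return io.TextIOWrapper(zf.open(inner), encoding="utf-8"), True
    return open(path, mode, encoding="utf-8"), True


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def read_mitab(source, mode: str = "strict") -> MitabTable:
    """Parse a MITAB 2.6 stream or path into a :class:`MitabTable`.

    In ``strict`` mode any malformed line raises :class:`MitabParseError`;
    in ``lenient`` mode malformed lines are skipped and counted in
    ``meta["skipped_lines"]``.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode: {mode!r}")
    stream, owned = _open_text(source, "rt")
    try:
        header = stream.readline()
        if not header.strip():
            raise DialectError("missing MITAB header line")
        cols = tuple(header.lstrip("#").rstrip("\r\n").split("\t"))
        matches = [name for name, c in DIALECTS.items() if c == cols]
        dialect = (DEFAULT_DIALECT if DEFAULT_DIALECT in matches
                   else matches[0] if matches else None)
        if dialect is None:
            if CORE_COLUMNS <= set(cols):
                dialect = "custom"
            else:
                missing = sorted(CORE_COLUMNS - set(cols))
                raise DialectError(f"unrecognized MITAB header; missing columns {missing}")
        records: list[MitabRecord] = []
        skipped = 0
        for lineno, line in enumerate(stream, start=2):
            if not line.strip():
                continue
            values = line.rstrip("\r\n").split("\t")
            try:
                if len(values) != len(cols):
                    raise ValueError(
                        f"expected {len(cols)} columns, got {len(values)}")
                records.append(_parse_record(dict(zip(cols, values))))
            except (ValueError, KeyError) as exc:
                if mode == "strict":
                    raise MitabParseError(f"line {lineno}: {exc}") from exc
                skipped += 1
                log.warning("skipping malformed line %d: %s", lineno, exc)
        meta = {"dialect": dialect, "columns": cols, "skipped_lines": skipped}
        return MitabTable(records, meta)
    finally:
        if owned:
            stream.close()


def write_mitab(table: MitabTable, sink) -> int:
    """Serialise a table (header + one line per record); returns the data-line count."""
    cols = tuple(table.meta.get("columns", DIALECTS[DEFAULT_DIALECT]))
    stream, owned = _open_text(sink, "wt")
    try:
        stream.write("#" + "\t".join(cols) + "\n")
        n = 0
        for record in table.records:
            stream.write("\t".join(_serialize_record(record, cols)) + "\n")
            n += 1
        return n
    finally:
        if owned:
            stream.close()


# ---------------------------------------------------------------------------
# fetch
# ---------------------------------------------------------------------------

#: archive layout of the iRefIndex distribution site; the per-release file
#: date-code changes between builds, so ``filename`` may be overridden.
RELEASE_URLS = {
    "7.0": "ftp://ftp.no.embnet.org/irefindex/data/archive/release_7.0/psimi_tab/MITAB2.6",
    "8.0": "ftp://ftp.no.embnet.org/irefindex/data/archive/release_8.0/psimi_tab/MITAB2.6",
}


def fetch_irefindex(version: str, taxon, dest, *, filename: str | None = None,
                    overwrite: bool = False, retries: int = 3) -> Path:
    """Download and decompress one release file (by taxon or ``"all"``).

    Network-dependent; never invoked by the test suite.
    """
    if version not in RELEASE_URLS:
        raise LookupError(f"unknown iRefIndex release: {version!r}; "
                          f"known: {sorted(RELEASE_URLS)}")
    if taxon != "all":
        try:
            taxon = int(taxon)
        except (TypeError, ValueError):
            raise LookupError(f"taxon must be an NCBI taxid integer or 'all', got {taxon!r}")
    dest = Path(dest)
    if dest.exists() and not overwrite:
        raise FileExistsError(f"{dest} exists; pass overwrite=True to replace")
    if filename is None:
        filename = f"{taxon}.mitab.txt.zip"
    url = f"{RELEASE_URLS[version]}/{filename}"
    last_exc: Exception | None = None
    for attempt in range(1, retries + 1):
        try:
            log.info("fetching %s (attempt %d/%d)", url, attempt, retries)
            tmp = dest.parent / filename
            with urllib.request.urlopen(url) as resp, open(tmp, "wb") as out:
                out.write(resp.read())
            stream, _ = _open_text(tmp, "rt")
            with open(dest, "w", encoding="utf-8") as out:
                out.write(stream.read())
            stream.close()
            tmp.unlink(missing_ok=True)
            return dest
        except OSError as exc:  # pragma: no cover - network path
            last_exc = exc
            time.sleep(min(2 ** attempt, 30))
    raise FetchError(f"failed to fetch {url} after {retries} attempts: {last_exc}")


__all__ = [
    "ABSENT", "MI_BAIT", "MI_PREY",
    "InteractorRef", "MITerm", "MitabRecord", "MitabTable",
    "classify_record", "read_mitab", "write_mitab", "fetch_irefindex",
    "DIALECTS", "IREFINDEX_26_COLUMNS", "replace",
]
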