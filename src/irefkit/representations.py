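"""Interconversion among MITAB, complexList, edgeList and graph representations.

An n-ary (complex) record lists m proteins observed together without pairwise
claims, so turning it into edges requires an explicit expansion policy:

``bipartite``
    m edges between a pseudo-node (``complex:<rigid>``) and the members — a
    faithful list view, not binary interactions;
``spoke``
    m-1 edges from one hub (the experimental bait when a unique one is
    recorded, else the lexicographically smallest member) to the other members;
``matrix``
    all m(m-1)/2 member pairs;
``exclude``
    n-ary records contribute nothing.

Edge weights count the distinct source records supporting each node pair
(optionally distinct publications).  Node identity is chosen per conversion:
sequence-specific ROGIDs or canonical cROGIDs.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from .errors import IrefkitError
from .mitab import MI_BAIT, MitabTable, classify_record

log = logging.getLogger(__name__)

NARY_POLICIES = ("exclude", "spoke", "matrix", "bipartite")


# ---------------------------------------------------------------------------
# complexList
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexRow:
    complex_id: str
    members: tuple[str, ...]  # sorted, distinct
    origin: str  # "reported" | "regenerated"
    num_participants: int
    support: tuple[int, ...] = ()  # record indices in the source table


@dataclass
class ComplexList:
    """(complex id, sorted distinct member ids) rows at a stated id level."""

    rows: list[ComplexRow] = field(default_factory=list)
    id_level: str = "rogid"

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.complex_id, ",".join(r.members), r.origin, r.num_participants)
             for r in self.rows],
            columns=["complex_id", "members", "origin", "num_participants"],
        )


# ---------------------------------------------------------------------------
# edgeList / graph
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Weighted node-pair rows plus the conversion parameters that built them.

    Undirected rows are stored with ``node_a <= node_b``; there are no
    duplicate pairs.
    """

    df: pd.DataFrame  # columns node_a, node_b, weight
    id_level: str = "rogid"
    nary_policy: str = "exclude"
    directed: bool = False

    def __len__(self) -> int:
        return len(self.df)

    def pairs(self) -> set[tuple[str, str]]:
        """Unordered pair set (normalised even for directed lists)."""
        return {
            tuple(sorted((a, b)))
            for a, b in zip(self.df["node_a"], self.df["node_b"])
        }


def _complex_members(t: MitabTable, indices, id_level: str) -> list[str]:
    members = {
        t[i].interactor_key("b", id_level)
        for i in indices
        if t[i].interactor_key("b", id_level) is not None
    }
    return sorted(members)


def _complex_hub(t: MitabTable, indices, id_level: str, members: list[str]) -> str:
    """Unique bait member if exactly one is recorded, else smallest member id."""
    baits = {
        t[i].interactor_key("b", id_level)
        for i in indices
        if t[i].role_b is not None and t[i].role_b.code == MI_BAIT
    }
    baits.discard(None)
    baits &= set(members)
    if len(baits) == 1:
        return next(iter(baits))
    if baits:
        log.debug("complex with %d bait members; falling back to smallest id", len(baits))
    return members[0]


def mitab_to_edgelist(t: MitabTable, nary_policy: str = "exclude",
                      id_level: str = "rogid", directed: bool = False,
                      include_self_loops: bool = False,
                      weight_by: str = "records",
                      drop_undirected: bool = False) -> EdgeList:
    """Expand a MITAB table into a weighted edge list.

    Binary records give one edge per distinct node pair; complexes are
    expanded per ``nary_policy``; polymers (self-pairs) are excluded unless
    ``include_self_loops``.  With ``directed=True`` edges are oriented
    bait→prey (hub→member for spoke); role-less binary edges are embedded as
    reciprocal arc pairs, or dropped when ``drop_undirected``.
    """
    if nary_policy not in NARY_POLICIES:
        raise IrefkitError(f"unknown n-ary policy: {nary_policy!r}")
    if directed and nary_policy == "matrix":
        raise IrefkitError("matrix expansion has no direction semantics")
    if weight_by not in ("records", "publications"):
        raise IrefkitError(f"unknown weight mode: {weight_by!r}")

    support: dict[tuple[str, str], set] = {}

    def add(a: str, b: str, token, oriented: bool) -> None:
        if a == b and not include_self_loops:
            return
        if directed and oriented:
            keys = [(a, b)]
        elif directed:
            keys = [(a, b), (b, a)] if a != b else [(a, b)]
        else:
            keys = [tuple(sorted((a, b)))]
        for key in keys:
            support.setdefault(key, set()).add(token)

    for i, r in enumerate(t):
        kind = classify_record(r)
        if kind == "complex":
            continue
        a = r.interactor_key("a", id_level)
        b = r.interactor_key("b", id_level)
        if a is None or b is None:
            continue
        if kind == "polymer" and not include_self_loops:
            continue
        token = r.pmids[0] if weight_by == "publications" and r.pmids else ("X", i)
        if weight_by == "publications" and not r.pmids:
            token = ("X", i)
        if directed:
            bait_a = r.role_a is not None and r.role_a.code == MI_BAIT
            bait_b = r.role_b is not None and r.role_b.code == MI_BAIT
            if bait_a != bait_b:
                src, dst = (a, b) if bait_a else (b, a)
                add(src, dst, token, oriented=True)
            elif not drop_undirected:
                add(a, b, token, oriented=False)
        else:
            add(a, b, token, oriented=False)

    if nary_policy != "exclude":
        for rigid, indices in t.complex_groups("rigid").items():
            members = _complex_members(t, indices, id_level)
            if len(members) < 2:
                continue
            if weight_by == "publications":
                pmids = {p for i in indices for p in t[i].pmids}
                token = next(iter(sorted(pmids))) if pmids else ("C", rigid)
            else:
                token = ("C", rigid)
            if nary_policy == "spoke":
                hub = _complex_hub(t, indices, id_level, members)
                for m in members:
                    if m != hub:
                        add(hub, m, token, oriented=directed)
            elif nary_policy == "matrix":
                for x, y in itertools.combinations(members, 2):
                    add(x, y, token, oriented=False)
            else:  # bipartite
                pseudo = f"complex:{rigid}"
                for m in members:
                    support.setdefault(
                        (pseudo, m) if directed else (min(pseudo, m), max(pseudo, m)),
                        set(),
                    ).add(token)

    rows = sorted((a, b, len(tokens)) for (a, b), tokens in support.items())
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    return EdgeList(df, id_level=id_level, nary_policy=nary_policy, directed=directed)


def edgelist_to_mitab(e: EdgeList, t: MitabTable,
                      include_complexes: bool = False) -> MitabTable:
    """Records of ``t`` whose interactor pair (at the edge list's id level)
    appears in ``e``.

    With ``include_complexes``, a complex is retrieved whole when any of its
    expansion edges (under the edge list's own policy) matches.
    """
    wanted = e.pairs()
    keep = []
    for r in t:
        if classify_record(r) == "complex":
            keep.append(False)
            continue
        a = r.interactor_key("a", e.id_level)
        b = r.interactor_key("b", e.id_level)
        keep.append(a is not None and b is not None
                    and tuple(sorted((a, b))) in wanted)
    if include_complexes and e.nary_policy != "exclude":
        for rigid, indices in t.complex_groups("rigid").items():
            members = _complex_members(t, indices, e.id_level)
            if len(members) < 2:
                continue
            if e.nary_policy == "bipartite":
                pseudo = f"complex:{rigid}"
                pairs = {tuple(sorted((pseudo, m))) for m in members}
            elif e.nary_policy == "spoke":
                hub = _complex_hub(t, indices, e.id_level, members)
                pairs = {tuple(sorted((hub, m))) for m in members if m != hub}
            else:
                pairs = {tuple(sorted(p)) for p in itertools.combinations(members, 2)}
            if pairs & wanted:
                for i in indices:
                    keep[i] = True
    return t.subset([i for i, k in enumerate(keep) if k])


def mitab_to_complexlist(t: MitabTable, id_level: str = "rogid",
                         include_regenerated: str = "no") -> ComplexList:
    """Group n-ary rows into a complexList; optionally append regenerated
    complexes (``"yes"`` = permissive n-ary-method set, ``"conservative"`` =
    BioGrid + affinity chromatography only)."""
    if include_regenerated not in ("no", "yes", "conservative"):
        raise IrefkitError(f"unknown include_regenerated: {include_regenerated!r}")
    key_level = "crigid" if id_level == "crogid" else "rigid"
    rows = []
    for key, indices in t.complex_groups(key_level).items():
        members = tuple(_complex_members(t, indices, id_level))
        rows.append(ComplexRow(
            complex_id=key,
            members=members,
            origin="reported",
            num_participants=t[indices[0]].num_participants,
            support=tuple(indices),
        ))
    rows.sort(key=lambda r: r.complex_id)
    if include_regenerated != "no":
        from .regeneration import DEFAULT_NARY_METHODS, conservative_preset, regenerate_complexes
        if include_regenerated == "conservative":
            regenerated = conservative_preset(t, id_level=id_level)
        else:
            regenerated = regenerate_complexes(
                t, DEFAULT_NARY_METHODS, require_bait="auto", id_level=id_level)
        for rc in regenerated:
            rows.append(ComplexRow(
                complex_id=rc.complex_id,
                members=rc.members,
                origin="regenerated",
                num_participants=len(rc.members),
                support=rc.support,
            ))
    return ComplexList(rows, id_level=id_level)


def complexlist_to_mitab(c: ComplexList, t: MitabTable,
                         include_regenerated: bool = False) -> MitabTable:
    """Records of ``t`` backing a complexList: the C rows of each reported
    complex and, flag-gated, the binary records supporting regenerated ones."""
    key_level = "crigid" if c.id_level == "crogid" else "rigid"
    wanted_keys = {r.complex_id for r in c.rows if r.origin == "reported"}
    keep = [False] * len(t)
    for key, indices in t.complex_groups(key_level).items():
        if key in wanted_keys:
            for i in indices:
                keep[i] = True
    if include_regenerated:
        for row in c.rows:
            if row.origin == "regenerated":
                for i in row.support:
                    keep[i] = True
    return t.subset([i for i, k in enumerate(keep) if k])


def merge_complex_lists(a: ComplexList, b: ComplexList) -> ComplexList:
    """Union of two complexLists deduplicated on the sorted member set.

    The first occurrence's id and origin are kept; order is a's rows then b's
    novel rows.
    """
    if a.id_level != b.id_level:
        raise IrefkitError(
            f"cannot merge complexLists at different id levels: "
            f"{a.id_level} vs {b.id_level}")
    seen: set[tuple[str, ...]] = set()
    rows = []
    for row in itertools.chain(a.rows, b.rows):
        if row.members not in seen:
            seen.add(row.members)
            rows.append(row)
    return ComplexList(rows, id_level=a.id_level)


def edgelist_to_graph(e: EdgeList) -> nx.Graph:
    """Build a networkx (Di)Graph carrying edge weights and conversion meta."""
    g: nx.Graph = nx.DiGraph() if e.directed else nx.Graph()
    for a, b, w in zip(e.df["node_a"], e.df["node_b"], e.df["weight"]):
        g.add_edge(a, b, weight=int(w))
    g.graph.update(
        id_level=e.id_level, nary_policy=e.nary_policy, directed=e.directed)
    return g


def graph_to_edgelist(g: nx.Graph) -> EdgeList:
    """Exact inverse of :func:`edgelist_to_graph`."""
    directed = g.is_directed()
    rows = []
    for a, b, data in g.edges(data=True):
        w = int(data.get("weight", 1))
        if directed:
            rows.append((a, b, w))
        else:
            x, y = sorted((a, b))
            rows.append((x, y, w))
    rows.sort()
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    return EdgeList(
        df,
        id_level=g.graph.get("id_level", "rogid"),
        nary_policy=g.graph.get("nary_policy", "exclude"),
        directed=directed,
    )


def regen_complex_id(db: str, pmid: int, method: str, members) -> str:
    """Deterministic token naming a regenerated complex."""
    payload = f"{db}|{pmid}|{method}|{','.join(sorted(members))}"
    return "regen:" + hashlib.sha1(payload.encode()).hexdigest()[:16]


__all__ = [
    "ComplexRow", "ComplexList", "EdgeList", "NARY_POLICIES",
    "mitab_to_edgelist", "edgelist_to_mitab",
    "mitab_to_complexlist", "complexlist_to_mitab",
    "merge_complex_lists", "edgelist_to_graph", "graph_to_edgelist",
    "regen_complex_id", "replace",
]
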