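"""Bibliometric scores and descriptive summaries.

For each distinct interaction (RIGID) with supporting publication set P and
publication reuse ``reuse(p) = |{RIGIDs supported by p}|``:

    np  = |P|                      (number of supporting publications)
    lpr = min_{p in P} reuse(p)    (lowest publication re-use)
    hpr = max_{p in P} reuse(p)    (highest publication re-use)

``lpr = 1`` means at least one supporting paper describes this interaction
and nothing else — the signature of a low-throughput experiment — while a
large lpr means every supporting paper is a screen.  The conventional
low-throughput cut is ``lpr <= 21`` (equivalently ``lpr < 22``); these are
bibliometric descriptors, not confidence scores.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .mitab import MitabTable, classify_record
from .selection import select_taxon

LOW_THROUGHPUT_LPR = 21


class ScoreTable:
    """Per-RIGID (np, lpr, hpr) rows, sorted by RIGID."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def as_dict(self) -> dict[str, tuple[int, int, int]]:
        return {
            row.rigid: (int(row.np), int(row.lpr), int(row.hpr))
            for row in self.df.itertuples()
        }


def compute_bibliometric_scores(t: MitabTable) -> ScoreTable:
    """Recompute np/lpr/hpr for every scored RIGID in the table.

    Records without PubMed ids contribute nothing and get no score row.
    """
    pmids_of: dict[str, set[int]] = {}
    rigids_of: dict[int, set[str]] = {}
    for r in t:
        rigid = r.rigid
        if rigid is None or not r.pmids:
            continue
        pmids_of.setdefault(rigid, set()).update(r.pmids)
        for p in r.pmids:
            rigids_of.setdefault(p, set()).add(rigid)
    rows = []
    for rigid in sorted(pmids_of):
        reuse = [len(rigids_of[p]) for p in pmids_of[rigid]]
        rows.append((rigid, len(pmids_of[rigid]), min(reuse), max(reuse)))
    return ScoreTable(pd.DataFrame(rows, columns=["rigid", "np", "lpr", "hpr"]))


ThroughputPartition = namedtuple("ThroughputPartition", ["low", "high", "unscored"])


def classify_throughput(t: MitabTable, threshold: int = LOW_THROUGHPUT_LPR,
                        use_file_scores: bool = False) -> ThroughputPartition:
    """Partition records into low-throughput (lpr <= threshold), high-throughput
    and unscored sub-tables.

    By default lpr is recomputed from the table itself; ``use_file_scores``
    trusts the file's confidence column instead (release-wide values).
    """
    if use_file_scores:
        lpr_of_record = [r.confidence.get("lpr") for r in t]
    else:
        lpr = {
            row.rigid: int(row.lpr)
            for row in compute_bibliometric_scores(t).df.itertuples()
        }
        lpr_of_record = [lpr.get(r.rigid) if r.rigid is not None else None for r in t]
    low, high, unscored = [], [], []
    for i, v in enumerate(lpr_of_record):
        if v is None:
            unscored.append(i)
        elif v <= threshold:
            low.append(i)
        else:
            high.append(i)
    return ThroughputPartition(t.subset(low), t.subset(high), t.subset(unscored))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summary_table(t: MitabTable, taxid: int | None = None) -> dict:
    """Record counts by type and database, distinct-entity counts at both
    redundancy levels, and (given a taxid) intra- vs inter-species counts."""
    from .identifiers import distinct_interactions, distinct_proteins

    by_type = {"binary": 0, "complex": 0, "polymer": 0}
    by_db: dict[str, int] = {}
    for r in t:
        by_type[classify_record(r)] += 1
        db = (r.source_db.label or r.source_db.code) if r.source_db else "unknown"
        by_db[db.lower()] = by_db.get(db.lower(), 0) + 1
    report = {
        "n_records": len(t),
        "records_by_type": by_type,
        "records_by_db": dict(sorted(by_db.items())),
        "distinct_rogids": len(distinct_proteins(t, "rogid")),
        "distinct_crogids": len(distinct_proteins(t, "crogid")),
        "distinct_rigids": len(distinct_interactions(t, "rigid")),
        "distinct_crigids": len(distinct_interactions(t, "crigid")),
    }
    if taxid is not None:
        any_t = select_taxon(t, taxid, "at_least_one")
        all_t = select_taxon(t, taxid, "all_interactors")
        report["taxid"] = taxid
        report["records_with_taxon"] = len(any_t)
        report["records_intra_species"] = len(all_t)
        report["records_interspecies"] = len(any_t) - len(all_t)
    return report


def summary_protein(t: MitabTable, protein_id: str, id_level: str = "rogid") -> dict:
    """Record, partner, complex, publication and database counts for one protein."""
    records = 0
    partners: set[str] = set()
    complexes: set[str] = set()
    pmids: set[int] = set()
    dbs: set[str] = set()
    for r in t:
        ka = r.interactor_key("a", id_level)
        kb = r.interactor_key("b", id_level)
        if protein_id not in (ka, kb):
            continue
        records += 1
        pmids.update(r.pmids)
        if r.source_db is not None:
            dbs.add((r.source_db.label or r.source_db.code).lower())
        if classify_record(r) == "complex":
            if r.rigid is not None:
                complexes.add(r.rigid)
        else:
            other = kb if ka == protein_id else ka
            if other is not None and other != protein_id:
                partners.add(other)
    return {
        "id": protein_id,
        "id_level": id_level,
        "n_records": records,
        "n_partners": len(partners),
        "n_complexes": len(complexes),
        "n_pmids": len(pmids),
        "n_source_dbs": len(dbs),
    }


@dataclass(frozen=True)
class DegreeSummary:
    """Network size and degree statistics (Table-style: n I X C dav dvar dmax)."""

    n: int
    dav: float
    dvar: float
    dmax: int
    I: int | None = None  # distinct interactions in the source table
    X: int | None = None  # binary records
    C: int | None = None  # complexes


def summary_graph(g: nx.Graph, table: MitabTable | None = None,
                  id_level: str = "rogid") -> DegreeSummary:
    """Degree statistics of a graph (total degree for directed graphs).

    ``dvar`` is the population variance.  When the source table is given, the
    I/X/C columns are filled from it.
    """
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    n = g.number_of_nodes()
    if n == 0:
        stats = dict(dav=0.0, dvar=0.0, dmax=0)
    else:
        stats = dict(
            dav=float(degrees.mean()),
            dvar=float(degrees.var()),  # population variance (ddof=0)
            dmax=int(degrees.max()),
        )
    I = X = C = None
    if table is not None:
        from .identifiers import distinct_interactions
        level = "crigid" if id_level == "crogid" else "rigid"
        I = len(distinct_interactions(table, level))
        X = len(distinct_interactions(
            _of_kind(table, "binary"), level))
        C = len(distinct_interactions(
            _of_kind(table, "complex"), level))
    return DegreeSummary(n=n, I=I, X=X, C=C, **stats)


def _of_kind(t: MitabTable, kind: str) -> MitabTable:
    from .selection import select_interaction_type
    return select_interaction_type(t, {kind})


__all__ = [
    "LOW_THROUGHPUT_LPR", "ScoreTable", "ThroughputPartition", "DegreeSummary",
    "compute_bibliometric_scores", "classify_throughput",
    "summary_table", "summary_protein", "summary_graph",
]
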