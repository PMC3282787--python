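"""Synthetic iRefIndex-style MITAB tables with exact ground-truth manifests.

The generator emulates the structural features real consolidated interaction
files exhibit, at a scale where every downstream result can be predicted
exactly:

* a protein pool with real ROGIDs (sequence+taxon digests), a fraction of
  foreign-taxon proteins, and isoform groups sharing one cROGID;
* independent low-throughput binary records (one fresh publication each),
  a fraction of them curated twice (two source records, one RIGID);
* high-throughput screens: single publications supporting many binary
  records with bait/prey roles, using yeast two-hybrid (a binary-producing
  method, so screens never masquerade as spoke-represented complexes);
* reported n-ary records, bipartite-represented (one C line per member,
  ``complex:<rigid>`` pseudo-node, numParticipants >= 3), optionally with a
  bait member;
* planted spoke-represented complexes: per complex, one hub (bait) and its
  preys as binary records sharing database, publication and an
  n-ary-producing method — exactly what the regeneration detector looks for;
* polymer records (homodimers).

Every stochastic choice derives from one integer seed through per-component
sub-streams, so adding a record class never shifts other draws and the same
seed always yields a byte-identical table.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import FixtureConfigError
from .identifiers import compute_rigid, compute_rogid
from .mitab import (DIALECTS, DEFAULT_DIALECT, InteractorRef, MITerm,
                    MitabRecord, MitabTable)
from . import powerlaw as _pl

AA = "ACDEFGHIKLMNPQRSTVWY"

MI = {
    "MI:0004": "affinity chromatography technology",
    "MI:0006": "anti bait coimmunoprecipitation",
    "MI:0018": "two hybrid",
    "MI:0096": "pull down",
    "MI:0114": "x-ray crystallography",
    "MI:0676": "tandem affinity purification",
    "MI:0496": "bait",
    "MI:0498": "prey",
    "MI:0407": "direct interaction",
    "MI:0915": "physical association",
}

DBS = {
    "biogrid": "MI:0463",
    "intact": "MI:0469",
    "mint": "MI:0471",
    "dip": "MI:0465",
    "bind": "MI:0462",
}


def _term(code: str) -> MITerm:
    return MITerm(code, MI[code])


def _db_term(label: str) -> MITerm:
    return MITerm(DBS[label], label)


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic table (defaults: a small mixed
    interactome extract with every structural feature present)."""

    n_proteins: int = 60
    seq_len: tuple[int, int] = (50, 400)
    primary_taxid: int = 4932          # S. cerevisiae
    foreign_taxids: tuple[int, ...] = (9606, 10090)
    foreign_fraction: float = 0.15     # of the protein pool
    isoform_group_sizes: tuple[int, ...] = (3, 2, 2)
    n_binary: int = 80                 # independent (one fresh pmid each)
    interspecies_fraction: float = 0.10
    duplicate_fraction: float = 0.15   # re-curated by a second database
    n_ht_screens: int = 2
    ht_screen_size: int = 25           # binary records per screen publication
    n_reported_complexes: int = 5
    complex_size: tuple[int, int] = (3, 9)
    complex_bait_fraction: float = 0.6
    n_spoke_complexes: int = 4
    spoke_size: tuple[int, int] = (3, 8)   # members including the hub
    n_polymers: int = 3

    def validate(self) -> None:
        if self.n_proteins < 4:
            raise FixtureConfigError("need at least 4 proteins")
        if self.complex_size[0] < 3 or self.spoke_size[0] < 3:
            raise FixtureConfigError("complex sizes must be >= 3")
        if self.complex_size[0] > self.complex_size[1] or self.spoke_size[0] > self.spoke_size[1]:
            raise FixtureConfigError("size ranges must be (lo, hi) with lo <= hi")
        for name in ("foreign_fraction", "interspecies_fraction",
                     "duplicate_fraction", "complex_bait_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_binary", "n_ht_screens", "ht_screen_size",
                     "n_reported_complexes", "n_spoke_complexes", "n_polymers"):
            if getattr(self, name) < 0:
                raise FixtureConfigError(f"{name} must be >= 0")
        n_primary = self.n_proteins - int(round(self.n_proteins * self.foreign_fraction))
        largest = max(
            self.complex_size[1] if self.n_reported_complexes else 0,
            self.spoke_size[1] if self.n_spoke_complexes else 0,
            self.ht_screen_size + 1 if self.n_ht_screens else 0,
            sum(self.isoform_group_sizes),
        )
        if largest > n_primary:
            raise FixtureConfigError(
                f"largest group ({largest}) exceeds the primary-taxon pool ({n_primary})")


@dataclass(frozen=True)
class Protein:
    name: str
    sequence: str
    taxid: int
    rogid: str
    crogid: str
    uniprot: str
    geneid: int


@dataclass
class FixtureManifest:
    """Exact ground truth for one generated table (record order = table order)."""

    seed: int
    config: dict
    records: list[dict] = field(default_factory=list)
    proteins: list[dict] = field(default_factory=list)
    isoform_map: dict[str, str] = field(default_factory=dict)  # rogid -> crogid
    reported_complexes: list[dict] = field(default_factory=list)
    spoke_complexes: list[dict] = field(default_factory=list)
    polymers: list[dict] = field(default_factory=list)
    scores: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _make_proteins(cfg: FixtureConfig, rng: np.random.Generator) -> list[Protein]:
    n_foreign = int(round(cfg.n_proteins * cfg.foreign_fraction))
    proteins: list[Protein] = []
    for i in range(cfg.n_proteins):
        length = int(rng.integers(cfg.seq_len[0], cfg.seq_len[1] + 1))
        seq = "".join(rng.choice(list(AA), size=length))
        if i < cfg.n_proteins - n_foreign:
            taxid = cfg.primary_taxid
        else:
            taxid = int(rng.choice(cfg.foreign_taxids))
        rogid = compute_rogid(seq, taxid)
        proteins.append(Protein(
            name=f"P{i:03d}", sequence=seq, taxid=taxid, rogid=rogid,
            crogid=rogid,  # identity until isoform groups are assigned
            uniprot=f"Q{10000 + i}", geneid=850000 + i,
        ))
    # isoform groups among primary-taxon proteins: group members share the
    # representative's rogid as crogid
    primary_idx = [i for i, p in enumerate(proteins) if p.taxid == cfg.primary_taxid]
    cursor = 0
    for size in cfg.isoform_group_sizes:
        group = primary_idx[cursor:cursor + size]
        if len(group) < size:
            raise FixtureConfigError("not enough primary-taxon proteins for isoform groups")
        rep = proteins[group[0]]
        for j in group[1:]:
            p = proteins[j]
            proteins[j] = Protein(p.name, p.sequence, p.taxid, p.rogid,
                                  rep.rogid, p.uniprot, p.geneid)
        cursor += size
    return proteins


def _interactor_cols(p: Protein) -> dict:
    return dict(
        uid=InteractorRef("uniprotkb", p.uniprot),
        alt=(InteractorRef("entrezgene/locuslink", str(p.geneid)),
             InteractorRef("refseq", f"NP_{p.geneid}")),
        alias=(InteractorRef("rogid", p.rogid),),
    )


def _binary_record(pa: Protein, pb: Protein, db: str, method: str,
                   pmid: int, bait: str | None = None,
                   itype: str = "MI:0915") -> MitabRecord:
    a, b = _interactor_cols(pa), _interactor_cols(pb)
    rigid = compute_rigid([pa.rogid, pb.rogid])
    crigid = compute_rigid(sorted({pa.crogid, pb.crogid}))
    role_a = role_b = None
    if bait == "a":
        role_a, role_b = _term("MI:0496"), _term("MI:0498")
    elif bait == "b":
        role_a, role_b = _term("MI:0498"), _term("MI:0496")
    return MitabRecord(
        uid_a=a["uid"], uid_b=b["uid"], alt_a=a["alt"], alt_b=b["alt"],
        alias_a=a["alias"], alias_b=b["alias"],
        method=_term(method), pmids=(pmid,),
        taxon_a=pa.taxid, taxon_b=pb.taxid,
        interaction_type=_term(itype), source_db=_db_term(db),
        interaction_ids=(("rigid", rigid),),
        role_a=role_a, role_b=role_b,
        edgetype="X", num_participants=2,
        crogid_a=pa.crogid, crogid_b=pb.crogid, crigid=crigid,
    )


def generate_mitab(config: FixtureConfig | None = None, seed: int = 0
                   ) -> tuple[MitabTable, FixtureManifest]:
    """Generate a valid MITAB table plus its exact ground-truth manifest."""
    cfg = config or FixtureConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    (ss_prot, ss_bin, ss_ht, ss_cplx, ss_spoke, ss_poly,
     ss_shuffle) = [np.random.default_rng(s) for s in ss.spawn(7)]

    proteins = _make_proteins(cfg, ss_prot)
    n_foreign = sum(p.taxid != cfg.primary_taxid for p in proteins)
    primary = [p for p in proteins if p.taxid == cfg.primary_taxid]
    foreign = [p for p in proteins if p.taxid != cfg.primary_taxid]

    pmid_counter = [5_000_000]

    def fresh_pmid(rng: np.random.Generator) -> int:
        pmid_counter[0] += int(rng.integers(1, 50))
        return pmid_counter[0]

    # tagged records: (record, ground-truth class tag, extra info)
    tagged: list[tuple[MitabRecord, str, dict]] = []

    # --- independent binary records --------------------------------------
    used_pairs: set[tuple[str, str]] = set()
    lt_dbs = sorted(DBS)
    binary_methods = ["MI:0018", "MI:0114", "MI:0004", "MI:0096"]
    n_inter = int(round(cfg.n_binary * cfg.interspecies_fraction)) if foreign else 0
    for k in range(cfg.n_binary):
        for _ in range(200):
            if k < n_inter:
                pa = primary[int(ss_bin.integers(len(primary)))]
                pb = foreign[int(ss_bin.integers(len(foreign)))]
            else:
                ia, ib = ss_bin.choice(len(primary), size=2, replace=False)
                pa, pb = primary[int(ia)], primary[int(ib)]
            key = tuple(sorted((pa.rogid, pb.rogid)))
            if key not in used_pairs:
                used_pairs.add(key)
                break
        else:  # pragma: no cover - pool exhausted
            raise FixtureConfigError("cannot place distinct binary pairs; enlarge pool")
        db = lt_dbs[int(ss_bin.integers(len(lt_dbs)))]
        method = binary_methods[int(ss_bin.integers(len(binary_methods)))]
        rec = _binary_record(pa, pb, db, method, fresh_pmid(ss_bin))
        tagged.append((rec, "independent_binary",
                       {"interspecies": k < n_inter}))
        if ss_bin.random() < cfg.duplicate_fraction:
            other_db = lt_dbs[(lt_dbs.index(db) + 1) % len(lt_dbs)]
            dup = _binary_record(pa, pb, other_db, method, fresh_pmid(ss_bin))
            tagged.append((dup, "duplicate_binary", {"of_rigid": rec.rigid}))

    # --- high-throughput screens (two-hybrid stars, bait roles) ----------
    for s in range(cfg.n_ht_screens):
        pmid = fresh_pmid(ss_ht)
        db = "biogrid" if s % 2 == 0 else "intact"
        hub_i = int(ss_ht.integers(len(primary)))
        hub = primary[hub_i]
        prey_pool = [p for p in primary if p.rogid != hub.rogid]
        preys_idx = ss_ht.choice(len(prey_pool), size=cfg.ht_screen_size, replace=False)
        for j in preys_idx:
            prey = prey_pool[int(j)]
            rec = _binary_record(hub, prey, db, "MI:0018", pmid, bait="a")
            tagged.append((rec, "ht_screen", {"screen": s, "pmid": pmid}))

    # --- reported n-ary records (bipartite C rows) ------------------------
    reported = []
    seen_complex_rigids: set[str] = set()
    for c in range(cfg.n_reported_complexes):
        for _ in range(200):
            size = int(ss_cplx.integers(cfg.complex_size[0], cfg.complex_size[1] + 1))
            members = [primary[int(i)]
                       for i in ss_cplx.choice(len(primary), size=size, replace=False)]
            rigid = compute_rigid([m.rogid for m in members])
            if rigid not in seen_complex_rigids:
                seen_complex_rigids.add(rigid)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise FixtureConfigError("cannot place distinct reported complexes")
        crigid = compute_rigid(sorted({m.crogid for m in members}))
        db = "intact" if c % 2 == 0 else "dip"
        method = "MI:0004" if c % 2 == 0 else "MI:0676"
        pmid = fresh_pmid(ss_cplx)
        with_bait = ss_cplx.random() < cfg.complex_bait_fraction
        rows = []
        for j, m in enumerate(members):
            cols = _interactor_cols(m)
            role = _term("MI:0496") if (with_bait and j == 0) else None
            rows.append(MitabRecord(
                uid_a=InteractorRef("complex", rigid),
                uid_b=cols["uid"], alt_b=cols["alt"], alias_b=cols["alias"],
                method=_term(method), pmids=(pmid,),
                taxon_a=None, taxon_b=m.taxid,
                interaction_type=_term("MI:0915"), source_db=_db_term(db),
                interaction_ids=(("rigid", rigid),),
                expansion="bipartite",
                role_b=role,
                edgetype="C", num_participants=size,
                crogid_b=m.crogid,
                crigid=crigid,
            ))
        for row in rows:
            tagged.append((row, "reported_complex_member", {"rigid": rigid}))
        reported.append({
            "rigid": rigid, "crigid": crigid,
            "members_rogid": sorted(m.rogid for m in members),
            "members_crogid": sorted({m.crogid for m in members}),
            "size": size, "db": db, "method": method, "pmid": pmid,
            "bait_rogid": members[0].rogid if with_bait else None,
        })

    # --- planted spoke-represented complexes -------------------------------
    spoke = []
    spoke_settings = [("biogrid", "MI:0004"), ("mint", "MI:0004"),
                      ("biogrid", "MI:0096"), ("biogrid", "MI:0004")]
    for c in range(cfg.n_spoke_complexes):
        size = int(ss_spoke.integers(cfg.spoke_size[0], cfg.spoke_size[1] + 1))
        picks = ss_spoke.choice(len(primary), size=size, replace=False)
        hub, *preys = [primary[int(i)] for i in picks]
        db, method = spoke_settings[c % len(spoke_settings)]
        pmid = fresh_pmid(ss_spoke)
        for prey in preys:
            rec = _binary_record(hub, prey, db, method, pmid, bait="a")
            tagged.append((rec, "spoke_member", {"spoke": c, "pmid": pmid}))
        spoke.append({
            "hub_rogid": hub.rogid,
            "members_rogid": sorted([hub.rogid] + [p.rogid for p in preys]),
            "size": size, "db": db, "db_code": DBS[db],
            "method": method, "pmid": pmid,
        })

    # --- polymers -----------------------------------------------------------
    polymers = []
    for _ in range(cfg.n_polymers):
        p = primary[int(ss_poly.integers(len(primary)))]
        rigid = compute_rigid([p.rogid, p.rogid])
        crigid = compute_rigid([p.crogid, p.crogid])
        cols = _interactor_cols(p)
        rec = MitabRecord(
            uid_a=cols["uid"], uid_b=cols["uid"],
            alt_a=cols["alt"], alt_b=cols["alt"],
            alias_a=cols["alias"], alias_b=cols["alias"],
            method=_term("MI:0114"), pmids=(fresh_pmid(ss_poly),),
            taxon_a=p.taxid, taxon_b=p.taxid,
            interaction_type=_term("MI:0407"), source_db=_db_term("bind"),
            interaction_ids=(("rigid", rigid),),
            edgetype="Y", num_participants=2,
            crogid_a=p.crogid, crogid_b=p.crogid, crigid=crigid,
        )
        tagged.append((rec, "polymer", {"rogid": p.rogid}))
        polymers.append({"rogid": p.rogid, "rigid": rigid})

    # --- shuffle, keeping C groups contiguous ------------------------------
    blocks: list[list[int]] = []
    i = 0
    while i < len(tagged):
        rec = tagged[i][0]
        if rec.edgetype == "C":
            j = i
            while j < len(tagged) and tagged[j][0].edgetype == "C" \
                    and tagged[j][0].rigid == rec.rigid:
                j += 1
            blocks.append(list(range(i, j)))
            i = j
        else:
            blocks.append([i])
            i += 1
    order = [i for b in ss_shuffle.permutation(len(blocks)) for i in blocks[int(b)]]
    tagged = [tagged[i] for i in order]

    # --- bibliometric ground truth & confidence columns --------------------
    pmids_of: dict[str, set[int]] = {}
    rigids_of: dict[int, set[str]] = {}
    for rec, _, _ in tagged:
        pmids_of.setdefault(rec.rigid, set()).update(rec.pmids)
        for p in rec.pmids:
            rigids_of.setdefault(p, set()).add(rec.rigid)
    scores = {}
    for rigid, P in pmids_of.items():
        reuse = [len(rigids_of[p]) for p in P]
        scores[rigid] = (len(P), min(reuse), max(reuse))
    for rec, _, _ in tagged:
        np_, lpr, hpr = scores[rec.rigid]
        rec.confidence = {"np": float(np_), "lpr": float(lpr), "hpr": float(hpr)}

    # --- assemble ----------------------------------------------------------
    manifest = FixtureManifest(seed=seed, config=asdict(cfg))
    records = []
    support_of_spoke: dict[int, list[int]] = {}
    for idx, (rec, tag, info) in enumerate(tagged):
        records.append(rec)
        manifest.records.append({
            "index": idx, "class": tag,
            "edgetype": rec.edgetype,
            "db": rec.source_db.label, "db_code": rec.source_db.code,
            "method": rec.method.code, "pmids": list(rec.pmids),
            "taxa": [rec.taxon_a, rec.taxon_b],
            "rogids": [rec.rogid_a, rec.rogid_b],
            "rigid": rec.rigid, "crigid": rec.crigid,
            "bait_side": "a" if (rec.role_a and rec.role_a.code == "MI:0496")
                         else ("b" if (rec.role_b and rec.role_b.code == "MI:0496") else None),
            **info,
        })
        if tag == "spoke_member":
            support_of_spoke.setdefault(info["spoke"], []).append(idx)
    for c, entry in enumerate(spoke):
        entry["record_indices"] = support_of_spoke.get(c, [])
    manifest.proteins = [asdict(p) for p in proteins]
    manifest.isoform_map = {p.rogid: p.crogid for p in proteins}
    manifest.reported_complexes = reported
    manifest.spoke_complexes = spoke
    manifest.polymers = polymers
    manifest.scores = scores
    by_class: dict[str, int] = {}
    for _, tag, _ in tagged:
        by_class[tag] = by_class.get(tag, 0) + 1
    manifest.counts = {
        "records": len(records),
        "binary": sum(1 for r in records if r.edgetype == "X"),
        "complex_rows": sum(1 for r in records if r.edgetype == "C"),
        "polymer": sum(1 for r in records if r.edgetype == "Y"),
        "foreign_proteins": n_foreign,
        **{f"class_{k}": v for k, v in by_class.items()},
    }
    table = MitabTable(records, meta={
        "dialect": DEFAULT_DIALECT,
        "columns": DIALECTS[DEFAULT_DIALECT],
        "provenance": f"irefkit synthetic fixture, seed={seed}",
    })
    return table, manifest


def generate_degree_sample(dist: str, params: dict, n: int, seed: int = 0) -> np.ndarray:
    """Deterministic positive-integer degree sample from a named distribution.

    ``powerlaw`` (alpha, xmin), ``geometric`` (p), or ``poisson`` (lam,
    zero-truncated so degrees stay positive).
    """
    rng = np.random.default_rng(seed)
    if dist == "powerlaw":
        return _pl.sample_discrete_powerlaw(
            params["alpha"], params["xmin"], n, rng=rng)
    if dist == "geometric":
        return rng.geometric(params["p"], size=n).astype(np.int64)
    if dist == "poisson":
        out = rng.poisson(params["lam"], size=n)
        while np.any(out == 0):  # zero-truncation: redraw zeros
            zeros = out == 0
            out[zeros] = rng.poisson(params["lam"], size=int(zeros.sum()))
        return out.astype(np.int64)
    raise FixtureConfigError(f"unknown distribution: {dist!r}")


__all__ = [
    "FixtureConfig", "FixtureManifest", "Protein",
    "generate_mitab", "generate_degree_sample", "DBS", "MI",
]
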