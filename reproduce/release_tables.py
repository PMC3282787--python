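#!/usr/bin/env python
"""Regenerate the organism-scale summary tables from a downloaded release file.

This script is NOT part of the test suite: it needs a real iRefIndex MITAB
2.6 file (hundreds of MB), e.g. fetched with
``irefkit fetch --version 8.0 --taxon 4932 --dest yeast.mitab``.  Given such
a file it recomputes, for the chosen taxon:

* distinct protein and interaction counts at both redundancy levels,
  intra-species and with interspecies records included;
* record counts by interaction type and source database;
* regenerated spoke-represented complexes (permissive and conservative),
  their size distribution against reported complexes, and the two-sample
  KS comparison;
* the low/high-throughput partition of binary records (lpr cut 21);
* network summary statistics (n, I, X, C, dav, dvar, dmax) for
  spoke/matrix expansions at both id levels;
* discrete power-law fits with bootstrap p-values for the degree
  distributions of binary, spoke-regenerated and n-ary subsets.

Usage:
    python reproduce/release_tables.py RELEASE.mitab[.gz|.zip] --taxon 4932 \
        [--bootstrap 1000] [--seed 42] [--out tables.json]
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import irefkit as ik  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("mitab", help="iRefIndex MITAB 2.6 file (gzip/zip ok)")
    ap.add_argument("--taxon", type=int, default=4932)
    ap.add_argument("--bootstrap", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()

    print(f"reading {args.mitab} ...", file=sys.stderr)
    t = ik.read_mitab(args.mitab, mode="lenient")
    out: dict = {"file": str(args.mitab), "taxon": args.taxon,
                 "records": len(t), "skipped": t.meta.get("skipped_lines", 0)}

    out["summary"] = ik.summary_table(t, taxid=args.taxon)

    intra = ik.select_taxon(t, args.taxon, "all_interactors")
    out["distinct"] = {
        "rogids_any": len(ik.distinct_proteins(t, "rogid")),
        "crogids_any": len(ik.distinct_proteins(t, "crogid")),
        "rogids_intra": len(ik.distinct_proteins(intra, "rogid")),
        "crogids_intra": len(ik.distinct_proteins(intra, "crogid")),
        "rigids": len(ik.distinct_interactions(t, "rigid")),
        "crigids": len(ik.distinct_interactions(t, "crigid")),
    }

    print("regenerating complexes ...", file=sys.stderr)
    permissive = ik.regenerate_complexes(t, ik.DEFAULT_NARY_METHODS,
                                         require_bait="auto")
    conservative = ik.conservative_preset(t)
    reported = ik.mitab_to_complexlist(t, "crogid").rows
    out["complexes"] = {
        "reported": len(reported),
        "regenerated": len(permissive),
        "regenerated_conservative": len(conservative),
        "regenerated_low_throughput": sum(
            1 for c in permissive if c.throughput == "low"),
    }
    if reported and permissive:
        D, p = ik.compare_size_distributions(reported, permissive)
        out["complexes"]["size_ks"] = {"D": D, "p": p}

    binary = ik.select_interaction_type(t, {"binary"})
    part = ik.classify_throughput(binary)
    out["throughput"] = {
        "binary_records": len(binary),
        "low_pct": 100.0 * len(part.low) / max(len(binary), 1),
        "high_pct": 100.0 * len(part.high) / max(len(binary), 1),
    }

    out["networks"] = {}
    for id_level in ("rogid", "crogid"):
        for policy in ("spoke", "matrix"):
            g = ik.edgelist_to_graph(ik.mitab_to_edgelist(t, policy, id_level))
            s = ik.summary_graph(g, table=t, id_level=id_level)
            out["networks"][f"{id_level}_{policy}"] = s.__dict__

    print("power-law fits ...", file=sys.stderr)
    out["powerlaw"] = {}
    spoke_regen_idx = {i for c in permissive for i in c.support}
    subsets = {
        "true_binary": binary.subset(
            [i for i, r in enumerate(binary)
             if id(r) not in {id(t[j]) for j in spoke_regen_idx}]),
        "nary": ik.select_interaction_type(t, {"complex"}),
    }
    for name, sub in subsets.items():
        if not len(sub):
            continue
        g = ik.edgelist_to_graph(ik.mitab_to_edgelist(sub, "spoke", "crogid"))
        degrees = [d for _, d in g.degree()]
        try:
            fit = ik.assess_powerlaw(degrees, B=args.bootstrap, seed=args.seed)
            out["powerlaw"][name] = {
                "n": len(degrees), "alpha": fit.alpha, "xmin": fit.xmin,
                "ntail": fit.ntail, "p_value": fit.p_value,
                "verdict": fit.verdict,
            }
        except ik.IrefkitError as exc:
            out["powerlaw"][name] = {"error": str(exc)}

    text = json.dumps(out, indent=2, default=str)
    if args.out:
        args.out.write_text(text + "\n", encoding="utf-8")
    else:
        print(text)
    return 0


if __name__ == "__main__":
    sys.exit(main())
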