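#!/usr/bin/env python
"""Published-value comparisons on the deposited NGF structures.

Needs the coordinate files under data/pdb/ (not redistributed here):

    mkdir -p data/pdb && cd data/pdb
    for id in 5LSD 1BTG 4EAX 4XPJ; do
        curl -sO https://files.rcsb.org/download/$id.pdb
    done

With the files present this script computes, and writes to
results/deposited/deposited.json:
  - mean backbone RMSD of the 5LSD bundle to its lowest-energy model
  - core-residue backbone RMSD of 5LSD model 1 vs 1BTG/4EAX/4XPJ
  - inter-protomer CA distances at residues 46 (loop II) and 95 (loop V)
  - the O(i)...NH(i+3/i+4) bundle extremes for donors S2-G10
Without them it prints the fetch instructions and exits cleanly.
"""

import json
import sys
from pathlib import Path

from nmrens.geometry import ca_distance, cross_rmsd, ensemble_rmsd
from nmrens.helicity import nterm_hbond_report
from nmrens.io_formats import Selection, read_multimodel_pdb

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "data" / "pdb"
OUT = ROOT / "results" / "deposited"

CORE = Selection.backbone(residue_ranges=[(15, 22), (51, 58), (78, 89), (100, 111)])
NEEDED = ("5LSD", "1BTG", "4EAX", "4XPJ")


def main() -> None:
    missing = [n for n in NEEDED if not (DATA / f"{n}.pdb").exists()]
    if missing:
        print(f"missing coordinate files under {DATA}: {', '.join(missing)}")
        print(__doc__.split("\n\n")[1])
        return

    OUT.mkdir(parents=True, exist_ok=True)
    out: dict = {}
    nmr = read_multimodel_pdb(DATA / "5LSD.pdb")
    res = ensemble_rmsd(nmr, Selection.backbone())
    out["ensemble_backbone_rmsd_A"] = round(res.mean, 2)
    print(f"5LSD bundle backbone RMSD to model 1: {res.mean:.2f} A")

    out["core_rmsd_A"] = {}
    for name in ("1BTG", "4EAX", "4XPJ"):
        ref = read_multimodel_pdb(DATA / f"{name}.pdb").models[0]
        r, cmap = cross_rmsd(nmr.models[0], ref, CORE)
        out["core_rmsd_A"][name] = round(r, 2)
        print(f"core backbone RMSD 5LSD vs {name}: {r:.2f} A (chains {cmap})")

    out["interprotomer_A"] = {}
    for name in ("1BTG", "4XPJ", "5LSD"):
        model = read_multimodel_pdb(DATA / f"{name}.pdb").models[0]
        chains = model.chains
        for anchor in (46, 95):
            pairs = [
                ca_distance(model, a, anchor, b, anchor)
                for i, a in enumerate(chains) for b in chains[i + 1:]
                if model.has(a, anchor, "CA") and model.has(b, anchor, "CA")
            ]
            if pairs:
                out["interprotomer_A"][f"{name}_{anchor}"] = round(min(pairs), 1)
                print(f"{name} residue {anchor}: {min(pairs):.1f} A")

    extremes = []
    for chain in nmr.models[0].chains:
        _, summary = nterm_hbond_report(nmr, chain, (2, 10))
        extremes.append((summary["min"], summary["max"]))
    out["nterm_bundle_min_A"] = round(min(e[0] for e in extremes), 2)
    out["nterm_bundle_max_A"] = round(max(e[1] for e in extremes), 2)
    print(f"N-terminal H-bond bundle extremes: "
          f"{out['nterm_bundle_min_A']} - {out['nterm_bundle_max_A']} A")

    (OUT / "deposited.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
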