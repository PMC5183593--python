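#!/usr/bin/env python
"""Titration analysis: exchange-regime classes and spatial epitope patches.

Reads the three synthetic peak lists (0, 0.15, 0.45 ligand equivalents) and
the bundle's first model, classifies every residue (disappeared /
attenuated / shifted / unaffected), maps the affected residues onto the
structure as contact patches, and checks the classes against the
generator's truth.  Writes csp_final.tsv, epitope.json and an
epitope_selection.pml visualisation helper under results/epitope/.
"""

import json
from pathlib import Path

from nmrens.csp_epitope import TitrationSeries, titration_report
from nmrens.io_formats import read_multimodel_pdb, read_peak_table

ROOT = Path(__file__).resolve().parents[1]
SRC = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "epitope"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((SRC / "titration_truth.json").read_text())
    eqs = truth["equivalents"]
    lists = [read_peak_table(SRC / f"peaks_eq{eq:g}.tsv") for eq in eqs]
    series = TitrationSeries(equivalents=eqs, peak_lists=lists)
    structure = read_multimodel_pdb(SRC / "ensemble.pdb").models[0]

    rep = titration_report(series, structure)
    rep.per_point[-1].to_csv(OUT / "csp_final.tsv", sep="\t", index=False)

    for cls in ("disappeared", "attenuated", "shifted"):
        got = rep.class_members[cls]
        want = truth[cls]
        status = "exact" if got == want else f"MISMATCH (want {want})"
        print(f"{cls:12s}: {len(got):2d} residues {got} -> {status}")

    out = {"class_members": rep.class_members}
    if rep.epitope is not None:
        out["patches"] = [sorted(f"{c}{r}" for c, r in p["residues"])
                          for p in rep.epitope.patches]
        out["unassigned"] = sorted(f"{c}{r}" for c, r in rep.epitope.unassigned)
        print(f"epitope: {len(rep.epitope.patches)} spatial patches, "
              f"largest {max(len(p['residues']) for p in rep.epitope.patches)} "
              "residues")
        lines = [
            "select patch%d, resi %s" % (
                i + 1, "+".join(sorted({str(r) for _, r in p["residues"]},
                                       key=int)))
            for i, p in enumerate(rep.epitope.patches)
        ]
        (OUT / "epitope_selection.pml").write_text("\n".join(lines) + "\n")
    (OUT / "epitope.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
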