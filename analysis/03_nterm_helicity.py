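#!/usr/bin/env python
"""N-terminal nascent helix: hydrogen-bond distances and helix fractions.

Reads the synthetic bundle, tabulates the O(i)...NH(i+3/i+4) distances over
the donor span, classifies each segment residue per model, and checks the
recovered segment fraction against the generator's ground truth.
Writes nterm_hbonds.tsv and helicity.json under results/helicity/.
"""

import json
from pathlib import Path

from nmrens.helicity import HelixCriteria, helical_fraction, nterm_hbond_report
from nmrens.io_formats import read_multimodel_pdb

ROOT = Path(__file__).resolve().parents[1]
SRC = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "helicity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ensemble = read_multimodel_pdb(SRC / "ensemble.pdb")
    truth = json.loads((SRC / "ensemble_truth.json").read_text())
    seg_lo, seg_hi = truth["helix_segment"]

    df, summary = nterm_hbond_report(ensemble, "A", (2, seg_hi))
    df.to_csv(OUT / "nterm_hbonds.tsv", sep="\t", index=False)
    print(f"H-bond distances over donors 2-{seg_hi}: "
          f"bundle min {summary['min']:.2f} A, max {summary['max']:.2f} A")

    prof = helical_fraction(ensemble, "A", (seg_lo, seg_hi), HelixCriteria())
    result = {
        "segment": [seg_lo, seg_hi],
        "segment_fraction": prof.segment_fraction,
        "fraction_alpha": prof.fraction_alpha,
        "fraction_310": prof.fraction_310,
        "fraction_helical": prof.fraction_helical,
        "expected_fraction": len(truth["helical_models"]) / truth["n_models"],
    }
    (OUT / "helicity.json").write_text(json.dumps(result, indent=2))
    print(f"segment {seg_lo}-{seg_hi} helical in "
          f"{prof.segment_fraction:.0%} of models "
          f"(generated: {result['expected_fraction']:.0%})")


if __name__ == "__main__":
    main()
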