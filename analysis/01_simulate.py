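#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analysis stages.

Writes, under results/synthetic/:
  ensemble.pdb          20-model two-protomer bundle (rigid core, mobile
                        loops, N-terminal segment helical in half the models)
  relaxation.tsv        per-residue T1/T2/hetNOE at tau_c = 14.8 ns, 600 MHz
  peaks_eq*.tsv         HSQC peak lists at 0, 0.15 and 0.45 ligand equivalents
  *_truth.json          the generating ground truth for each input
"""

import json
from pathlib import Path

from nmrens.io_formats import write_multimodel_pdb, write_peak_table, write_relaxation_table
from nmrens.synthetic import (
    EnsembleSpec,
    RelaxationSpec,
    TitrationSpec,
    make_dimer_ensemble,
    make_relaxation,
    make_titration,
)

SEED = 20160083
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ens_spec = EnsembleSpec(seed=SEED)
    ensemble, ens_truth = make_dimer_ensemble(ens_spec)
    write_multimodel_pdb(OUT / "ensemble.pdb", ensemble)
    (OUT / "ensemble_truth.json").write_text(json.dumps({
        "seed": SEED,
        "n_models": ens_spec.n_models,
        "helical_models": sorted(ens_truth.helical_models),
        "helix_segment": list(ens_spec.helix_segment),
        "core_residues": sorted(ens_truth.core_residues),
        "loop_residues": sorted(ens_truth.loop_residues),
        "sigma_core_A": ens_spec.sigma_core,
        "sigma_loop_A": ens_spec.sigma_loop,
    }, indent=2))
    print(f"ensemble: {ens_spec.n_models} models, "
          f"{len(ens_truth.helical_models)} with a helical N-terminal segment")

    rel_spec = RelaxationSpec(seed=SEED)
    records, rel_truth = make_relaxation(rel_spec)
    write_relaxation_table(OUT / "relaxation.tsv", records)
    (OUT / "relaxation_truth.json").write_text(json.dumps({
        "seed": SEED,
        "tau_c_ns": rel_spec.tau_c_ns,
        "field_mhz": rel_spec.field_mhz,
        "flexible_residues": sorted(rel_truth.flexible),
    }, indent=2))
    print(f"relaxation: {len(records)} residues at tau_c = {rel_spec.tau_c_ns} ns, "
          f"{len(rel_truth.flexible)} flexible")

    tit_spec = TitrationSpec(seed=SEED)
    series, tit_truth = make_titration(tit_spec)
    for eq, peaks in zip(series.equivalents, series.peak_lists):
        write_peak_table(OUT / f"peaks_eq{eq:g}.tsv", peaks)
    (OUT / "titration_truth.json").write_text(json.dumps({
        "seed": SEED,
        "equivalents": list(tit_spec.equivalents),
        "disappeared": sorted(tit_spec.disappeared),
        "attenuated": sorted(tit_spec.attenuated),
        "shifted": sorted(tit_spec.shifted),
    }, indent=2))
    print(f"titration: {len(series.equivalents)} points, classes "
          f"{len(tit_spec.disappeared)}/{len(tit_spec.attenuated)}/"
          f"{len(tit_spec.shifted)} (disappeared/attenuated/shifted)")


if __name__ == "__main__":
    main()
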