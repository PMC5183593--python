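# nmrens

Conformational-ensemble analysis for homodimeric proteins in solution,
built around the questions asked of nerve growth factor (NGF)-like
systems: how precise is an NMR ensemble, which loops move, does the
N-terminus sample a nascent helix, which conformer best represents a
frame stack, how fast does the dimer tumble, and where does an antibody
bind.

It is organised as an analysis project: the library under `src/nmrens/`
holds every computation, the numbered drivers under `analysis/` run the
study end to end on generated inputs, and a `nmrens` command-line tool
exposes the individual steps.

## What it computes

- **Ensemble geometry** — least-squares rigid superposition (Kabsch, SVD
  with reflection correction), per-model backbone RMSD to a reference
  conformer, per-residue RMSF about the iteratively re-fitted ensemble
  mean, inter-protomer Cα distances, and atom-pair distance series over
  frames. Cross-structure RMSD for homodimers tries every chain bijection
  and keeps the lowest value, since protomer labels are deposition
  accidents.
- **Nascent-helix detection** — per-residue helix labels from backbone
  hydrogen-bond geometry: residue *i* is `alpha` when O(i)…NH(i+4) is
  within hydrogen-bond distance (O…N ≤ 3.5 Å, or O…H ≤ 2.7 Å when amide
  hydrogens are present), `three_ten` when only the i→i+3 bond holds, with
  α-precedence on bifurcated bonds; plus bundle-level fractions and the
  O(i)…NH(i+3/i+4) distance table with its extremes.
- **Conformational clustering** — the greedy RMSD-cutoff scheme
  (GROMOS/Daura): repeatedly take the conformer with the most neighbours
  within the cutoff (conventionally 0.15 nm on backbone atoms) as a
  cluster centre, remove the cluster, iterate; the centre of the most
  populated cluster is the representative structure.
- **¹⁵N relaxation** — overall rotational correlation time from the
  rigid-rotor relation τc = √(6·T1/T2 − 7)/(4π·ν_N), averaged over
  residues that pass a hetNOE rigidity filter and a median ± 1.5·IQR trim
  on T1/T2; flexibility flags from hetNOE against the profile mean.
- **Epitope mapping** — combined chemical-shift perturbation
  Δδ = √(ΔδH² + (0.14·ΔδN)²), exchange-regime classification
  (disappeared > attenuated > shifted > unaffected) across a titration,
  and spatial epitope patches as connected components of the contact
  graph on a structure.
- **Synthetic data** — seeded generators for dimer bundles (rigid core,
  mobile loops, tunable helical fraction of an N-terminal segment),
  titration peak lists with the three perturbation classes, and
  relaxation tables at a target τc, each returning its ground truth.

## Worked example

```
python analysis/01_simulate.py
python analysis/02_ensemble_geometry.py
python analysis/03_nterm_helicity.py
python analysis/04_cluster_frames.py
python analysis/05_relaxation.py
python analysis/06_epitope_mapping.py
```

prints, among other things:

```
RMSF: core mean 1.33 A, loop mean 2.78 A; 16/16 loop residues above the core maximum
segment 6-10 helical in 45% of models (generated: 50%)
2 clusters at 1.5 A backbone cutoff; sizes [10, 10]; representative model 1
tau_c = 14.82 ns from 83 rigid residues (generated at 14.8 ns)
disappeared :  5 residues [14, 23, 101, 110, 111] -> exact
```

Reading the output: the mobile loop residues are recovered as more
flexible than the rigid β-core in every case; the N-terminal segment
generated helical in half the models is detected in 45% of them (per-atom
coordinate noise costs one model its three-consecutive-residue helical
run); the 0.15 nm backbone clustering separates the helical- and
extended-N-terminus conformers into two clusters of ten; the correlation
time estimated from T1/T2 matches the 14.8 ns used to generate the table;
and the titration classifier returns the exact generated residue classes.

The same steps run on deposited coordinates:
`analysis/07_deposited_structures.py` computes the ensemble RMSD,
core-residue RMSD against crystal structures, inter-protomer loop-tip
distances and N-terminal hydrogen-bond extremes for PDB entries 5LSD,
1BTG, 4EAX and 4XPJ once those files are placed under `data/pdb/` (the
script prints the `curl` commands; coordinates are not redistributed
here, and the corresponding tests fail with a diagnostic until the files
are present).

## Command-line tool

`nmrens` exposes the steps individually: `rmsd`, `rmsf`, `distance`,
`helicity`, `cluster`, `tauc`, `epitope`, `synth
ensemble|titration|relaxation`, and `run --config analysis.yml` for the
config-driven pipeline (see `nmrens <command> --help`).
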