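# Methods

This note records the models, estimators, numerical choices and known
limitations behind `nmrens`, in the package's own terms.

## Coordinates, numbering, selections

All coordinates are Å; residue numbers are the deposited PDB numbering,
1-based and never re-indexed, because the surrounding literature cites
residues by those numbers. Multi-model PDB files are parsed with gemmi;
alternate locations resolve to the highest-occupancy conformer (first on
ties), ATOM records and HETATM records carrying standard amino acids are
kept, waters and ligands dropped. An ensemble's topology is the ordered
intersection of atom keys across models: atoms missing from any model are
kept on their models but excluded from ensemble math, which makes NMR
bundles and crystal structures with disordered residues comparable
without special cases. Selections are (chains, inclusive residue ranges,
atom-name set); the backbone set is {N, CA, C, O}. An empty resolved
selection is always an error — every downstream quantity is undefined
on it.

## Superposition and RMSD

Rigid superposition is the closed-form least-squares fit via SVD of the
3×3 correlation matrix, with the smallest singular direction flipped when
the naive solution is a reflection; point sets whose second singular value
vanishes (collinear or coincident) are rejected rather than silently
fitted. The test suite checks the implementation against an independent
quaternion (Horn) oracle and against scipy's `Rotation.align_vectors`.

Ensemble RMSD is mean-to-reference: each model is superposed on the
reference (by default the first model, which in an energy-ranked bundle is
the lowest-energy structure) over the chosen selection and scored on that
same selection; mean ± sd are taken over the non-reference models.
Superposed RMSD is not a metric, so no triangle-inequality property is
asserted anywhere — only symmetry and non-negativity.

For RMSD between two homodimeric structures the chain correspondence is
not knowable from labels, so `cross_rmsd` evaluates every chain bijection
and keeps the lowest value; comparisons against crystal structures with
unmodelled residues restrict to the atoms present in both models.

RMSF superposes all models on the evolving ensemble mean (up to five
iterations, converged when the mean stops moving; the first model seeds
the reference) over a fit selection — all Cα by default, a rigid-core
selection when a core-fitted baseline is wanted — then reports the RMS
deviation of each Cα from its mean position, averaged per residue.

## Helix classification

A residue *i* is labelled from its own donor bonds: `alpha` when
O(i)…NH(i+4) is within hydrogen-bond distance, else `three_ten` when
O(i)…NH(i+3) is, else `none`. Cutoffs are standard hydrogen-bond
geometry — O…N ≤ 3.5 Å, O…H ≤ 2.7 Å when the amide hydrogen exists —
and both are configurable. The O…H criterion is used whenever hydrogens
are present (NMR models); the O…N fallback covers X-ray structures. α
takes precedence on bifurcated bonds, following DSSP-style convention.
There is no angular criterion by default, because hydrogen placement in
NMR ensembles is model-dependent while heavy-atom distances are robust; an
optional Ramachandran gate (φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]) is
available instead. A segment-level statistic reports the share of models
in which a span contains at least k (default 3) consecutive helical
residues; "helical" counts both α and 3₁₀. On programmatically built
canonical helices the classifier is exact for interior residues; chain
ends where i+3 does not exist are ill-posed and raise.

## Clustering

The GROMOS/Daura scheme is re-implemented directly: compute the matrix of
pairwise superposed RMSDs over the clustering selection (fit and score on
the same atoms, so a backbone clustering is backbone throughout), then
greedily extract the conformer with the most neighbours within the cutoff
together with those neighbours, repeating on the remainder. All ties —
neighbour counts, equal cluster sizes — break toward the lowest model
index, making results deterministic. The conventional cutoff 0.15 nm is
stored as 1.5 Å internally; the CLI accepts an explicit `nm` or `A`
suffix. The implementation is tested against a brute-force re-derivation
that recounts neighbours from scratch each round.

## Correlation time and flexibility

τc uses the isotropic rigid-rotor approximation of the T1/T2 ratio,
τc = √(6·(T1/T2) − 7)/(4π·ν_N), valid when ω·τc ≫ 1, i.e. for a folded
protein at high field. It is a ratio estimator, deliberately free of
spectral-density fitting: no Lipari–Szabo order parameters, no
anisotropic diffusion tensor. Residues enter the average only if (a) both
T1 and T2 are present with T1/T2 > 7/6 (below which the square root is
undefined), (b) their hetNOE is at or above the rigidity threshold
(default 0.7; internal motion biases the ratio down), and (c) their ratio
lies within median ± 1.5·IQR of the eligible set (conformational exchange
shortens T2 and inflates the ratio; the trim removes such outliers).
ν_N is derived from a proton-frequency field specification via
|γN|/γH = 0.10137. Flexibility classification is independent of τc:
hetNOE below a threshold (a number, or the profile mean) flags a residue
flexible.

## Titration analysis

Combined CSP is the standard ¹⁵N-weighted distance
Δδ = √(ΔδH² + (α·ΔδN)²) with α = 0.14. Classification from the final
titration point applies, in order of precedence: `disappeared` when the
peak is gone or its intensity ratio falls below 0.1; `attenuated` when
the ratio falls below 0.5; `shifted` when Δδ reaches the significance
threshold (default: mean + 1 sd of the observed Δδ distribution);
`unaffected` otherwise. The intensity thresholds are package defaults for
sorting slow / slow-intermediate / fast exchange — the regimes themselves
are physical, the cutoffs are tunable conventions. Sub-stoichiometric
titrations mean classes reflect exchange regime rather than saturation,
so no dissociation constant is ever fitted. Epitope patches are connected
components (≥2 residues) of the graph joining affected residues whose
minimal inter-residue distance is within a contact cutoff — 8 Å between
Cα by default, or ~5 Å in all-heavy-atom mode; isolated affected residues
are reported separately rather than forced into patches.

## Synthetic data: what it emulates, what it does not

Scaffolds are built residue-by-residue from ideal backbone internal
coordinates (NeRF construction) at given (φ, ψ): bond lengths N–CA 1.458,
CA–C 1.525, C–N 1.329, C=O 1.231, N–H 1.010 Å; angles N–CA–C 111.2°,
CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°. Carbonyl O lies in the peptide
plane at dihedral ψ + 180°, the amide H trans to the preceding carbonyl
carbon at φ + 180°. Canonical dihedrals: α (−57°, −47°), 3₁₀
(−49°, −26°), extended (180°, 180°), β-strand (−120°, 130°).

The dimer generator defaults are the study conditions: 20 models, two
118-residue protomers, rigid-core ranges 15–22/51–58/78–89/100–111 at
σ = 0.2 Å, loop ranges 39–47/91–97 at σ = 1.5 Å, N-terminal segment 6–10
helical in half the models. The helical variant carries α dihedrals from
the first donor through its last acceptor (segment end + 4) so every
segment residue's donor bond is helical, and the variants are rigidly
aligned on their shared downstream atoms, so models differ only at the
N-terminus plus noise; the helical models are the lowest-numbered ones,
deterministically. Per-atom iid Gaussian noise of the residue's σ makes
per-residue RMSF ≈ σ√3 and mean model-to-reference RMSD ≈ σ√6 (both
checked as analytic-expectation tests). The scaffold is an extended
chain, not a β-sandwich: inter-protomer distances are geometrically valid
inputs for the distance operators but are not meant to match any real
dimer's values, and passing tests demonstrate operator correctness, not
realism of the toy protein. Real features deliberately absent: side
chains, secondary-structure packing, correlated loop motions,
peak-overlap ambiguity, and assignment errors.

The titration generator moves shifted residues linearly with ligand
equivalents along a fixed random ¹H/¹⁵N direction of combined magnitude
0.08–0.20 ppm (large enough that every generated effect clears the
mean + 1 sd threshold at zero noise), attenuates intensities
geometrically toward a final ratio in 0.15–0.45, and drives disappearing
residues below ratio 0.04; noise is Gaussian on shifts (σ on ¹H, σ/α on
¹⁵N) and on the ratio. Default class sets are the 5/10/14 residue lists
observed in the antibody titration of the NGF study system, at titration
points 0, 0.15 and 0.45 equivalents. The relaxation generator inverts the
τc estimator to set rigid-residue T1/T2 at the target τc (default
14.8 ns, 600 MHz, T1 = 1.1 s), gives flexible residues effective
tumbling of 5–9 ns with hetNOE 0.2–0.6 versus 0.75–0.85 for rigid ones,
and applies independent multiplicative noise (default 2%) to T1 and T2.
All generators are bit-exact under a fixed seed.

## Problem sizes

The analysis drivers and the acceptance script run on the default
generator conditions: 20-model bundles of 2 × 118 residues, 118-residue
titration and relaxation tables, 100 seeded relaxation tables for the
recovery distribution, and 20-frame fixtures for the clustering
cross-checks. These sizes keep every stage comfortably within desk-scale
runtimes while leaving all statistical margins (recovery tolerances,
class-separation gaps) intact.

## Known limitations

- The τc estimator assumes isotropic tumbling and high field; it reports
  a single overall time, not per-residue dynamics.
- Helix classification is donor-bond based and intentionally not a full
  secondary-structure assignment (no sheets, turns, bridges, or
  chemical-shift-based inference).
- The exchange-class intensity cutoffs (0.1, 0.5) are conventions; on
  real titrations the boundaries between regimes are softer than any
  threshold.
- Cross-structure RMSD assumes shared residue numbering between
  depositions; structures renumbered on deposit must be renumbered before
  comparison.
- The pairwise RMSD matrix is O(n²) superpositions and is intended for
  ensembles and down-sampled trajectories, not for >10⁴ raw frames.
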