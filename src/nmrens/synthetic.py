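"""Seeded generators for every input the analyses consume, with ground truth.

The generators emulate the statistical structure of the real data — a
two-protomer ensemble with a rigid core and mobile loops, an N-terminal
segment that is helical in a chosen fraction of models, titration peak
lists with the three exchange-regime classes, and relaxation tables
consistent with one rotational correlation time plus flexible tails — so
that every downstream stage can be scored against a known answer without
downloading anything.

Scaffolds are built residue-by-residue from ideal backbone internal
coordinates (the NeRF construction) given per-residue (φ, ψ); they are
geometrically valid for the operators under test (superposition, distances,
hydrogen-bond geometry) without pretending to be physically realistic
proteins.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .csp_epitope import TitrationSeries
from .geometry import kabsch_superpose
from .io_formats import (
    Atom,
    Ensemble,
    PeakRecord,
    RelaxationRecord,
    StructureModel,
)
from .relaxation import nitrogen_frequency_hz, ratio_from_tau_c

__all__ = [
    "ALPHA_DIHEDRALS",
    "THREE_TEN_DIHEDRALS",
    "EXTENDED_DIHEDRALS",
    "BETA_DIHEDRALS",
    "build_peptide",
    "EnsembleSpec",
    "EnsembleTruth",
    "make_dimer_ensemble",
    "TitrationSpec",
    "TitrationTruth",
    "make_titration",
    "RelaxationSpec",
    "RelaxationTruth",
    "make_relaxation",
]

# canonical backbone dihedrals (degrees)
ALPHA_DIHEDRALS = (-57.0, -47.0)
THREE_TEN_DIHEDRALS = (-49.0, -26.0)
EXTENDED_DIHEDRALS = (180.0, 180.0)
BETA_DIHEDRALS = (-120.0, 130.0)

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_CA_N_H = 120.5, 118.2


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    phi_psi: Sequence[tuple[float, float]],
    chain_id: str = "A",
    start_res: int = 1,
    res_names: Optional[Sequence[str]] = None,
    with_hydrogens: bool = True,
    model_id: int = 1,
) -> StructureModel:
    """Build an ideal-geometry backbone (N, H, CA, C, O) from per-residue (φ, ψ).

    φ of residue 1 is unused (no preceding carbonyl) and residue 1 carries
    no amide hydrogen.  Carbonyl oxygens are placed in the peptide plane
    (dihedral ψ + 180°) and amide hydrogens trans to the preceding carbonyl
    carbon (dihedral φ + 180°), which is what the helix hydrogen-bond
    measurements assume.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    if res_names is None:
        res_names = ["ALA"] * n_res
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    # first C in the xy-plane with an ideal N-CA-C angle
    ang = math.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])

    atoms: list[Atom] = []

    def emit(res_i: int, name: str, pos: np.ndarray) -> None:
        atoms.append(Atom(chain_id, start_res + res_i, res_names[res_i],
                          name, tuple(float(v) for v in pos)))

    prev = {"N": N, "CA": CA, "C": C}
    for i, (phi, psi) in enumerate(phi_psi):
        if i == 0:
            emit(0, "N", N)
            emit(0, "CA", CA)
            emit(0, "C", C)
            o = _place(prev["N"], prev["CA"], prev["C"], _B_C_O, _A_CA_C_O,
                       psi + 180.0)
            emit(0, "O", o)
            continue
        n_i = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N,
                     phi_psi[i - 1][1])  # torsion = psi of previous residue
        ca_i = _place(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = _place(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        emit(i, "N", n_i)
        if with_hydrogens:
            h_i = _place(c_i, ca_i, n_i, _B_N_H, _A_CA_N_H, phi + 180.0)
            emit(i, "H", h_i)
        emit(i, "CA", ca_i)
        emit(i, "C", c_i)
        o_i = _place(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psi + 180.0)
        emit(i, "O", o_i)
        prev = {"N": n_i, "CA": ca_i, "C": c_i}
    return StructureModel(model_id, atoms)


# ---------------------------------------------------------------------------
# Dimer ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """Conditions for a synthetic two-protomer bundle.

    Defaults mirror the analysed system: 20 models of a 118-residue
    protomer pair, rigid core (σ 0.2 Å) at the β-strand ranges, mobile
    loops (σ 1.5 Å) at the loop II / loop V ranges, and an N-terminal
    segment (residues 6–10) helical in half the models.
    """

    n_models: int = 20
    chain_length: int = 118
    chains: tuple[str, str] = ("A", "B")
    core_ranges: tuple[tuple[int, int], ...] = ((15, 22), (51, 58), (78, 89), (100, 111))
    sigma_core: float = 0.2
    loop_ranges: tuple[tuple[int, int], ...] = ((39, 47), (91, 97))
    sigma_loop: float = 1.5
    helix_segment: tuple[int, int] = (6, 10)
    helix_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_core < 0 or self.sigma_loop < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.helix_fraction <= 1.0:
            raise ValueError("helix_fraction must be in [0, 1]")
        for lo, hi in (*self.core_ranges, *self.loop_ranges):
            if not 1 <= lo <= hi <= self.chain_length:
                raise ValueError(f"range ({lo}, {hi}) outside chain")
        lo, hi = self.helix_segment
        # the classifier needs 4 more residues downstream of the last donor
        if not 1 <= lo <= hi <= self.chain_length - 4:
            raise ValueError("helix_segment must end >= 4 residues before the C-terminus")


@dataclass
class EnsembleTruth:
    spec: EnsembleSpec
    helical_models: frozenset[int]  # model ids whose segment is helical
    sigma_by_residue: dict[int, float]
    loop_residues: frozenset[int]
    core_residues: frozenset[int]


def _chain_dihedrals(spec: EnsembleSpec, helical: bool) -> list[tuple[float, float]]:
    lo, hi = spec.helix_segment
    out = []
    for res in range(1, spec.chain_length + 1):
        # donors lo..hi need helical geometry through their i+4 acceptors
        if helical and lo <= res <= hi + 4:
            out.append(ALPHA_DIHEDRALS)
        else:
            out.append(BETA_DIHEDRALS)
    return out


def make_dimer_ensemble(spec: EnsembleSpec) -> tuple[Ensemble, EnsembleTruth]:
    """Generate the bundle and its ground truth.

    The two base conformers (segment helical / segment extended) share
    identical geometry downstream of the helix segment; the helical variant
    is rigidly superposed onto the extended one over that shared part, so
    models differ only at the N-terminal segment plus the per-residue
    Gaussian noise.  ``round(helix_fraction · n_models)`` models — the
    lowest-numbered ones, for determinism — receive the helical segment.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.helix_segment

    base = {}
    for ci, chain_id in enumerate(spec.chains):
        ext = build_peptide(_chain_dihedrals(spec, False), chain_id=chain_id)
        hel = build_peptide(_chain_dihedrals(spec, True), chain_id=chain_id)
        anchor = [a.key for a in ext.atoms if a.res_seq > hi + 4]
        sp = kabsch_superpose(hel.coords(anchor), ext.coords(anchor))
        hel_xyz = sp.apply(np.array([a.xyz for a in hel.atoms]))
        hel_atoms = [
            Atom(a.chain_id, a.res_seq, a.res_name, a.atom_name, tuple(map(float, p)))
            for a, p in zip(hel.atoms, hel_xyz)
        ]
        # place the second protomer head-to-head: flip and offset
        if ci == 1:
            R = np.diag([1.0, -1.0, -1.0])
            t = np.array([0.0, 25.0, 8.0])
            def move(atom_list):
                return [
                    Atom(a.chain_id, a.res_seq, a.res_name, a.atom_name,
                         tuple(map(float, R @ np.asarray(a.xyz) + t)))
                    for a in atom_list
                ]
            ext = StructureModel(1, move(ext.atoms))
            hel_atoms = move(hel_atoms)
        base[chain_id] = {"extended": ext.atoms, "helical": hel_atoms}

    sigma: dict[int, float] = {}
    for res in range(1, spec.chain_length + 1):
        in_loop = any(l <= res <= h for l, h in spec.loop_ranges)
        sigma[res] = spec.sigma_loop if in_loop else spec.sigma_core

    n_helical = round(spec.helix_fraction * spec.n_models)
    helical_models = frozenset(range(1, n_helical + 1))

    models = []
    for mid in range(1, spec.n_models + 1):
        variant = "helical" if mid in helical_models else "extended"
        atoms = []
        for chain_id in spec.chains:
            for a in base[chain_id][variant]:
                noise = rng.normal(0.0, sigma[a.res_seq], size=3)
                atoms.append(
                    Atom(a.chain_id, a.res_seq, a.res_name, a.atom_name,
                         tuple(float(v) for v in np.asarray(a.xyz) + noise))
                )
        models.append(StructureModel(mid, atoms))

    core_res = frozenset(
        r for l, h in spec.core_ranges for r in range(l, h + 1)
    )
    loop_res = frozenset(
        r for l, h in spec.loop_ranges for r in range(l, h + 1)
    )
    truth = EnsembleTruth(
        spec=spec,
        helical_models=helical_models,
        sigma_by_residue=sigma,
        loop_residues=loop_res,
        core_residues=core_res,
    )
    return Ensemble(models), truth


# ---------------------------------------------------------------------------
# Titration series
# ---------------------------------------------------------------------------

# the three perturbation classes observed in the antibody titration
DISAPPEARED_RESIDUES = frozenset({14, 23, 101, 110, 111})
ATTENUATED_RESIDUES = frozenset({26, 39, 45, 46, 52, 65, 93, 99, 100, 115})
SHIFTED_RESIDUES = frozenset({10, 13, 18, 40, 49, 56, 79, 81, 92, 94, 95, 96, 102, 109})

_KNOWN_NAMES = {
    14: "VAL", 23: "GLY", 101: "PHE", 110: "CYS", 111: "VAL",
    26: "THR", 39: "LEU", 45: "ASN", 46: "ASN", 52: "TYR", 65: "GLU",
    93: "ASP", 99: "TRP", 100: "ARG", 115: "LYS",
    10: "GLY", 13: "SER", 18: "VAL", 40: "ALA", 49: "PHE", 56: "THR",
    79: "TYR", 81: "THR", 92: "THR", 94: "GLU", 95: "LYS", 96: "GLN",
    102: "ILE", 109: "VAL",
}


@dataclass
class TitrationSpec:
    """Conditions for a synthetic sub-stoichiometric antibody titration.

    Defaults reproduce the observed class structure: 5 disappearing, 10
    attenuated and 14 significantly shifting residues out of a 118-residue
    universe, sampled at 0.15 and 0.45 ligand equivalents.
    """

    residues: tuple[int, ...] = tuple(range(1, 119))
    chain_id: str = "A"
    disappeared: frozenset[int] = DISAPPEARED_RESIDUES
    attenuated: frozenset[int] = ATTENUATED_RESIDUES
    shifted: frozenset[int] = SHIFTED_RESIDUES
    equivalents: tuple[float, ...] = (0.0, 0.15, 0.45)
    effect_range: tuple[float, float] = (0.08, 0.20)  # combined Δδ, ppm
    attenuation_ratio_range: tuple[float, float] = (0.15, 0.45)
    disappearance_ratio_range: tuple[float, float] = (0.0, 0.04)
    noise_shift: float = 0.0  # ppm, Gaussian on 1H (and scaled 15N) shifts
    noise_ratio: float = 0.0  # Gaussian on the intensity ratio
    alpha: float = 0.14
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [self.disappeared, self.attenuated, self.shifted]
        if sum(len(s) for s in sets) != len(frozenset().union(*sets)):
            raise ValueError("disappeared/attenuated/shifted sets must be disjoint")
        universe = set(self.residues)
        for s in sets:
            if not s <= universe:
                raise ValueError("class residues must be in the residue universe")
        if len(self.equivalents) < 2 or self.equivalents[0] != 0.0:
            raise ValueError("equivalents must start at 0 (the reference)")


@dataclass
class TitrationTruth:
    spec: TitrationSpec
    effects: dict[int, float]  # shifted residue -> combined Δδ at the final point
    final_ratios: dict[int, float]  # attenuated/disappeared residue -> final ratio


def make_titration(spec: TitrationSpec) -> tuple[TitrationSeries, TitrationTruth]:
    """Generate peak lists across the titration and the generating truth.

    Shifted residues move linearly with ligand equivalents along a fixed
    per-residue direction; attenuated and disappearing residues lose
    intensity geometrically toward their final ratio; noise is then applied
    per point.
    """
    rng = np.random.default_rng(spec.seed)
    max_eq = max(spec.equivalents)

    ref_shift_H = {r: rng.uniform(7.0, 10.0) for r in spec.residues}
    ref_shift_N = {r: rng.uniform(105.0, 130.0) for r in spec.residues}
    ref_intensity = {r: float(np.exp(rng.normal(np.log(1e5), 0.3)))
                     for r in spec.residues}

    effects: dict[int, float] = {}
    directions: dict[int, tuple[float, float]] = {}
    for r in sorted(spec.shifted):
        eff = rng.uniform(*spec.effect_range)
        w = rng.uniform(0.2, 0.8)  # split between 1H and 15N contributions
        dh = eff * math.sqrt(w) * rng.choice([-1.0, 1.0])
        dn = eff * math.sqrt(1.0 - w) / spec.alpha * rng.choice([-1.0, 1.0])
        effects[r] = eff
        directions[r] = (dh, dn)
    final_ratios: dict[int, float] = {}
    for r in sorted(spec.attenuated):
        final_ratios[r] = rng.uniform(*spec.attenuation_ratio_range)
    for r in sorted(spec.disappeared):
        final_ratios[r] = rng.uniform(*spec.disappearance_ratio_range)

    name = lambda r: _KNOWN_NAMES.get(r, "ALA")
    lists: list[list[PeakRecord]] = []
    for eq in spec.equivalents:
        frac = eq / max_eq
        peaks = []
        for r in spec.residues:
            sh, sn = ref_shift_H[r], ref_shift_N[r]
            if r in spec.shifted and frac > 0:
                dh, dn = directions[r]
                sh, sn = sh + dh * frac, sn + dn * frac
            ratio = 1.0
            if r in final_ratios and frac > 0:
                ratio = final_ratios[r] ** frac if final_ratios[r] > 0 else (
                    0.0 if frac >= 1.0 else 0.02 ** frac)
            if frac > 0 and spec.noise_shift > 0:
                sh += rng.normal(0.0, spec.noise_shift)
                sn += rng.normal(0.0, spec.noise_shift / spec.alpha)
            if frac > 0 and spec.noise_ratio > 0:
                ratio = max(0.0, ratio + rng.normal(0.0, spec.noise_ratio))
            peaks.append(
                PeakRecord(
                    chain_id=spec.chain_id,
                    res_seq=r,
                    res_name=name(r),
                    shift_H=float(sh),
                    shift_N=float(sn),
                    intensity=float(ref_intensity[r] * ratio),
                )
            )
        lists.append(peaks)
    series = TitrationSeries(equivalents=list(spec.equivalents), peak_lists=lists)
    return series, TitrationTruth(spec=spec, effects=effects, final_ratios=final_ratios)


# ---------------------------------------------------------------------------
# Relaxation tables
# ---------------------------------------------------------------------------

@dataclass
class RelaxationSpec:
    """Conditions for a synthetic 15N relaxation table.

    Rigid residues carry the T1/T2 ratio implied by the target correlation
    time (the inverse of the estimator); flexible residues (loop and
    terminal stretches by default) tumble effectively faster and show
    depressed hetNOE.
    """

    tau_c_ns: float = 14.8
    field_mhz: float = 600.0  # 1H frequency
    residues: tuple[int, ...] = tuple(range(1, 119))
    flexible: frozenset[int] = frozenset(
        set(range(1, 6)) | set(range(40, 49)) | set(range(92, 98))
        | set(range(114, 119))
    )
    t1_seconds: float = 1.1
    flexible_tau_range_ns: tuple[float, float] = (5.0, 9.0)
    rigid_noe_range: tuple[float, float] = (0.75, 0.85)
    flexible_noe_range: tuple[float, float] = (0.2, 0.6)
    noise_fraction: float = 0.02  # multiplicative on T1 and T2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_c_ns <= 0 or self.field_mhz <= 0:
            raise ValueError("tau_c and field must be positive")
        if not self.flexible <= set(self.residues):
            raise ValueError("flexible residues must be in the residue universe")


@dataclass
class RelaxationTruth:
    spec: RelaxationSpec
    flexible: frozenset[int]
    rigid_ratio: float


def make_relaxation(spec: RelaxationSpec
                    ) -> tuple[list[RelaxationRecord], RelaxationTruth]:
    rng = np.random.default_rng(spec.seed)
    nu_n = nitrogen_frequency_hz(spec.field_mhz, "1H")
    rigid_ratio = ratio_from_tau_c(spec.tau_c_ns * 1e-9, nu_n)
    records = []
    for r in spec.residues:
        if r in spec.flexible:
            tau_eff = rng.uniform(*spec.flexible_tau_range_ns) * 1e-9
            ratio = ratio_from_tau_c(tau_eff, nu_n)
            noe = rng.uniform(*spec.flexible_noe_range)
        else:
            ratio = rigid_ratio
            noe = rng.uniform(*spec.rigid_noe_range)
        t1 = spec.t1_seconds * (1.0 + rng.normal(0.0, spec.noise_fraction)
                                if spec.noise_fraction > 0 else 1.0)
        t2 = (t1 / ratio) * (1.0 + rng.normal(0.0, spec.noise_fraction)
                             if spec.noise_fraction > 0 else 1.0)
        records.append(RelaxationRecord(res_seq=r, T1=float(t1), T2=float(t2),
                                        hetNOE=float(noe)))
    truth = RelaxationTruth(spec=spec, flexible=spec.flexible,
                            rigid_ratio=rigid_ratio)
    return records, truth
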