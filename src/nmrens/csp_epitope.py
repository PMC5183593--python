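"""Titration analysis: chemical-shift perturbations, exchange classes, epitope patches.

A ligand titration followed by HSQC spectra sorts the residues of the
antigen into exchange regimes: peaks that *disappear* (slow exchange),
peaks that *decrease in intensity* (slow–intermediate) and peaks that
*shift* continuously (fast exchange).  The combined perturbation uses the
standard 15N-weighted distance

    Δδ = sqrt(ΔδH² + (α·ΔδN)²),  α = 0.14

and classification applies the precedence disappeared > attenuated >
shifted, so a strongly attenuated peak that also moved counts once, in the
slower regime.  Affected residues are then grouped into spatial patches —
connected components of the contact graph on a structure — to expose the
epitope as a surface region rather than a residue list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import PeakRecord, StructureModel

__all__ = [
    "CSPRecord",
    "EpitopeMap",
    "TitrationSeries",
    "TitrationReport",
    "combined_csp",
    "classify_exchange",
    "epitope_patches",
    "titration_report",
]

CLASSES = ("disappeared", "attenuated", "shifted", "unaffected")


@dataclass
class CSPRecord:
    chain_id: str
    res_seq: int
    res_name: str
    delta_H: Optional[float]  # ppm; None when either peak is unobserved
    delta_N: Optional[float]
    delta_combined: Optional[float]
    intensity_ratio: Optional[float]  # titrated / reference
    exchange_class: Optional[str] = None


@dataclass
class TitrationSeries:
    """Peak lists at increasing ligand equivalents; point 0 is the reference."""

    equivalents: list[float]
    peak_lists: list[list[PeakRecord]]

    def __post_init__(self) -> None:
        if len(self.equivalents) != len(self.peak_lists):
            raise ValueError("equivalents and peak lists must align")
        if len(self.equivalents) < 2:
            raise ValueError("a titration needs a reference and >= 1 point")


def combined_csp(
    reference: Sequence[PeakRecord],
    titrated: Sequence[PeakRecord],
    alpha: float = 0.14,
) -> list[CSPRecord]:
    """Per-residue combined CSP and intensity ratio between two peak lists.

    Every reference residue yields a record; residues absent from the
    titrated list (or observed without shifts) get ``None`` deltas and an
    intensity ratio of 0 — the signature of a vanished peak.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    tit = {(p.chain_id, p.res_seq): p for p in titrated}
    if not any((p.chain_id, p.res_seq) in tit for p in reference):
        raise ValueError("reference and titrated lists share no residues")
    out: list[CSPRecord] = []
    for ref in reference:
        t = tit.get((ref.chain_id, ref.res_seq))
        if t is not None and ref.observed and t.observed:
            dh = abs(t.shift_H - ref.shift_H)
            dn = abs(t.shift_N - ref.shift_N)
            dc = float(np.hypot(dh, alpha * dn))
        else:
            dh = dn = dc = None
        if ref.intensity is not None and t is not None and t.intensity is not None:
            ratio = t.intensity / ref.intensity if ref.intensity > 0 else None
        elif t is None or t.intensity is None:
            ratio = 0.0 if ref.intensity is not None else None
        else:
            ratio = None
        out.append(
            CSPRecord(
                chain_id=ref.chain_id,
                res_seq=ref.res_seq,
                res_name=ref.res_name,
                delta_H=dh,
                delta_N=dn,
                delta_combined=dc,
                intensity_ratio=ratio,
            )
        )
    return out


def resolve_csp_threshold(records: Sequence[CSPRecord],
                          threshold: float | str) -> float:
    if isinstance(threshold, str):
        if threshold != "mean+sd":
            raise ValueError("csp_threshold must be a number or 'mean+sd'")
        vals = np.array([r.delta_combined for r in records
                         if r.delta_combined is not None])
        if vals.size == 0:
            raise ValueError("no observed CSPs to derive a threshold from")
        return float(vals.mean() + vals.std(ddof=0))
    return float(threshold)


def classify_exchange(
    records: Sequence[CSPRecord],
    csp_threshold: float | str = "mean+sd",
    attenuation_threshold: float = 0.5,
    disappearance_threshold: float = 0.1,
) -> list[CSPRecord]:
    """Fill the exchange class of each record (precedence: disappeared >
    attenuated > shifted > unaffected)."""
    if all(r.delta_combined is None and r.intensity_ratio is None for r in records):
        raise ValueError("nothing observed: cannot classify")
    thr = resolve_csp_threshold(records, csp_threshold)
    for r in records:
        if r.intensity_ratio is not None and r.intensity_ratio < disappearance_threshold:
            r.exchange_class = "disappeared"
        elif r.delta_combined is None:
            r.exchange_class = "disappeared"  # peak gone without an intensity
        elif r.intensity_ratio is not None and r.intensity_ratio < attenuation_threshold:
            r.exchange_class = "attenuated"
        elif r.delta_combined >= thr:
            r.exchange_class = "shifted"
        else:
            r.exchange_class = "unaffected"
    return list(records)


@dataclass
class EpitopeMap:
    """Spatial patches of affected residues on a structure."""

    patches: list[dict]  # {"residues": set[(chain, res)], "centroid": (x, y, z)}
    unassigned: set  # affected residues that are spatially isolated
    contact_cutoff: float
    mode: str

    @property
    def patch_residue_sets(self) -> list[set]:
        return [p["residues"] for p in self.patches]


def _residue_coords(structure: StructureModel, chain: str, res: int, mode: str
                    ) -> np.ndarray:
    if mode == "ca":
        if structure.has(chain, res, "CA"):
            return structure.coords([(chain, res, "CA")])
        raise KeyError(f"no CA for residue {res} chain {chain}")
    atoms = [a for a in structure.atoms
             if a.chain_id == chain and a.res_seq == res
             and not a.atom_name.startswith("H")]
    if not atoms:
        raise KeyError(f"no heavy atoms for residue {res} chain {chain}")
    return np.array([a.xyz for a in atoms])


def epitope_patches(
    structure: StructureModel,
    affected: Sequence,
    contact_cutoff: float = 8.0,
    mode: str = "ca",
) -> EpitopeMap:
    """Group affected residues into spatial patches on ``structure``.

    ``affected`` holds residue numbers (applied to every chain that has
    them) or explicit ``(chain, res_seq)`` pairs.  Residues are connected
    when their minimal inter-residue distance is within ``contact_cutoff``
    (default 8 Å between Cα; ``mode="heavy"`` with ~5 Å is the all-heavy-atom
    alternative).  Patches are connected components with >= 2 residues;
    isolated residues are reported unassigned.
    """
    if mode not in ("ca", "heavy"):
        raise ValueError("mode must be 'ca' or 'heavy'")
    pairs: list[tuple[str, int]] = []
    for item in affected:
        if isinstance(item, tuple):
            pairs.append((str(item[0]), int(item[1])))
        else:
            for ch in structure.chains:
                if any(a.chain_id == ch and a.res_seq == int(item)
                       for a in structure.atoms):
                    pairs.append((ch, int(item)))
    pairs = sorted(set(pairs))
    if not pairs:
        raise ValueError("no affected residue found in the structure")
    coords = [_residue_coords(structure, ch, r, mode) for ch, r in pairs]
    n = len(pairs)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :],
                               axis=2).min()
            if d <= contact_cutoff:
                rows += [i, j]
                cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    patches = []
    unassigned: set = set()
    for comp in range(n_comp):
        members = [pairs[i] for i in range(n) if labels[i] == comp]
        if len(members) < 2:
            unassigned.update(members)
            continue
        pts = np.vstack([coords[i] for i in range(n) if labels[i] == comp])
        patches.append({"residues": set(members),
                        "centroid": tuple(pts.mean(axis=0))})
    patches.sort(key=lambda p: (-len(p["residues"]), sorted(p["residues"])[0]))
    return EpitopeMap(patches=patches, unassigned=unassigned,
                      contact_cutoff=contact_cutoff, mode=mode)


@dataclass
class TitrationReport:
    per_point: list[pd.DataFrame]  # CSP table per titration point (vs reference)
    final_records: list[CSPRecord]
    class_members: dict[str, list[int]]  # class -> residue numbers
    epitope: Optional[EpitopeMap]
    new_epitope_residues: Optional[set] = None
    known_epitope_residues: Optional[set] = None


def _records_frame(records: Sequence[CSPRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain": [r.chain_id for r in records],
            "res_seq": [r.res_seq for r in records],
            "res_name": [r.res_name for r in records],
            "delta_H": [r.delta_H for r in records],
            "delta_N": [r.delta_N for r in records],
            "delta_combined": [r.delta_combined for r in records],
            "intensity_ratio": [r.intensity_ratio for r in records],
            "class": [r.exchange_class for r in records],
        }
    )


def titration_report(
    series: TitrationSeries,
    structure: Optional[StructureModel] = None,
    alpha: float = 0.14,
    csp_threshold: float | str = "mean+sd",
    attenuation_threshold: float = 0.5,
    disappearance_threshold: float = 0.1,
    contact_cutoff: float = 8.0,
    prior_epitope: Optional[Sequence[int]] = None,
) -> TitrationReport:
    """Full titration analysis: per-point CSP tables, final classes, epitope map.

    Classes come from the last titration point (largest ligand excess); the
    epitope map is built from all residues whose class is not ``unaffected``.
    With ``prior_epitope`` the affected residues are split into previously
    known and newly identified sets.
    """
    reference = series.peak_lists[0]
    ref_universe = {(p.chain_id, p.res_seq) for p in reference}
    for pl in series.peak_lists[1:]:
        extra = {(p.chain_id, p.res_seq) for p in pl} - ref_universe
        if extra:
            raise ValueError(f"titration point contains unknown residues: {sorted(extra)}")
    per_point = []
    final_records: list[CSPRecord] = []
    for pl in series.peak_lists[1:]:
        recs = combined_csp(reference, pl, alpha=alpha)
        per_point.append(_records_frame(recs))
        final_records = recs
    final_records = classify_exchange(
        final_records,
        csp_threshold=csp_threshold,
        attenuation_threshold=attenuation_threshold,
        disappearance_threshold=disappearance_threshold,
    )
    per_point[-1] = _records_frame(final_records)
    class_members = {
        c: sorted(r.res_seq for r in final_records if r.exchange_class == c)
        for c in CLASSES
    }
    affected = [r.res_seq for r in final_records
                if r.exchange_class not in (None, "unaffected")]
    epitope = None
    if structure is not None and affected:
        epitope = epitope_patches(structure, affected, contact_cutoff=contact_cutoff)
    known = new = None
    if prior_epitope is not None:
        prior = set(int(r) for r in prior_epitope)
        known = set(affected) & prior
        new = set(affected) - prior
    return TitrationReport(
        per_point=per_point,
        final_records=final_records,
        class_members=class_members,
        epitope=epitope,
        new_epitope_residues=new,
        known_epitope_residues=known,
    )
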