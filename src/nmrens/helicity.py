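"""Per-residue helix classification from backbone hydrogen-bond geometry.

A residue is labelled ``alpha`` when its carbonyl oxygen forms an i→i+4
hydrogen bond, ``three_ten`` when (failing that) it forms an i→i+3 bond, and
``none`` otherwise.  Distance criteria follow standard hydrogen-bond
geometry — O…N ≤ 3.5 Å, or O…H ≤ 2.7 Å when amide hydrogens are present —
and α takes precedence over 3₁₀ when both bonds exist (the bifurcated case),
mirroring DSSP-style precedence.  An optional dihedral gate restricts labels
to the helical region of the Ramachandran map; it is off by default because
hydrogen placement in NMR ensembles is model-dependent while the heavy-atom
distances are robust.

This intentionally stops short of a full secondary-structure assignment
(no sheets, turns or bridges): the question it answers is the one asked of
nascent helices — does this stretch of backbone make helical hydrogen bonds,
and in what fraction of the bundle or trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import hbond_distance
from .io_formats import Ensemble, StructureModel

__all__ = [
    "HelixCriteria",
    "HelicityProfile",
    "classify_residue_helix",
    "helical_fraction",
    "nterm_hbond_report",
]

LABELS = ("alpha", "three_ten", "none")


@dataclass(frozen=True)
class HelixCriteria:
    """Distance (and optional dihedral) criteria for helix hydrogen bonds."""

    o_n_cutoff: float = 3.5  # Å, O(i)…N(i+n)
    o_h_cutoff: float = 2.7  # Å, O(i)…H(i+n) when the amide H exists
    use_hydrogen: str = "auto"  # auto | never | always
    dihedral_gate: bool = False
    phi_range: tuple[float, float] = (-100.0, -30.0)
    psi_range: tuple[float, float] = (-80.0, -5.0)


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(model: StructureModel, chain: str, res: int
                       ) -> tuple[Optional[float], Optional[float]]:
    """(φ, ψ) of a residue, ``None`` at chain ends or with missing atoms."""
    def atom(r, name):
        return model.get(chain, r, name).coord if model.has(chain, r, name) else None

    c_prev = atom(res - 1, "C")
    n, ca, c = atom(res, "N"), atom(res, "CA"), atom(res, "C")
    n_next = atom(res + 1, "N")
    core_ok = n is not None and ca is not None and c is not None
    phi = _dihedral(c_prev, n, ca, c) if core_ok and c_prev is not None else None
    psi = _dihedral(n, ca, c, n_next) if core_ok and n_next is not None else None
    return phi, psi


def _bond_ok(model, chain, res, offset, criteria: HelixCriteria) -> bool:
    acceptor = res + offset
    if not (model.has(chain, acceptor, "N") or model.has(chain, acceptor, "H")):
        return False
    if not model.has(chain, res, "O"):
        return False
    d, conv = hbond_distance(model, chain, res, offset,
                             use_hydrogen=criteria.use_hydrogen)
    cutoff = criteria.o_h_cutoff if conv == "O...H" else criteria.o_n_cutoff
    return d <= cutoff


def classify_residue_helix(
    model: StructureModel,
    chain: str,
    res: int,
    criteria: HelixCriteria = HelixCriteria(),
) -> str:
    """Label residue ``res`` as ``alpha``, ``three_ten`` or ``none``.

    Requires at least residue ``res + 3`` to exist (otherwise the question is
    ill-posed and a ``ValueError`` is raised); an absent ``res + 4`` simply
    rules out the α bond.
    """
    if not (model.has(chain, res + 3, "N") or model.has(chain, res + 3, "H")):
        raise ValueError(
            f"chain {chain} too short at residue {res}: no residue {res + 3}"
        )
    if criteria.dihedral_gate:
        phi, psi = backbone_dihedrals(model, chain, res)
        lo_f, hi_f = criteria.phi_range
        lo_p, hi_p = criteria.psi_range
        if phi is None or psi is None or not (lo_f <= phi <= hi_f and lo_p <= psi <= hi_p):
            return "none"
    has_i4 = model.has(chain, res + 4, "N") or model.has(chain, res + 4, "H")
    if has_i4 and _bond_ok(model, chain, res, 4, criteria):
        return "alpha"
    if _bond_ok(model, chain, res, 3, criteria):
        return "three_ten"
    return "none"


@dataclass
class HelicityProfile:
    """Per-(model, residue) helix labels with aggregate per-residue fractions.

    ``segment_fraction`` is the share of models in which the analysed span
    contains at least ``k_consecutive`` consecutive helical (α or 3₁₀)
    residues — the bundle-level statistic behind statements like "in almost
    half the models the segment is helical".
    """

    labels: dict[tuple[int, str, int], str]  # (model_id, chain, res) -> label
    fraction_alpha: dict[int, float]
    fraction_310: dict[int, float]
    fraction_helical: dict[int, float]
    segment_fraction: float
    k_consecutive: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "chain": c, "res_seq": r, "label": lab}
            for (m, c, r), lab in self.labels.items()
        ]
        return pd.DataFrame(rows)


def helical_fraction(
    ensemble: Ensemble,
    chain: str,
    span: tuple[int, int],
    criteria: HelixCriteria = HelixCriteria(),
    k_consecutive: int = 3,
) -> HelicityProfile:
    """Classify every span residue in every model; aggregate the fractions.

    ``fraction_helical`` counts both α and 3₁₀ labels, matching the usual
    reading of "time spent in a helical conformation".
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    lo, hi = span
    labels: dict[tuple[int, str, int], str] = {}
    n_models = len(ensemble)
    counts = {r: {"alpha": 0, "three_ten": 0} for r in range(lo, hi + 1)}
    n_segment = 0
    for m in ensemble.models:
        run = best_run = 0
        for r in range(lo, hi + 1):
            lab = classify_residue_helix(m, chain, r, criteria)
            labels[(m.model_id, chain, r)] = lab
            if lab != "none":
                counts[r][lab] += 1
                run += 1
                best_run = max(best_run, run)
            else:
                run = 0
        if best_run >= k_consecutive:
            n_segment += 1
    frac_a = {r: counts[r]["alpha"] / n_models for r in counts}
    frac_3 = {r: counts[r]["three_ten"] / n_models for r in counts}
    return HelicityProfile(
        labels=labels,
        fraction_alpha=frac_a,
        fraction_310=frac_3,
        fraction_helical={r: frac_a[r] + frac_3[r] for r in counts},
        segment_fraction=n_segment / n_models,
        k_consecutive=k_consecutive,
    )


def nterm_hbond_report(
    ensemble: Ensemble,
    chain: str,
    donor_span: tuple[int, int],
    use_hydrogen: str = "auto",
) -> tuple[pd.DataFrame, dict]:
    """Tabulate O(i)…NH(i+3) and O(i)…NH(i+4) distances over a donor span.

    Returns the full per-model table (model, donor, offset, distance,
    convention) and a summary with the bundle-wide minimum and maximum plus
    the mean per (donor, offset).  Donors whose acceptor residue falls
    outside the chain are skipped; a donor missing its carbonyl oxygen in
    any model is an error.
    """
    lo, hi = donor_span
    rows = []
    for m in ensemble.models:
        for donor in range(lo, hi + 1):
            if not m.has(chain, donor, "O"):
                raise KeyError(
                    f"carbonyl O of donor {donor} chain {chain} missing "
                    f"in model {m.model_id}"
                )
            for offset in (3, 4):
                acceptor = donor + offset
                if not (m.has(chain, acceptor, "N") or m.has(chain, acceptor, "H")):
                    continue
                d, conv = hbond_distance(m, chain, donor, offset, use_hydrogen)
                rows.append(
                    {"model": m.model_id, "donor": donor, "offset": offset,
                     "distance": d, "convention": conv}
                )
    if not rows:
        raise ValueError("no measurable donor/acceptor pairs in the span")
    df = pd.DataFrame(rows)
    summary = {
        "min": float(df["distance"].min()),
        "max": float(df["distance"].max()),
        "mean_per_pair": {
            (int(d), int(o)): float(g["distance"].mean())
            for (d, o), g in df.groupby(["donor", "offset"])
        },
    }
    return df, summary
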