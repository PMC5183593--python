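"""Interpretation of per-residue 15N relaxation: tumbling time and flexibility.

The overall rotational correlation time τc is estimated from the T1/T2
ratio with the isotropic rigid-rotor approximation (valid when ω·τc ≫ 1,
i.e. for folded proteins at high field):

    τc = sqrt(6·(T1/T2) − 7) / (4π·ν_N)

with ν_N the 15N Larmor frequency in Hz.  Only residues that tumble with
the molecule should enter the estimate, so residues flagged flexible by a
low heteronuclear NOE and residues whose T1/T2 lies outside
median ± 1.5·IQR (conformational exchange broadens T2 and inflates the
ratio) are excluded before averaging.

Flexibility itself is read straight off the hetNOE: values below the
profile average (≈0.7 for a folded protein at 600 MHz) indicate fast
internal motion of that amide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import RelaxationRecord

__all__ = [
    "GAMMA_N_OVER_H",
    "CorrelationTimeResult",
    "FlexibilityProfile",
    "tau_c_from_ratio",
    "ratio_from_tau_c",
    "estimate_tau_c",
    "flexibility_flags",
]

#: |γ(15N)| / γ(1H); converts a proton spectrometer frequency to ν_N.
GAMMA_N_OVER_H = 0.10137


def tau_c_from_ratio(ratio: float, nu_n_hz: float) -> float:
    """τc in seconds from a T1/T2 ratio at 15N frequency ``nu_n_hz``."""
    if ratio < 7.0 / 6.0:
        raise ValueError("T1/T2 below 7/6: rigid-rotor estimate undefined")
    return math.sqrt(6.0 * ratio - 7.0) / (4.0 * math.pi * nu_n_hz)


def ratio_from_tau_c(tau_c_s: float, nu_n_hz: float) -> float:
    """Inverse of :func:`tau_c_from_ratio`: the T1/T2 ratio a rigid residue shows."""
    if tau_c_s <= 0:
        raise ValueError("tau_c must be positive")
    x = 4.0 * math.pi * nu_n_hz * tau_c_s
    return (x * x + 7.0) / 6.0


def nitrogen_frequency_hz(field_mhz: float, nucleus: str = "1H") -> float:
    """15N Larmor frequency in Hz from a field stated as 1H or 15N MHz."""
    if nucleus == "1H":
        return field_mhz * 1e6 * GAMMA_N_OVER_H
    if nucleus == "15N":
        return field_mhz * 1e6
    raise ValueError("nucleus must be '1H' or '15N'")


@dataclass
class CorrelationTimeResult:
    tau_c_ns: float
    per_residue_ns: dict[int, float]  # every residue with a defined estimate
    residues_used: frozenset[int]  # survivors of the rigidity/outlier filters
    nu_n_hz: float


def estimate_tau_c(
    records: Sequence[RelaxationRecord],
    field_mhz: float,
    nucleus: str = "1H",
    noe_threshold: Optional[float] = 0.7,
    iqr_factor: float = 1.5,
) -> CorrelationTimeResult:
    """Overall τc (ns) from per-residue T1/T2, filtered to rigid residues.

    ``noe_threshold`` excludes residues with hetNOE below it (``None``
    disables the filter); the median ± ``iqr_factor``·IQR trim on T1/T2
    removes exchange-broadened outliers.  The reported τc is the mean of
    the surviving per-residue estimates.
    """
    if field_mhz <= 0:
        raise ValueError("field must be positive")
    nu_n = nitrogen_frequency_hz(field_mhz, nucleus)
    with_both = [r for r in records if r.T1 is not None and r.T2 is not None]
    if len(with_both) < 5:
        raise ValueError("need at least 5 residues with both T1 and T2")
    ratios = {r.res_seq: r.T1 / r.T2 for r in with_both}
    per_res = {
        res: tau_c_from_ratio(ratio, nu_n) * 1e9
        for res, ratio in ratios.items()
        if ratio > 7.0 / 6.0
    }
    if not per_res:
        raise ValueError("no residue has T1/T2 > 7/6; estimate undefined")

    eligible = set(per_res)
    if noe_threshold is not None:
        for r in with_both:
            if r.hetNOE is not None and r.hetNOE < noe_threshold:
                eligible.discard(r.res_seq)
    vals = np.array([ratios[res] for res in eligible])
    if vals.size:
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = med - iqr_factor * iqr, med + iqr_factor * iqr
        eligible = {res for res in eligible if lo <= ratios[res] <= hi}
    if not eligible:
        raise ValueError("all residues rejected by the rigidity/outlier filters")
    tau = float(np.mean([per_res[res] for res in eligible]))
    return CorrelationTimeResult(
        tau_c_ns=tau,
        per_residue_ns=per_res,
        residues_used=frozenset(eligible),
        nu_n_hz=nu_n,
    )


@dataclass
class FlexibilityProfile:
    classes: dict[int, str]  # res_seq -> "rigid" | "flexible"
    threshold: float

    @property
    def flexible(self) -> frozenset[int]:
        return frozenset(r for r, c in self.classes.items() if c == "flexible")


def flexibility_flags(
    records: Sequence[RelaxationRecord],
    threshold: float | str = "mean",
) -> FlexibilityProfile:
    """Classify residues rigid/flexible by hetNOE against a threshold.

    ``threshold="mean"`` resolves to the mean hetNOE over observed residues
    (the natural baseline: a folded protein's profile is flat near it, and
    mobile tails and loops dip below).
    """
    observed = [r for r in records if r.hetNOE is not None]
    if not observed:
        raise ValueError("no hetNOE data")
    thr = float(np.mean([r.hetNOE for r in observed])) if threshold == "mean" \
        else float(threshold)
    classes = {
        r.res_seq: ("flexible" if r.hetNOE < thr else "rigid") for r in observed
    }
    return FlexibilityProfile(classes=classes, threshold=thr)
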