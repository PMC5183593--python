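"""Rigid-body superposition, RMSD/RMSF and the distance metrics of the analyses.

All distances are Å.  The superposition is the classic least-squares rigid
fit (Kabsch, via SVD with reflection correction); RMSD between structures is
computed after superposing on the same selection unless ``superpose=False``.

For homodimers compared across depositions the chain labelling is arbitrary
(protomer 1 of one structure may correspond to protomer 2 of another), so
cross-structure RMSD can try every chain bijection and keep the lowest value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    AtomKey,
    Ensemble,
    Selection,
    StructureModel,
    select_keys,
)

__all__ = [
    "SuperpositionResult",
    "DistanceResult",
    "RMSFProfile",
    "EnsembleRMSDResult",
    "kabsch_superpose",
    "rmsd_between",
    "cross_rmsd",
    "ensemble_rmsd",
    "rmsf",
    "ca_distance",
    "distance_series",
    "hbond_distance",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference: x' = R @ x + t."""

    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Both arrays are (n, 3) with n >= 3 non-collinear points.  The rotation is
    forced proper (a reflection in the SVD solution is corrected by flipping
    the smallest singular direction), and the reported RMSD is computed after
    applying the transform.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear/coincident point sets leave the rotation underdetermined
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate point set: collinear or coincident points")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt((d * d).sum() / a.shape[0]))


def _mapped_keys(keys: Sequence[AtomKey], chain_map: dict[str, str]) -> list[AtomKey]:
    return [(chain_map.get(c, c), r, a) for (c, r, a) in keys]


def rmsd_between(
    model_a: StructureModel,
    model_b: StructureModel,
    sel: Selection,
    superpose: bool = True,
    chain_map: Optional[dict[str, str]] = None,
    allow_missing: bool = False,
) -> float:
    """RMSD between two models over a selection, optionally after superposition.

    ``chain_map`` maps chains of ``model_a`` onto chains of ``model_b``
    (homodimer protomers may be labelled differently across depositions).
    With ``allow_missing`` the comparison silently restricts to atoms present
    in both models — needed against crystal structures whose disordered
    residues are absent.
    """
    keys_a = [a.key for a in model_a.atoms if sel.matches(a.key)]
    if not keys_a:
        raise ValueError("selection matched no atoms in the first model")
    cmap = chain_map or {}
    pairs = [(ka, kb) for ka, kb in zip(keys_a, _mapped_keys(keys_a, cmap))]
    if allow_missing:
        pairs = [(ka, kb) for ka, kb in pairs if kb in model_b]
        if not pairs:
            raise ValueError("no selected atoms shared by both models")
    A = model_a.coords([ka for ka, _ in pairs])
    B = model_b.coords([kb for _, kb in pairs])
    if superpose:
        return kabsch_superpose(A, B).rmsd
    return _raw_rmsd(A, B)


def cross_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    sel: Selection,
    superpose: bool = True,
    allow_missing: bool = True,
) -> tuple[float, dict[str, str]]:
    """Minimum RMSD over every chain bijection between the two models.

    Returns ``(rmsd, chain_map)`` for the best mapping.  This is the honest
    comparison for homodimers, where which protomer is "A" is a deposition
    accident.
    """
    chains_a = model_a.chains
    chains_b = model_b.chains
    if len(chains_b) < len(chains_a):
        raise ValueError("second model has fewer chains than the first")
    best: tuple[float, dict[str, str]] | None = None
    for perm in itertools.permutations(chains_b, len(chains_a)):
        cmap = dict(zip(chains_a, perm))
        try:
            r = rmsd_between(model_a, model_b, sel, superpose=superpose,
                             chain_map=cmap, allow_missing=allow_missing)
        except ValueError:
            continue
        if best is None or r < best[0]:
            best = (r, cmap)
    if best is None:
        raise ValueError("no chain mapping yields a comparable atom set")
    return best


@dataclass
class EnsembleRMSDResult:
    """Per-model RMSD to a reference model plus the bundle mean ± sd."""

    reference_index: int
    per_model: list[float]  # one entry per model, reference entry is 0.0
    mean: float  # over non-reference models
    sd: float


def ensemble_rmsd(
    ensemble: Ensemble,
    sel: Selection,
    reference: int | str = "lowest-index",
) -> EnsembleRMSDResult:
    """RMSD of every model to a reference model after superposition on ``sel``.

    The reference defaults to the first model — for an energy-ranked NMR
    bundle that is the lowest-energy structure.  Mean and sd are taken over
    the non-reference models.
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble RMSD needs at least 2 models")
    ref_i = 0 if reference == "lowest-index" else int(reference)
    if not 0 <= ref_i < len(ensemble):
        raise IndexError(f"reference index {ref_i} out of range")
    keys = select_keys(ensemble.topology_key, sel)
    coords = ensemble.coords(keys)
    ref = coords[ref_i]
    per_model = []
    for i in range(len(ensemble)):
        per_model.append(0.0 if i == ref_i else kabsch_superpose(coords[i], ref).rmsd)
    others = [v for i, v in enumerate(per_model) if i != ref_i]
    return EnsembleRMSDResult(
        reference_index=ref_i,
        per_model=per_model,
        mean=float(np.mean(others)),
        sd=float(np.std(others, ddof=1)) if len(others) > 1 else 0.0,
    )


@dataclass
class RMSFProfile:
    """Per-residue positional fluctuation (Å) about the ensemble mean."""

    values: dict[tuple[str, int], float]  # (chain, res_seq) -> Å

    def as_arrays(self) -> tuple[list[tuple[str, int]], np.ndarray]:
        keys = list(self.values)
        return keys, np.array([self.values[k] for k in keys])


def rmsf(
    ensemble: Ensemble,
    sel: Optional[Selection] = None,
    fit_sel: Optional[Selection] = None,
    n_iter: int = 5,
) -> RMSFProfile:
    """Root-mean-square fluctuation per residue about the ensemble mean.

    Models are iteratively superposed on the evolving ensemble mean over
    ``fit_sel`` (default: all Cα — pass a rigid-core selection to mimic a
    core-fitted baseline), then the fluctuation of each ``sel`` atom
    (default Cα) about its mean position is averaged per residue.
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least 2 models")
    sel = sel or Selection.calpha()
    fit_sel = fit_sel or Selection.calpha()
    fit_keys = select_keys(ensemble.topology_key, fit_sel)
    out_keys = select_keys(ensemble.topology_key, sel)
    all_keys = list(dict.fromkeys(list(fit_keys) + list(out_keys)))
    fit_idx = [all_keys.index(k) for k in fit_keys]
    out_idx = [all_keys.index(k) for k in out_keys]

    X = ensemble.coords(all_keys)  # (M, n, 3)
    ref = X[0, fit_idx].copy()
    for _ in range(n_iter):
        fitted = np.empty_like(X)
        for m in range(X.shape[0]):
            sp = kabsch_superpose(X[m, fit_idx], ref)
            fitted[m] = sp.apply(X[m])
        new_ref = fitted[:, fit_idx].mean(axis=0)
        if np.allclose(new_ref, ref, atol=1e-10):
            X = fitted
            break
        ref = new_ref
        X = fitted

    mean_pos = X.mean(axis=0)
    sq = ((X - mean_pos) ** 2).sum(axis=2)  # (M, n)
    atom_rmsf = np.sqrt(sq.mean(axis=0))  # (n,)

    per_res: dict[tuple[str, int], list[float]] = {}
    for j, k in zip(out_idx, out_keys):
        per_res.setdefault((k[0], k[1]), []).append(atom_rmsf[j])
    return RMSFProfile(values={k: float(np.mean(v)) for k, v in per_res.items()})


def ca_distance(
    model: StructureModel, chain_a: str, res_a: int, chain_b: str, res_b: int
) -> float:
    """Euclidean Cα–Cα distance, e.g. the inter-protomer loop-tip separations."""
    a = model.get(chain_a, res_a, "CA").coord
    b = model.get(chain_b, res_b, "CA").coord
    return float(np.linalg.norm(a - b))


@dataclass
class DistanceResult:
    """A labelled atom-pair distance evaluated across every model/frame."""

    label: str
    pair: tuple[AtomKey, AtomKey]
    distances: np.ndarray  # one value per model, in model order


def distance_series(ensemble: Ensemble, atom_a: AtomKey, atom_b: AtomKey,
                    label: Optional[str] = None) -> DistanceResult:
    """Distance between two atoms evaluated in every model, in order."""
    for k in (atom_a, atom_b):
        for m in ensemble.models:
            if k not in m:
                raise KeyError(f"atom {k} missing from model {m.model_id}")
    A = ensemble.coords([atom_a])[:, 0, :]
    B = ensemble.coords([atom_b])[:, 0, :]
    d = np.linalg.norm(A - B, axis=1)
    if label is None:
        label = f"{atom_a[0]}{atom_a[1]}:{atom_a[2]}-{atom_b[0]}{atom_b[1]}:{atom_b[2]}"
    return DistanceResult(label=label, pair=(atom_a, atom_b), distances=d)


def hbond_distance(
    model: StructureModel,
    chain: str,
    donor_res: int,
    offset: int,
    use_hydrogen: str = "auto",
) -> tuple[float, str]:
    """Backbone helix hydrogen-bond distance O(i)…NH(i+n), n in {3, 4}.

    Measures from the carbonyl oxygen of residue ``donor_res`` to the amide
    of residue ``donor_res + offset``.  With ``use_hydrogen="auto"`` the
    amide hydrogen is used when present (NMR models) and the nitrogen
    otherwise (X-ray structures without hydrogens); ``"never"`` forces O…N,
    ``"always"`` requires the hydrogen.  Returns ``(distance, convention)``
    with convention ``"O...H"`` or ``"O...N"``.
    """
    if offset not in (3, 4):
        raise ValueError("offset must be 3 (3_10-type) or 4 (alpha-type)")
    o = model.get(chain, donor_res, "O").coord
    acceptor_res = donor_res + offset
    if use_hydrogen not in ("auto", "never", "always"):
        raise ValueError("use_hydrogen must be auto|never|always")
    if use_hydrogen != "never" and model.has(chain, acceptor_res, "H"):
        nh = model.get(chain, acceptor_res, "H").coord
        conv = "O...H"
    elif use_hydrogen == "always":
        raise KeyError(
            f"amide hydrogen of residue {acceptor_res} chain {chain} not present"
        )
    else:
        nh = model.get(chain, acceptor_res, "N").coord
        conv = "O...N"
    return float(np.linalg.norm(o - nh)), conv
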