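"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nmrens.io_formats import Atom, Ensemble, StructureModel
from nmrens.synthetic import (
    ALPHA_DIHEDRALS,
    EXTENDED_DIHEDRALS,
    THREE_TEN_DIHEDRALS,
    build_peptide,
)


# ---------------------------------------------------------------------------
# Independent oracles (never call the implementation they check)
# ---------------------------------------------------------------------------

def horn_quaternion_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition via Horn's closed-form quaternion method.

    Independent of the SVD route in nmrens.geometry: builds the 4x4 key
    matrix from the correlation tensor and takes the eigenvector of its
    largest eigenvalue as the rotation quaternion.
    Returns (rotation_matrix, rmsd).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    p0 = P - P.mean(axis=0)
    q0 = Q - Q.mean(axis=0)
    S = p0.T @ q0  # correlation tensor
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(N)
    q = v[:, np.argmax(w)]
    a, b, c, d = q
    R = np.array([
        [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
        [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
        [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
    ])
    diff = p0 @ R.T - q0
    rmsd = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    return R, rmsd


def brute_force_daura(matrix: np.ndarray, cutoff: float):
    """Literal greedy clustering: recompute every neighbour count each round."""
    n = matrix.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        counts = {}
        for i in sorted(remaining):
            counts[i] = sum(1 for j in remaining if matrix[i, j] <= cutoff)
        best = max(counts.values())
        center = min(i for i, c in counts.items() if c == best)
        members = frozenset(j for j in remaining if matrix[center, j] <= cutoff)
        clusters.append((center, members))
        remaining -= members
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return clusters


def brute_force_components(pairs, edges):
    """Connected components by naive label propagation (for patch checks)."""
    labels = {p: i for i, p in enumerate(pairs)}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            lo = min(labels[a], labels[b])
            if labels[a] != lo or labels[b] != lo:
                labels[a] = labels[b] = lo
                changed = True
    groups: dict[int, set] = {}
    for p, l in labels.items():
        groups.setdefault(l, set()).add(p)
    return list(groups.values())


# ---------------------------------------------------------------------------
# Toy-structure builders
# ---------------------------------------------------------------------------

def model_from_coords(coords: dict, model_id: int = 1) -> StructureModel:
    """Build a model from {(chain, res, atom): (x, y, z)}."""
    atoms = [
        Atom(c, r, "ALA", a, tuple(float(v) for v in xyz))
        for (c, r, a), xyz in coords.items()
    ]
    return StructureModel(model_id, atoms)


def ca_ensemble(frames: np.ndarray) -> Ensemble:
    """Ensemble of CA-only models from an (n_models, n_res, 3) stack."""
    models = []
    for mi in range(frames.shape[0]):
        coords = {("A", r + 1, "CA"): frames[mi, r] for r in range(frames.shape[1])}
        models.append(model_from_coords(coords, model_id=mi + 1))
    return Ensemble(models)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def ideal_alpha():
    return build_peptide([ALPHA_DIHEDRALS] * 12)


@pytest.fixture(scope="session")
def ideal_three_ten():
    return build_peptide([THREE_TEN_DIHEDRALS] * 12)


@pytest.fixture(scope="session")
def ideal_extended():
    return build_peptide([EXTENDED_DIHEDRALS] * 12)
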