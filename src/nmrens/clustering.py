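"""RMSD-cutoff conformational clustering (the GROMOS/Daura scheme).

The algorithm is greedy: compute the matrix of pairwise superposed RMSDs
over a selection (backbone by convention), then repeatedly take the
conformer with the most neighbours within the cutoff as a cluster centre,
assign it and its neighbours to that cluster, remove them, and iterate.
The centre of the most populated cluster is the representative structure.

Ties — equal neighbour counts, equal cluster sizes — are broken by the
lowest model index so that results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose
from .io_formats import Ensemble, Selection, select_keys

__all__ = [
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "daura_cluster",
    "representative",
]


@dataclass
class ClusterResult:
    """Clusters as (centre index, member index set), largest first."""

    clusters: list[tuple[int, frozenset[int]]]
    cutoff: float  # Å
    selection: Selection

    @property
    def sizes(self) -> list[int]:
        return [len(members) for _, members in self.clusters]


def pairwise_rmsd_matrix(ensemble: Ensemble, sel: Selection) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs over ``sel`` (diagonal 0).

    The superposition uses the clustering selection itself, so a "backbone,
    0.15 nm" clustering both fits and scores on the backbone.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 models")
    keys = select_keys(ensemble.topology_key, sel)
    X = ensemble.coords(keys)
    n = X.shape[0]
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(X[i], X[j]).rmsd
            M[i, j] = M[j, i] = r
    return M


def daura_cluster(
    ensemble: Ensemble,
    sel: Selection,
    cutoff: float,
    matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Greedy neighbour-count clustering under an RMSD ``cutoff`` (Å)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if len(ensemble) == 1:
        return ClusterResult([(0, frozenset({0}))], cutoff, sel)
    M = pairwise_rmsd_matrix(ensemble, sel) if matrix is None else np.asarray(matrix)
    n = M.shape[0]
    remaining = list(range(n))
    clusters: list[tuple[int, frozenset[int]]] = []
    while remaining:
        # most neighbours within cutoff; ties -> lowest index (list is sorted)
        best_i, best_members = None, None
        for i in remaining:
            members = [j for j in remaining if M[i, j] <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best_i, best_members = i, members
        clusters.append((best_i, frozenset(best_members)))
        remaining = [j for j in remaining if j not in set(best_members)]
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return ClusterResult(clusters=clusters, cutoff=cutoff, selection=sel)


def representative(result: ClusterResult) -> int:
    """Centre of the most populated cluster (ties: lowest centre index)."""
    if not result.clusters:
        raise ValueError("empty cluster result")
    return result.clusters[0][0]
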