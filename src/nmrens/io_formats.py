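"""Coordinate and table I/O plus the atom-selection semantics shared by all analyses.

Coordinates are Å throughout and residue numbering is the deposited PDB
numbering (1-based, never re-indexed), because the literature on NGF and
other neurotrophins refers to residues by those numbers.

Multi-model PDB files (NMR ensembles, MD frame stacks exported as
MODEL/ENDMDL blocks) are parsed with :mod:`gemmi`; the in-memory containers
here are deliberately small and explicit so that the geometry, helicity,
clustering and epitope modules can share one vocabulary.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "StructureModel",
    "Ensemble",
    "Selection",
    "PeakRecord",
    "RelaxationRecord",
    "BACKBONE_ATOMS",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_peak_table",
    "write_peak_table",
    "read_relaxation_table",
    "write_relaxation_table",
    "resolve_selection",
]

#: Backbone heavy atoms in PDB naming; the default selection for RMSD work.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

AtomKey = tuple[str, int, str]  # (chain_id, res_seq, atom_name)


@dataclass(frozen=True)
class Atom:
    """One atom of one model: chain, residue number/name, atom name, xyz in Å."""

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not all(math.isfinite(v) for v in self.xyz):
            raise ValueError(f"non-finite coordinates for {self.key}")

    @property
    def key(self) -> AtomKey:
        return (self.chain_id, self.res_seq, self.atom_name)

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


class StructureModel:
    """A single conformer: an ordered list of atoms with unique (chain, res, name) keys."""

    def __init__(self, model_id: int, atoms: Sequence[Atom]):
        if model_id < 1:
            raise ValueError("model_id must be >= 1")
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a model must contain at least one atom")
        index: dict[AtomKey, int] = {}
        for i, a in enumerate(atoms):
            if a.key in index:
                raise ValueError(f"duplicate atom {a.key} in model {model_id}")
            index[a.key] = i
        self.model_id = model_id
        self.atoms = atoms
        self._index = index

    def __len__(self) -> int:
        return len(self.atoms)

    def __contains__(self, key: AtomKey) -> bool:
        return key in self._index

    def get(self, chain_id: str, res_seq: int, atom_name: str) -> Atom:
        try:
            return self.atoms[self._index[(chain_id, res_seq, atom_name)]]
        except KeyError:
            raise KeyError(
                f"atom {atom_name} of residue {res_seq} chain {chain_id} "
                f"not present in model {self.model_id}"
            ) from None

    def has(self, chain_id: str, res_seq: int, atom_name: str) -> bool:
        return (chain_id, res_seq, atom_name) in self._index

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self, chain_id: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.res_seq, None)
        return list(seen)

    def res_name(self, chain_id: str, res_seq: int) -> str:
        for a in self.atoms:
            if a.chain_id == chain_id and a.res_seq == res_seq:
                return a.res_name
        raise KeyError(f"residue {res_seq} not in chain {chain_id}")

    def coords(self, keys: Iterable[AtomKey]) -> np.ndarray:
        """(n, 3) array of coordinates for the given atom keys, in order."""
        return np.array(
            [self.atoms[self._index[k]].xyz for k in keys], dtype=float
        )


class Ensemble:
    """An ordered stack of models sharing one topology.

    ``topology_key`` is the ordered list of atom keys present in *every*
    model (first model's order); atoms outside it are kept on their models
    but excluded from all ensemble-level math.
    """

    def __init__(self, models: Sequence[StructureModel]):
        models = list(models)
        if not models:
            raise ValueError("an ensemble needs at least one model")
        common = set(models[0]._index)
        for m in models[1:]:
            common &= set(m._index)
        if not common:
            raise ValueError("models share no atoms: empty topology intersection")
        self.models = models
        self.topology_key: list[AtomKey] = [
            a.key for a in models[0].atoms if a.key in common
        ]

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i: int) -> StructureModel:
        return self.models[i]

    def coords(self, keys: Optional[Sequence[AtomKey]] = None) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate stack over the topology (or a subset)."""
        keys = self.topology_key if keys is None else list(keys)
        return np.stack([m.coords(keys) for m in self.models])


@dataclass(frozen=True)
class Selection:
    """Atom selection: optional chain filter, inclusive residue ranges, atom-name set.

    ``residue_ranges`` uses deposited numbering, e.g. the rigid-core ranges
    (15, 22), (51, 58), (78, 89), (100, 111) of the NGF protomer.
    """

    chains: Optional[frozenset[str]] = None
    residue_ranges: Optional[tuple[tuple[int, int], ...]] = None
    atom_names: Optional[frozenset[str]] = None

    @classmethod
    def make(
        cls,
        chains: Optional[Iterable[str]] = None,
        residue_ranges: Optional[Iterable[tuple[int, int]]] = None,
        atom_names: Optional[Iterable[str]] = None,
    ) -> "Selection":
        return cls(
            chains=frozenset(chains) if chains is not None else None,
            residue_ranges=tuple(tuple(r) for r in residue_ranges)
            if residue_ranges is not None
            else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
        )

    @classmethod
    def backbone(cls, chains=None, residue_ranges=None) -> "Selection":
        return cls.make(chains, residue_ranges, BACKBONE_ATOMS)

    @classmethod
    def calpha(cls, chains=None, residue_ranges=None) -> "Selection":
        return cls.make(chains, residue_ranges, ("CA",))

    def matches(self, key: AtomKey) -> bool:
        chain_id, res_seq, atom_name = key
        if self.chains is not None and chain_id not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
            lo <= res_seq <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.atom_names is not None and atom_name not in self.atom_names:
            return False
        return True


def resolve_selection(model: StructureModel, sel: Selection) -> list[Atom]:
    """Atoms of ``model`` matching ``sel``, in topology (file) order.

    Deterministic and idempotent; raises ``ValueError`` when nothing matches,
    since every downstream quantity (RMSD, RMSF, clustering) is undefined on
    an empty selection.
    """
    out = [a for a in model.atoms if sel.matches(a.key)]
    if not out:
        raise ValueError("selection matched no atoms")
    return out


def select_keys(keys: Iterable[AtomKey], sel: Selection) -> list[AtomKey]:
    """Filter an ordered key list (e.g. an ensemble topology) by a selection."""
    out = [k for k in keys if sel.matches(k)]
    if not out:
        raise ValueError("selection matched no atoms of the topology")
    return out


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _is_standard_residue(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def read_multimodel_pdb(path) -> Ensemble:
    """Read a multi-model PDB file (MODEL/ENDMDL blocks, or one implicit model).

    ATOM records and HETATM records carrying standard amino-acid residues
    (e.g. MSE) are kept; waters and ligands are dropped.  Alternate locations
    are resolved to the highest-occupancy conformer, first on ties.  The
    ensemble topology is the intersection of atom keys across models.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    models: list[StructureModel] = []
    for mi, gmodel in enumerate(st, start=1):
        atoms: list[Atom] = []
        for chain in gmodel:
            for res in chain:
                if not _is_standard_residue(res.name):
                    continue
                best: dict[str, gemmi.Atom] = {}
                for at in res:
                    prev = best.get(at.name)
                    # highest occupancy wins; the first-seen conformer on ties
                    if prev is None or at.occ > prev.occ + 1e-9:
                        best[at.name] = at
                for at in best.values():
                    atoms.append(
                        Atom(
                            chain_id=chain.name,
                            res_seq=res.seqid.num,
                            res_name=res.name,
                            atom_name=at.name,
                            xyz=(at.pos.x, at.pos.y, at.pos.z),
                        )
                    )
        if atoms:
            models.append(StructureModel(mi, atoms))
    if not models:
        raise ValueError(f"no models with protein atoms in {path}")
    return Ensemble(models)


def _pdb_atom_name(name: str) -> str:
    # wwPDB v3.3 alignment: names shorter than 4 chars start in column 14
    return name if len(name) == 4 else f" {name:<3s}"


def write_multimodel_pdb(path, ensemble: Ensemble) -> None:
    """Write an ensemble as a plain multi-model PDB (ATOM records, 3-decimal xyz)."""
    with open(path, "w") as fh:
        for m in ensemble.models:
            fh.write(f"MODEL {m.model_id:8d}\n")
            for serial, a in enumerate(m.atoms, start=1):
                x, y, z = a.xyz
                element = a.atom_name[0] if a.atom_name[0].isalpha() else a.atom_name[1]
                fh.write(
                    f"ATOM  {serial:5d} {_pdb_atom_name(a.atom_name)} "
                    f"{a.res_name:<3s} {a.chain_id}{a.res_seq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Peak and relaxation tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRecord:
    """One assigned HSQC cross-peak: amide 1H/15N shifts (ppm) and intensity.

    ``intensity`` (and the shifts) may be ``None`` when the peak was not
    observed at this titration point.
    """

    chain_id: str
    res_seq: int
    res_name: str
    shift_H: Optional[float] = None
    shift_N: Optional[float] = None
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        for v, label in ((self.shift_H, "shift_H"), (self.shift_N, "shift_N")):
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{label} must be finite for residue {self.res_seq}")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError(f"negative intensity for residue {self.res_seq}")

    @property
    def observed(self) -> bool:
        return self.shift_H is not None and self.shift_N is not None


@dataclass(frozen=True)
class RelaxationRecord:
    """Per-residue 15N relaxation: T1 (s), T2 (s), hetNOE; any field may be absent."""

    res_seq: int
    T1: Optional[float] = None
    T2: Optional[float] = None
    hetNOE: Optional[float] = None

    def __post_init__(self) -> None:
        for v, label in ((self.T1, "T1"), (self.T2, "T2")):
            if v is not None and v <= 0:
                raise ValueError(f"{label} must be > 0 (residue {self.res_seq})")

    @property
    def t1_t2_inverted(self) -> bool:
        """True when T2 > T1 — physically suspect, flagged but never rejected."""
        return self.T1 is not None and self.T2 is not None and self.T2 > self.T1


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_peak_table(path) -> list[PeakRecord]:
    """Read a delimited peak table: chain, res_seq, res_name, shift_H, shift_N, intensity.

    Tab- or comma-separated with a header row; empty cells mean "not observed".
    Duplicate (chain, res_seq) rows are an error (one amide, one cross-peak).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chain", "res_seq", "res_name", "shift_h", "shift_n", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    records: list[PeakRecord] = []
    seen: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        chain = str(row.chain).strip()
        res_seq = int(row.res_seq)
        if (chain, res_seq) in seen:
            raise ValueError(f"duplicate peak row for chain {chain} residue {res_seq}")
        seen.add((chain, res_seq))
        records.append(
            PeakRecord(
                chain_id=chain,
                res_seq=res_seq,
                res_name=str(row.res_name).strip(),
                shift_H=_opt(row.shift_h),
                shift_N=_opt(row.shift_n),
                intensity=_opt(row.intensity),
            )
        )
    return records


def write_peak_table(path, records: Sequence[PeakRecord]) -> None:
    df = pd.DataFrame(
        {
            "chain": [r.chain_id for r in records],
            "res_seq": [r.res_seq for r in records],
            "res_name": [r.res_name for r in records],
            "shift_H": [r.shift_H for r in records],
            "shift_N": [r.shift_N for r in records],
            "intensity": [r.intensity for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_relaxation_table(path) -> list[RelaxationRecord]:
    """Read a relaxation table: res_seq, T1, T2, hetNOE (blanks allowed).

    Units default to seconds; a ``# units: ms`` header comment switches the
    T1/T2 columns to milliseconds (converted on read).
    """
    path = Path(path)
    unit = "s"
    with open(path) as fh:
        head = fh.read()
    for line in head.splitlines():
        if line.startswith("#") and "units" in line.lower():
            if "ms" in line.lower().split("units", 1)[1]:
                unit = "ms"
            break
    df = pd.read_csv(io.StringIO(head), sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"res_seq", "t1", "t2", "hetnoe"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"relaxation table missing columns: {sorted(missing)}")
    scale = 1e-3 if unit == "ms" else 1.0
    out: list[RelaxationRecord] = []
    for row in df.itertuples(index=False):
        t1 = _opt(row.t1)
        t2 = _opt(row.t2)
        out.append(
            RelaxationRecord(
                res_seq=int(row.res_seq),
                T1=t1 * scale if t1 is not None else None,
                T2=t2 * scale if t2 is not None else None,
                hetNOE=_opt(row.hetnoe),
            )
        )
    return out


def write_relaxation_table(path, records: Sequence[RelaxationRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("# units: s\n")
        fh.write("res_seq\tT1\tT2\thetNOE\n")
        for r in records:
            f = lambda v: "" if v is None else f"{v:.6g}"
            fh.write(f"{r.res_seq}\t{f(r.T1)}\t{f(r.T2)}\t{f(r.hetNOE)}\n")
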