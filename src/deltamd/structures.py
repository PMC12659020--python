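"""Core data model: configurations, trajectories, molecular topology, periodic geometry.

Only orthorhombic (in practice cubic) cells are supported; all of the
condensed-phase systems in scope are cubic boxes of water molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .units import MASSES


class TopologyError(ValueError):
    """Raised when atoms cannot be grouped into intact water molecules."""


@dataclass
class AtomicConfiguration:
    """A single atomistic configuration.

    Positions in Å; energies in eV; forces in eV/Å.  `cell` is a 3×3
    matrix (diagonal for the orthorhombic cells in scope) or None for
    open-boundary clusters.  `info` carries provenance tags (theory
    level, carve radius, source frame ...).
    """

    elements: list[str]
    positions: np.ndarray
    cell: Optional[np.ndarray] = None
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None
    virial: Optional[np.ndarray] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an N×3 array")
        if len(self.elements) != len(self.positions):
            raise ValueError("elements and positions lengths differ")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if self.cell.shape != (3, 3):
                raise ValueError("cell must be 3×3")
            if abs(np.linalg.det(self.cell)) < 1e-12:
                raise ValueError("periodic cell must be nonsingular")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.positions.shape:
                raise ValueError("forces must match positions in shape")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def periodic(self) -> bool:
        return self.cell is not None

    @property
    def edge(self) -> float:
        """Edge length of a cubic cell."""
        if self.cell is None:
            raise ValueError("open-boundary configuration has no cell")
        _require_orthorhombic(self.cell)
        d = np.diag(self.cell)
        if not np.allclose(d, d[0]):
            raise ValueError("cell is orthorhombic but not cubic")
        return float(d[0])

    @property
    def masses(self) -> np.ndarray:
        return np.array([MASSES[el] for el in self.elements])

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            elements=list(self.elements),
            positions=self.positions.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
            virial=None if self.virial is None else self.virial.copy(),
            info=dict(self.info),
        )


@dataclass
class MoleculeTopology:
    """Assignment of atoms to intact water molecules.

    The O atom is the molecule's reference site for carving distances.
    """

    molecule_of: np.ndarray          # molecule index per atom
    oxygens: np.ndarray              # atom index of the O of each molecule
    hydrogens: np.ndarray            # (n_mol, 2) atom indices of the H atoms

    @property
    def n_molecules(self) -> int:
        return len(self.oxygens)

    def atoms_of(self, mol: int) -> list[int]:
        return [int(self.oxygens[mol]), int(self.hydrogens[mol, 0]), int(self.hydrogens[mol, 1])]


@dataclass
class Trajectory:
    """Time-ordered frames with the stride (fs) between stored frames."""

    frames: list[AtomicConfiguration]
    timestep_fs: float = 0.0
    ensemble: str = ""

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i], self.timestep_fs, self.ensemble)
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)


def _require_orthorhombic(cell: np.ndarray) -> None:
    off = cell - np.diag(np.diag(cell))
    if np.any(np.abs(off) > 1e-10):
        raise ValueError("only orthorhombic cells are supported")


def minimum_image(d: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Wrap displacement(s) `d` into the primary image of an orthorhombic cell.

    Each component of the result lies in [−L/2, L/2).
    """
    cell = np.asarray(cell, dtype=float)
    _require_orthorhombic(cell)
    lengths = np.diag(cell)
    d = np.asarray(d, dtype=float)
    return d - lengths * np.floor(d / lengths + 0.5)


def identify_molecules(cfg: AtomicConfiguration, oh_cut: float = 1.2) -> MoleculeTopology:
    """Group O and H atoms into water molecules.

    Each H is assigned to its nearest O within `oh_cut` Å (minimum image
    when periodic); every O must end up with exactly two H.
    """
    elements = np.asarray(cfg.elements)
    if not set(elements) <= {"O", "H"}:
        raise TopologyError("only O and H atoms are supported")
    o_idx = np.flatnonzero(elements == "O")
    h_idx = np.flatnonzero(elements == "H")
    if len(h_idx) != 2 * len(o_idx):
        raise TopologyError(f"{len(o_idx)} O and {len(h_idx)} H atoms cannot form intact waters")

    o_pos = cfg.positions[o_idx]
    assigned: list[list[int]] = [[] for _ in o_idx]
    for h in h_idx:
        d = o_pos - cfg.positions[h]
        if cfg.periodic:
            d = minimum_image(d, cfg.cell)
        r = np.linalg.norm(d, axis=1)
        j = int(np.argmin(r))
        if r[j] > oh_cut:
            raise TopologyError(f"H atom {h} has no O within {oh_cut} Å (nearest {r[j]:.3f} Å)")
        assigned[j].append(int(h))

    bad = [int(o_idx[j]) for j, hs in enumerate(assigned) if len(hs) != 2]
    if bad:
        raise TopologyError(f"O atoms with != 2 bonded H within {oh_cut} Å: {bad}")

    n_mol = len(o_idx)
    molecule_of = np.empty(cfg.n_atoms, dtype=np.int64)
    hydrogens = np.empty((n_mol, 2), dtype=np.int64)
    for m, (o, hs) in enumerate(zip(o_idx, assigned)):
        molecule_of[o] = m
        molecule_of[hs[0]] = m
        molecule_of[hs[1]] = m
        hydrogens[m] = hs
    return MoleculeTopology(molecule_of=molecule_of, oxygens=o_idx.astype(np.int64), hydrogens=hydrogens)
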