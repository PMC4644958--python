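"""Core domain containers: atoms, topologies, frames, trajectories, partitions.

Coordinates are stored in Å, charges in units of the elementary charge,
energies throughout the package in kcal/mol, masses in amu, times in ps.
Atom indices are 0-based everywhere internally; PDB serial numbers and
residue sequence numbers are preserved verbatim for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import StructureError, ParameterizationError

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass
class Atom:
    """One atom with its identity and (optionally) its force-field parameters.

    Parameter fields default to ``None`` and stay unset until a topology
    sidecar is merged; energetics operations demand full parameterization.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str = "A"
    charge: float | None = None          # e
    lj_rmin_half: float | None = None    # Å
    lj_epsilon: float | None = None      # kcal/mol
    gb_radius: float | None = None       # intrinsic Born radius, Å
    gb_screen: float | None = None       # dimensionless descreening scale
    mass: float | None = None            # amu

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.lj_rmin_half is not None and self.lj_rmin_half < 0:
            raise ValueError("lj_rmin_half must be >= 0")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be >= 0")
        if self.mass is not None and self.mass <= 0:
            raise ValueError("mass must be > 0")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.strip().upper() == "H"

    @property
    def parameterized(self) -> bool:
        return None not in (
            self.charge,
            self.lj_rmin_half,
            self.lj_epsilon,
            self.gb_radius,
            self.gb_screen,
            self.mass,
        )

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)

    def label(self) -> str:
        return f"{self.residue_name}{self.residue_seq}:{self.name}"


@dataclass
class Topology:
    """Ordered atom list plus the toy bonded force field and dielectrics.

    Bonds are ``(i, j, k_b, r0)`` with the AMBER-style harmonic energy
    ``k_b (r - r0)^2`` (k_b in kcal/mol/Å²); angles are
    ``(i, j, k, k_a, theta0)`` with ``k_a (theta - theta0)^2``
    (k_a in kcal/mol/rad², theta0 in rad).
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    interior_dielectric: float = 1.0
    exterior_dielectric: float = 80.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.atoms)
        if self.interior_dielectric <= 0 or self.exterior_dielectric <= 0:
            raise ValueError("dielectrics must be positive")
        if self.exterior_dielectric <= self.interior_dielectric:
            raise ValueError("exterior dielectric must exceed interior dielectric")
        seen = set()
        for (i, j, kb, r0) in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) references invalid atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        for (i, j, k, *_rest) in self.angles:
            if len({i, j, k}) != 3 or not all(0 <= x < n for x in (i, j, k)):
                raise ValueError(f"angle ({i},{j},{k}) references invalid atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self, subset: Sequence[int] | None = None) -> np.ndarray:
        idx = range(self.n_atoms) if subset is None else subset
        out = []
        for i in idx:
            m = self.atoms[i].mass
            if m is None:
                raise ParameterizationError(f"atom {self.atoms[i].label()} has no mass")
            out.append(m)
        return np.asarray(out, dtype=float)

    def charges(self, subset: Sequence[int] | None = None) -> np.ndarray:
        idx = range(self.n_atoms) if subset is None else subset
        out = []
        for i in idx:
            q = self.atoms[i].charge
            if q is None:
                raise ParameterizationError(f"atom {self.atoms[i].label()} has no charge")
            out.append(q)
        return np.asarray(out, dtype=float)

    def bonded_hydrogens(self, i: int) -> list[int]:
        """Indices of hydrogens bonded to atom ``i`` (via the bond table)."""
        out = []
        for (a, b, *_rest) in self.bonds:
            if a == i and self.atoms[b].is_hydrogen:
                out.append(b)
            elif b == i and self.atoms[a].is_hydrogen:
                out.append(a)
        return out

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Residue key -> atom indices, in first-appearance order."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            out.setdefault(atom.residue_key(), []).append(i)
        return out

    def require_parameterized(self, subset: Iterable[int] | None = None) -> None:
        idx = range(self.n_atoms) if subset is None else subset
        missing = [self.atoms[i].label() for i in idx if not self.atoms[i].parameterized]
        if missing:
            raise ParameterizationError(
                f"atoms missing force-field parameters: {', '.join(missing)}"
            )


@dataclass
class Frame:
    """One coordinate snapshot (N×3 Å) with its time stamp in ps."""

    coordinates: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError(
                f"coordinates must be N×3, got shape {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("coordinates contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def with_coordinates(self, coords: np.ndarray) -> "Frame":
        return Frame(coordinates=np.asarray(coords, dtype=float), time=self.time)


@dataclass
class Trajectory:
    """A topology plus an ordered sequence of frames."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise StructureError(
                    f"frame {k} has {fr.n_atoms} atoms, topology has {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k: int) -> Frame:
        return self.frames[k]


@dataclass(frozen=True)
class ComplexPartition:
    """Disjoint receptor/ligand atom-index sets covering the analysed system."""

    receptor: frozenset[int]
    ligand: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "receptor", frozenset(self.receptor))
        object.__setattr__(self, "ligand", frozenset(self.ligand))
        if not self.receptor or not self.ligand:
            raise StructureError("receptor and ligand sets must both be non-empty")
        if self.receptor & self.ligand:
            raise StructureError("receptor and ligand sets overlap")

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.asarray(sorted(self.receptor), dtype=int)

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.asarray(sorted(self.ligand), dtype=int)

    @property
    def all_indices(self) -> np.ndarray:
        return np.asarray(sorted(self.receptor | self.ligand), dtype=int)


def subset_topology(topology: Topology, indices: Sequence[int]) -> tuple[Topology, dict[int, int]]:
    """Extract a topology over ``indices``; bonded terms crossing out are dropped.

    Returns the new topology and the old->new index map.
    """
    order = sorted(indices)
    remap = {old: new for new, old in enumerate(order)}
    atoms = [replace(topology.atoms[i]) for i in order]
    bonds = [
        (remap[i], remap[j], kb, r0)
        for (i, j, kb, r0) in topology.bonds
        if i in remap and j in remap
    ]
    angles = [
        (remap[i], remap[j], remap[k], ka, th0)
        for (i, j, k, ka, th0) in topology.angles
        if i in remap and j in remap and k in remap
    ]
    sub = Topology(
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        interior_dielectric=topology.interior_dielectric,
        exterior_dielectric=topology.exterior_dielectric,
    )
    return sub, remap
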