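"""Readers and writers for the formats the pipeline touches.

Structures travel as multi-model PDB (ATOM/HETATM/MODEL/ENDMDL subset) or
multi-frame XYZ; per-atom force-field parameters arrive in a JSON sidecar
and are merged onto a parsed structure by ``merge_topology``. Steered-work
measurements are tab-separated text.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Atom, Frame, Topology, Trajectory
from .exceptions import PDBParseError, StructureError, ParameterizationError

logger = logging.getLogger(__name__)

WORK_TSV_COLUMNS = ["segment", "direction", "path", "displacement_A", "work_kcal_mol"]


def _parse_atom_record(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record: {exc}", lineno) from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the first alphabetic character of the atom name
        element = next((c for c in name if c.isalpha()), "X")
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=res_name,
        residue_seq=res_seq,
        chain_id=chain,
    )
    return atom, np.array([x, y, z])


def read_pdb(path: str | Path, model_policy: str = "all") -> Trajectory:
    """Read a (multi-model) PDB file into an unparameterized Trajectory.

    ``model_policy`` is ``"first"`` (stop after MODEL 1) or ``"all"`` (one
    frame per MODEL). Atom ordering is preserved; atoms carry no force-field
    parameters until a topology sidecar is merged. All MODELs must contain
    the same atoms in the same order.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    path = Path(path)
    atoms: list[Atom] = []
    models: list[list[np.ndarray]] = []
    current: list[np.ndarray] | None = None
    first_model_atoms: list[tuple[str, int, str]] | None = None
    in_first = True
    pending_check: list[tuple[str, int, str]] = []
    saw_model_record = False

    def close_model(lineno: int) -> None:
        nonlocal current, in_first, first_model_atoms, pending_check
        if current is None:
            return
        if first_model_atoms is None:
            first_model_atoms = list(pending_check)
        elif pending_check != first_model_atoms:
            raise StructureError(
                f"model {len(models) + 1} has inconsistent atoms "
                f"({len(pending_check)} vs {len(first_model_atoms)} expected)"
            )
        models.append(current)
        current = None
        in_first = False
        pending_check = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model_record = True
                if current is not None:
                    close_model(lineno)
                current = []
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                atom, xyz = _parse_atom_record(line, lineno)
                key = (atom.name, atom.residue_seq, atom.chain_id)
                if first_model_atoms is None and len(models) == 0:
                    atoms.append(atom)
                pending_check.append(key)
                current.append(xyz)
            elif rec == "ENDMDL":
                close_model(lineno)
            elif rec == "END":
                break
    if current is not None:
        close_model(-1)
    if not models or not atoms:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    if model_policy == "first":
        models = models[:1]
    if saw_model_record and any(len(m) != len(atoms) for m in models):
        raise StructureError("models have inconsistent atom counts")
    frames = [
        Frame(coordinates=np.vstack(m), time=float(k)) for k, m in enumerate(models)
    ]
    topo = Topology(atoms=atoms)
    return Trajectory(topology=topo, frames=frames)


def write_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (coordinates at 3 decimals)."""
    path = Path(path)
    multi = trajectory.n_frames > 1
    with open(path, "w") as fh:
        for k, frame in enumerate(trajectory.frames, start=1):
            if multi:
                fh.write(f"MODEL     {k:4d}\n")
            for atom, xyz in zip(trajectory.topology.atoms, frame.coordinates):
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {atom.serial:5d} {name:<4s} {atom.residue_name:<3s} "
                    f"{atom.chain_id:1s}{atom.residue_seq:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_xyz(path: str | Path) -> Trajectory:
    """Read a multi-frame XYZ file (element symbols only; no residue info)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    pos = 0
    frames: list[Frame] = []
    atoms: list[Atom] | None = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise PDBParseError("expected atom count", pos + 1) from exc
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise PDBParseError("truncated XYZ frame", pos + 1)
        coords = np.empty((n, 3))
        elements = []
        for i, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise PDBParseError("malformed XYZ atom line", pos + 3 + i)
            elements.append(parts[0])
            coords[i] = [float(v) for v in parts[1:4]]
        if atoms is None:
            atoms = [
                Atom(serial=i + 1, name=e, element=e, residue_name="UNK", residue_seq=1)
                for i, e in enumerate(elements)
            ]
        elif len(elements) != len(atoms):
            raise StructureError("XYZ frames have inconsistent atom counts")
        frames.append(Frame(coordinates=coords, time=float(len(frames))))
        pos += 2 + n
    if atoms is None:
        raise PDBParseError(f"no frames found in {path}")
    return Trajectory(topology=Topology(atoms=atoms), frames=frames)


def write_xyz(trajectory: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"{frame.n_atoms}\nt= {frame.time} ps\n")
            for atom, xyz in zip(trajectory.topology.atoms, frame.coordinates):
                fh.write(f"{atom.element:<2s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")


# --- topology sidecar -------------------------------------------------------

_SIDECAR_FIELDS = {
    "charge": "charge",
    "rmin_half": "lj_rmin_half",
    "epsilon": "lj_epsilon",
    "gb_radius": "gb_radius",
    "gb_screen": "gb_screen",
    "mass": "mass",
}


def read_topology_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_topology_sidecar(topology: Topology, path: str | Path) -> None:
    """Serialize a fully parameterized topology to the JSON sidecar dialect."""
    data = {
        "atoms": [
            {
                "serial": a.serial,
                "name": a.name,
                "element": a.element,
                "res_name": a.residue_name,
                "res_seq": a.residue_seq,
                "chain": a.chain_id,
                "charge": a.charge,
                "rmin_half": a.lj_rmin_half,
                "epsilon": a.lj_epsilon,
                "gb_radius": a.gb_radius,
                "gb_screen": a.gb_screen,
                "mass": a.mass,
            }
            for a in topology.atoms
        ],
        "bonds": [list(b) for b in topology.bonds],
        "angles": [list(a) for a in topology.angles],
        "dielectrics": {
            "interior": topology.interior_dielectric,
            "exterior": topology.exterior_dielectric,
        },
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def merge_topology(structure: Trajectory, sidecar: dict | str | Path) -> Trajectory:
    """Merge a topology sidecar onto a parsed structure.

    Sidecar atoms are keyed by ``(res_seq, name)`` (chain-qualified keys are
    used when the sidecar provides a chain). Every structure atom must match
    exactly one sidecar entry; extra sidecar entries are ignored with a
    warning. Atom order is never changed.
    """
    if not isinstance(sidecar, dict):
        sidecar = read_topology_sidecar(sidecar)
    entries: dict[tuple, dict] = {}
    for e in sidecar.get("atoms", []):
        key = (int(e["res_seq"]), str(e["name"]).strip())
        entries[key] = e
    unmatched = []
    new_atoms = []
    used = set()
    for atom in structure.topology.atoms:
        key = (atom.residue_seq, atom.name)
        e = entries.get(key)
        if e is None:
            unmatched.append(key)
            continue
        used.add(key)
        kwargs = {attr: e.get(src) for src, attr in _SIDECAR_FIELDS.items()}
        new_atoms.append(
            Atom(
                serial=atom.serial,
                name=atom.name,
                element=e.get("element", atom.element),
                residue_name=atom.residue_name,
                residue_seq=atom.residue_seq,
                chain_id=atom.chain_id,
                **kwargs,
            )
        )
    if unmatched:
        raise ParameterizationError(
            "sidecar is missing atoms (res_seq, name): "
            + ", ".join(repr(k) for k in unmatched)
        )
    extras = set(entries) - used
    if extras:
        logger.warning("sidecar has %d extra atom entries; ignored", len(extras))
    dielec = sidecar.get("dielectrics", {})
    topo = Topology(
        atoms=new_atoms,
        bonds=[tuple(b) for b in sidecar.get("bonds", [])],
        angles=[tuple(a) for a in sidecar.get("angles", [])],
        interior_dielectric=float(dielec.get("interior", 1.0)),
        exterior_dielectric=float(dielec.get("exterior", 80.0)),
    )
    return Trajectory(topology=topo, frames=structure.frames)


# --- steered-work TSV -------------------------------------------------------

def read_work_tsv(path: str | Path) -> pd.DataFrame:
    """Read a steered-work table; columns: segment, direction, path,
    displacement_A, work_kcal_mol."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WORK_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise PDBParseError(f"work TSV missing columns: {missing}")
    return df


def write_work_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=WORK_TSV_COLUMNS)
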