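"""Synthetic inputs with known ground truth.

Three generators stand in for the undeposited simulation data the analyses
were designed for:

* a toy host–guest complex — a three-residue ring "host" whose two
  positively charged side chains and one hydroxyl-like donor surround a
  five-atom "guest" carrying a doubly negative phosphate-like group, with
  hydrogen-bond donors/acceptors in contact so every structural and
  energetic analysis path is exercised;
* jittered bound-pose trajectories (i.i.d. Gaussian coordinate noise
  around the constructed pose, frames 1 ps apart);
* Crooks-consistent bidirectional work samples: per segment, forward works
  ~ N(ΔG_s + σ_W²/2k_BT, σ_W²) and reverse works ~ N(−ΔG_s + σ_W²/2k_BT,
  σ_W²), the regime in which the BD-FDT half-exponential estimator is
  exact in expectation — making planted free energies recoverable.

The printed nine-compound reference energy table ships as a fixture via
:func:`table1_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Atom, ComplexPartition, Frame, Topology, Trajectory
from .mmgbsa import AggregateResult, CompoundTable
from .pmf import WorkSample
from .entropy import KB_KCAL

# per-segment free energies (kcal/mol) of the default planted PMF: an early
# steep rise out of the binding well then a flat dissociated plateau,
# 16 x 1 Å segments summing to -13.0
DEFAULT_SEGMENT_DG = (
    -2.6, -2.4, -2.2, -1.8, -1.5, -1.2, -0.8, -0.5,
    0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
)


@dataclass
class GeneratorSpec:
    """Reproducible description of a synthetic system/sampling condition."""

    seed: int = 0
    kind: str = "host_guest"        # born_ion | two_charge | host_guest
    jitter_sigma: float = 0.01      # Å per coordinate (linear-response regime)
    n_frames: int = 500
    segment_dg: tuple[float, ...] = DEFAULT_SEGMENT_DG   # kcal/mol per segment
    work_sigma: float = 1.0         # kcal/mol
    n_paths: int = 4                # per direction per segment
    temperature: float = 300.0      # K
    segment_length: float = 1.0     # Å
    points_per_segment: int = 11    # work grid points per segment
    neutralize: bool = True

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


# LJ/GB/mass parameter block per element class (rmin/2 Å, ε kcal/mol,
# GB radius Å, GB screen, mass amu) — conventional force-field magnitudes
_PARAMS = {
    "C": (1.908, 0.1094, 1.70, 0.72, 12.011),
    "N": (1.824, 0.1700, 1.55, 0.79, 14.007),
    "O": (1.661, 0.2100, 1.50, 0.85, 15.999),
    "H": (0.600, 0.0157, 1.20, 0.85, 1.008),
    "P": (2.100, 0.2000, 1.85, 0.86, 30.974),
}


def _atom(serial, name, element, res_name, res_seq, chain, charge):
    rmin, eps, gb_r, gb_s, mass = _PARAMS[element]
    return Atom(
        serial=serial, name=name, element=element, residue_name=res_name,
        residue_seq=res_seq, chain_id=chain, charge=charge,
        lj_rmin_half=rmin, lj_epsilon=eps, gb_radius=gb_r, gb_screen=gb_s,
        mass=mass,
    )


def make_host_guest(spec: GeneratorSpec | None = None) -> tuple[Topology, Frame, ComplexPartition]:
    """Build the bound-pose toy complex.

    Host (chain A): residues 1–2 are arginine-like (+1 on the N–H side
    chain), residue 3 serine-like (polar O–H donor); the three CA atoms are
    bonded into a soft triangular scaffold so the free host has a bound
    minimum for normal-mode analysis. Guest (chain L, residue 101): a
    phosphate-like PO3 group (net −2) plus a carbon linker, each oxygen
    facing one host donor at hydrogen-bonding distance. Bond/angle
    equilibria are set to the constructed geometry, so the pose is at the
    bonded-term minimum by construction.
    """
    spec = spec or GeneratorSpec()
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1

    def add(name, element, res_name, res_seq, chain, charge, xyz):
        nonlocal serial
        atoms.append(_atom(serial, name, element, res_name, res_seq, chain, charge))
        coords.append(np.asarray(xyz, dtype=float))
        serial += 1
        return len(atoms) - 1

    # guest: P at origin, three O at 120° apart (radius 1.5, z=-0.2), C above
    guest_idx = []
    i_p = add("P", "P", "GST", 101, "L", 1.0, (0.0, 0.0, 0.0))
    guest_idx.append(i_p)
    o_idx = []
    for k in range(3):
        th = np.deg2rad(120.0 * k)
        i_o = add(f"O{k+1}", "O", "GST", 101, "L", -1.0,
                  (1.5 * np.cos(th), 1.5 * np.sin(th), -0.2))
        o_idx.append(i_o)
        guest_idx.append(i_o)
    i_c = add("C1", "C", "GST", 101, "L", 0.0, (0.0, 0.0, 1.6))
    guest_idx.append(i_c)

    # host: one residue per guest oxygen, donor pointing inward
    host_idx = []
    donor_specs = [
        ("ARG", 1, "NZ", "HZ", "N", 0.7, 0.3),
        ("ARG", 2, "NZ", "HZ", "N", 0.7, 0.3),
        ("SER", 3, "OG", "HG", "O", -0.5, 0.5),
    ]
    ca_idx = []
    bonds: list[tuple[int, int, float, float]] = []
    angles: list[tuple[int, int, int, float, float]] = []
    for k, (res_name, res_seq, dname, hname, delem, dq, hq) in enumerate(donor_specs):
        th = np.deg2rad(120.0 * k)
        u = np.array([np.cos(th), np.sin(th), 0.0])
        d_pos = (1.5 + 2.9) * u + np.array([0.0, 0.0, -0.2])   # donor heavy atom
        h_pos = (1.5 + 2.9 - 1.0) * u + np.array([0.0, 0.0, -0.2])  # H toward O
        ca_pos = (1.5 + 2.9 + 0.5) * u + np.array([0.0, 0.0, 1.2])
        i_ca = add("CA", "C", res_name, res_seq, "A", 0.0, ca_pos)
        i_d = add(dname, delem, res_name, res_seq, "A", dq, d_pos)
        i_h = add(hname, "H", res_name, res_seq, "A", hq, h_pos)
        host_idx += [i_ca, i_d, i_h]
        ca_idx.append(i_ca)
        bonds.append((i_ca, i_d, 300.0, 0.0))
        bonds.append((i_d, i_h, 450.0, 0.0))
        angles.append((i_ca, i_d, i_h, 50.0, 0.0))

    # guest bonded terms
    for i_o in o_idx:
        bonds.append((i_p, i_o, 400.0, 0.0))
    bonds.append((i_p, i_c, 250.0, 0.0))
    for a in range(3):
        for b in range(a + 1, 3):
            angles.append((o_idx[a], i_p, o_idx[b], 70.0, 0.0))
        angles.append((o_idx[a], i_p, i_c, 60.0, 0.0))
    # soft triangular scaffold holding the host together
    for a in range(3):
        b = (a + 1) % 3
        bonds.append((ca_idx[a], ca_idx[b], 10.0, 0.0))

    xyz = np.vstack(coords)
    # set equilibria to the constructed geometry
    bonds = [
        (i, j, kb, float(np.linalg.norm(xyz[i] - xyz[j])))
        for (i, j, kb, _r0) in bonds
    ]

    def _angle(i, j, k):
        u = xyz[i] - xyz[j]
        v = xyz[k] - xyz[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    angles = [
        (i, j, k, ka, _angle(i, j, k)) for (i, j, k, ka, _t0) in angles
    ]

    if spec.neutralize:
        total = sum(a.charge for a in atoms)
        atoms[i_c].charge -= total  # dump any residual on the linker carbon

    topo = Topology(atoms=atoms, bonds=bonds, angles=angles)
    frame = Frame(coordinates=xyz, time=0.0)
    partition = ComplexPartition(receptor=frozenset(host_idx),
                                 ligand=frozenset(guest_idx))
    return topo, frame, partition


def jitter_trajectory(base: Frame, topology: Topology,
                      spec: GeneratorSpec) -> Trajectory:
    """n_frames copies of ``base`` with i.i.d. Gaussian coordinate noise
    (σ = spec.jitter_sigma Å), time stamps 1 ps apart, seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for k in range(spec.n_frames):
        noise = rng.normal(0.0, spec.jitter_sigma, size=base.coordinates.shape)
        frames.append(Frame(coordinates=base.coordinates + noise, time=float(k + 1)))
    return Trajectory(topology=topology, frames=frames)


def crooks_work_sampler(spec: GeneratorSpec | None = None) -> list[WorkSample]:
    """Bidirectional work samples consistent with the Crooks relation.

    Per segment s the endpoint works are drawn as
    W_F ~ N(ΔG_s + σ_W²/2k_BT, σ_W²) and W_R ~ N(−ΔG_s + σ_W²/2k_BT, σ_W²)
    (equal dissipation both ways); cumulative work ramps linearly in
    displacement within the segment. Reverse samples are recorded from
    their own entry (the segment's far end), matching the WorkSample
    convention.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    kbt = KB_KCAL * spec.temperature
    dissipation = spec.work_sigma**2 / (2.0 * kbt)
    grid = np.linspace(0.0, spec.segment_length, spec.points_per_segment)
    ramp = grid / spec.segment_length
    out: list[WorkSample] = []
    for s, dg in enumerate(spec.segment_dg):
        for direction, mean_end in (
            ("forward", dg + dissipation),
            ("reverse", -dg + dissipation),
        ):
            ends = rng.normal(mean_end, spec.work_sigma, size=spec.n_paths)
            for p, w_end in enumerate(ends):
                out.append(
                    WorkSample(
                        segment_id=s,
                        direction=direction,
                        path_id=p,
                        displacement=grid.copy(),
                        work=w_end * ramp,
                    )
                )
    return out


# --- printed reference table ------------------------------------------------

# nine-compound reference values: per component (mean, sem) in kcal/mol,
# 500 enthalpy / 125 entropy snapshots; experimental ΔG where measured
_TABLE1 = {
    "R1": {"e_ele": (214.42, 1.31), "e_vdw": (-13.98, 0.23),
           "g_pol": (-247.44, 1.12), "g_nonpol": (-2.53, 0.01),
           "neg_t_ds": (18.99, 0.45), "exp": -7.28},
    "R2": {"e_ele": (152.11, 2.12), "e_vdw": (-6.73, 0.27),
           "g_pol": (-188.06, 1.80), "g_nonpol": (-2.23, 0.01),
           "neg_t_ds": (19.85, 0.34), "exp": -6.62},
    "R3": {"e_ele": (242.33, 1.36), "e_vdw": (-15.21, 0.23),
           "g_pol": (-268.85, 1.15), "g_nonpol": (-2.53, 0.01),
           "neg_t_ds": (20.99, 0.37), "exp": -6.58},
    "R4": {"e_ele": (246.06, 1.33), "e_vdw": (-13.68, 0.24),
           "g_pol": (-272.16, 1.15), "g_nonpol": (-2.51, 0.01),
           "neg_t_ds": (19.90, 0.48), "exp": -6.27},
    "R5": {"e_ele": (230.44, 1.16), "e_vdw": (-12.73, 0.22),
           "g_pol": (-256.08, 1.03), "g_nonpol": (-2.63, 0.01),
           "neg_t_ds": (20.04, 0.44), "exp": -6.21},
    "R6": {"e_ele": (267.29, 1.29), "e_vdw": (-14.30, 0.23),
           "g_pol": (-287.10, 1.19), "g_nonpol": (-2.48, 0.01),
           "neg_t_ds": (20.33, 0.45), "exp": -6.17},
    "R7": {"e_ele": (276.22, 1.20), "e_vdw": (-14.45, 0.23),
           "g_pol": (-295.70, 1.10), "g_nonpol": (-2.76, 0.01),
           "neg_t_ds": (21.04, 0.38), "exp": -6.10},
    "R8": {"e_ele": (316.32, 1.20), "e_vdw": (-13.73, 0.22),
           "g_pol": (-334.00, 1.09), "g_nonpol": (-2.69, 0.01),
           "neg_t_ds": (21.37, 0.32), "exp": -5.19},
    "R9": {"e_ele": (222.79, 1.35), "e_vdw": (-11.82, 0.23),
           "g_pol": (-254.20, 1.19), "g_nonpol": (-2.59, 0.01),
           "neg_t_ds": (19.81, 0.46), "exp": None},
}

# published composite sems (not derivable from the component sems alone)
_TABLE1_COMPOSITE_SEM = {
    "R1": {"g_ele_pol": 1.21, "g_vdw_nonpol": 0.12, "h": 0.32, "g_bind": 0.55},
    "R2": {"g_ele_pol": 1.96, "g_vdw_nonpol": 0.14, "h": 0.42, "g_bind": 0.58},
    "R3": {"g_ele_pol": 1.26, "g_vdw_nonpol": 0.12, "h": 0.32, "g_bind": 0.44},
    "R4": {"g_ele_pol": 1.24, "g_vdw_nonpol": 0.12, "h": 0.31, "g_bind": 0.55},
    "R5": {"g_ele_pol": 1.09, "g_vdw_nonpol": 0.11, "h": 0.29, "g_bind": 0.48},
    "R6": {"g_ele_pol": 1.24, "g_vdw_nonpol": 0.12, "h": 0.24, "g_bind": 0.48},
    "R7": {"g_ele_pol": 1.15, "g_vdw_nonpol": 0.12, "h": 0.23, "g_bind": 0.37},
    "R8": {"g_ele_pol": 1.15, "g_vdw_nonpol": 0.11, "h": 0.23, "g_bind": 0.36},
    "R9": {"g_ele_pol": 1.27, "g_vdw_nonpol": 0.12, "h": 0.34, "g_bind": 0.57},
}

EIGHT_COMPOUNDS = ("R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8")


def table1_fixture() -> CompoundTable:
    """The packaged nine-compound reference table (means, sems, ΔG_exp).

    Composite rows are rebuilt from the component means, so every composite
    identity holds exactly; composite sems are the published values.
    """
    table = CompoundTable()
    for label, vals in _TABLE1.items():
        mean = {k: vals[k][0] for k in ("e_ele", "e_vdw", "g_pol", "g_nonpol")}
        sem = {k: vals[k][1] for k in ("e_ele", "e_vdw", "g_pol", "g_nonpol")}
        mean["g_ele_pol"] = mean["e_ele"] + mean["g_pol"]
        mean["g_vdw_nonpol"] = mean["e_vdw"] + mean["g_nonpol"]
        mean["h"] = sum(mean[k] for k in ("e_ele", "e_vdw", "g_pol", "g_nonpol"))
        mean["neg_t_ds"] = vals["neg_t_ds"][0]
        sem["neg_t_ds"] = vals["neg_t_ds"][1]
        mean["g_bind"] = mean["h"] + mean["neg_t_ds"]
        sem.update(_TABLE1_COMPOSITE_SEM[label])
        table.add(
            label,
            AggregateResult(
                mean={k: round(v, 10) for k, v in mean.items()},
                sem=sem,
                n_snapshots=500,
                n_entropy=125,
                exp=vals["exp"],
            ),
        )
    return table
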