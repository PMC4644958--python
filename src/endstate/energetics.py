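"""Pairwise gas-phase energies, generalized-Born and SASA solvation terms,
and per-residue decomposition.

The binding enthalpy of a snapshot is assembled single-trajectory style:
the gas-phase terms are the receptor x ligand cross sums (intramolecular
terms cancel in the complex-minus-parts difference when all three species
share the same coordinates), while the solvation terms are true
complex − receptor − ligand differences evaluated on the same frame.

Conventions: Coulomb constant K = 332.0637 kcal·Å/(mol·e²); no cutoff and
no periodicity (end-state post-processing uses full pairwise sums); the
polar term is the Still generalized-Born energy over Hawkins–Cramer–Truhlar
(HCT) pairwise-descreening effective radii (0.09 Å offset); the nonpolar
term is γ·SASA + β with a Shrake–Rupley surface (probe 1.4 Å) using the
Lennard-Jones rmin/2 as the atomic radius proxy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ComplexPartition, Frame, Topology
from .exceptions import ParameterizationError, SingularityError

logger = logging.getLogger(__name__)

COULOMB_K = 332.0637        # kcal·Å/(mol·e²)
GB_OFFSET = 0.09            # Å subtracted from intrinsic Born radii (HCT)
DEFAULT_PROBE = 1.4         # Å
DEFAULT_GAMMA = 0.005       # kcal/mol/Å²
DEFAULT_BETA = 0.0          # kcal/mol
SASA_POINTS = 960
_R_EFF_CEILING = 30.0       # Å; floor clamp for non-positive inverse radii
_MIN_SEPARATION = 1e-6      # Å


@dataclass
class EnergyBreakdown:
    """The per-snapshot (or aggregate) component set of the binding enthalpy.

    All values kcal/mol. Derived sums are recomputed on construction so the
    composite identities hold exactly.
    """

    e_ele: float
    e_vdw: float
    g_pol: float
    g_nonpol: float
    g_ele_pol: float = field(init=False)
    g_vdw_nonpol: float = field(init=False)
    h: float = field(init=False)

    def __post_init__(self) -> None:
        self.g_ele_pol = self.e_ele + self.g_pol
        self.g_vdw_nonpol = self.e_vdw + self.g_nonpol
        self.h = self.e_ele + self.e_vdw + self.g_pol + self.g_nonpol

    def as_dict(self) -> dict[str, float]:
        return {
            "e_ele": self.e_ele,
            "e_vdw": self.e_vdw,
            "g_pol": self.g_pol,
            "g_nonpol": self.g_nonpol,
            "g_ele_pol": self.g_ele_pol,
            "g_vdw_nonpol": self.g_vdw_nonpol,
            "h": self.h,
        }


@dataclass
class ResidueContribution:
    """One residue's share of the binding enthalpy (pair terms split half/half)."""

    label: str
    e_ele: float
    e_vdw: float
    g_pol: float
    g_nonpol: float

    @property
    def total(self) -> float:
        return self.e_ele + self.e_vdw + self.g_pol + self.g_nonpol


# --- pair terms -------------------------------------------------------------

def coulomb_pair(qi: float, qj: float, r: float, dielectric: float = 1.0) -> float:
    """Coulomb energy K·qi·qj/(ε·r) in kcal/mol (r in Å, charges in e)."""
    if r <= 0:
        raise SingularityError(f"coulomb_pair called with r={r}")
    return COULOMB_K * qi * qj / (dielectric * r)


def lj_pair_params(eps_i: float, eps_j: float, rmin_half_i: float,
                   rmin_half_j: float, r: float) -> float:
    if r <= 0:
        raise SingularityError(f"lj_pair called with r={r}")
    eps = np.sqrt(eps_i * eps_j)
    if eps == 0.0:
        return 0.0
    rmin = rmin_half_i + rmin_half_j
    s6 = (rmin / r) ** 6
    return eps * (s6 * s6 - 2.0 * s6)


def lj_pair(atom_i, atom_j, r: float) -> float:
    """12-6 Lennard-Jones energy with Rmin_ij = rmin_half_i + rmin_half_j and
    ε_ij = sqrt(ε_i ε_j); the minimum is exactly −ε_ij at r = Rmin_ij."""
    return lj_pair_params(atom_i.lj_epsilon, atom_j.lj_epsilon,
                          atom_i.lj_rmin_half, atom_j.lj_rmin_half, r)


def intermolecular_energy(
    frame: Frame, topology: Topology, partition: ComplexPartition
) -> tuple[float, float]:
    """Receptor × ligand gas-phase (ΔE_ele, ΔE_vdw), full pairwise, no cutoff."""
    topology.require_parameterized(partition.all_indices)
    ri = partition.receptor_indices
    li = partition.ligand_indices
    xr = frame.coordinates[ri]
    xl = frame.coordinates[li]
    d = np.linalg.norm(xr[:, None, :] - xl[None, :, :], axis=-1)
    if np.any(d < _MIN_SEPARATION):
        a, b = np.unravel_index(np.argmin(d), d.shape)
        pair = (topology.atoms[ri[a]].label(), topology.atoms[li[b]].label())
        raise SingularityError(f"overlapping atoms {pair[0]} / {pair[1]}")
    qr = topology.charges(ri)
    ql = topology.charges(li)
    e_ele = COULOMB_K / topology.interior_dielectric * np.sum(
        np.outer(qr, ql) / d
    )
    eps = np.sqrt(np.outer(
        [topology.atoms[i].lj_epsilon for i in ri],
        [topology.atoms[j].lj_epsilon for j in li],
    ))
    rmin = (
        np.asarray([topology.atoms[i].lj_rmin_half for i in ri])[:, None]
        + np.asarray([topology.atoms[j].lj_rmin_half for j in li])[None, :]
    )
    s6 = (rmin / d) ** 6
    e_vdw = float(np.sum(eps * (s6 * s6 - 2.0 * s6)))
    return float(e_ele), e_vdw


# --- generalized Born -------------------------------------------------------

def _hct_term(r: float, rho_i: float, s_j: float) -> float:
    """HCT descreening integral H(r, ρ_i, s_j) = (1/4π) ∫ dV/r'^4 over the
    part of neighbour sphere s_j lying outside ρ_i (distance r between
    centres). Closed form of the standard pairwise-descreening expression."""
    if rho_i >= r + s_j:
        return 0.0  # neighbour sphere buried inside the self-sphere
    u = r + s_j
    if rho_i > abs(r - s_j):
        lo = rho_i
    else:
        lo = abs(r - s_j)
    term = (
        (1.0 / lo - 1.0 / u)
        + 0.25 * r * (1.0 / u**2 - 1.0 / lo**2)
        + 0.5 / r * np.log(lo / u)
        + 0.25 * s_j**2 / r * (1.0 / lo**2 - 1.0 / u**2)
    )
    h = 0.5 * term
    if s_j > r + rho_i:
        # atom i's reduced sphere is engulfed by the descreening sphere
        h += 1.0 / rho_i - 1.0 / lo
    return h


def effective_born_radii(
    frame: Frame, topology: Topology, subset
) -> np.ndarray:
    """HCT pairwise-descreening effective Born radii for ``subset`` (Å).

    1/R_i = 1/ρ_i − Σ_j H(r_ij, ρ_i, S_j ρ_j) with ρ_i the intrinsic radius
    minus the 0.09 Å offset. An isolated atom returns ρ_i; burial grows the
    radius. A non-positive inverse is clamped (R = 30 Å) with a warning.
    """
    idx = np.asarray(sorted(subset), dtype=int)
    rho = np.empty(len(idx))
    scale = np.empty(len(idx))
    for k, i in enumerate(idx):
        a = topology.atoms[i]
        if a.gb_radius is None or a.gb_screen is None:
            raise ParameterizationError(f"atom {a.label()} lacks GB parameters")
        if a.gb_radius <= 0:
            raise ParameterizationError(f"atom {a.label()} has non-positive GB radius")
        rho[k] = a.gb_radius - GB_OFFSET
        scale[k] = a.gb_screen
    coords = frame.coordinates[idx]
    n = len(idx)
    inv = 1.0 / rho
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if n > 1:
        # vectorized H(r_ij, rho_i, s_j) over the full pair matrix
        s = (scale * rho)[None, :]          # descreening sphere of atom j
        p = rho[:, None]                    # reduced self-radius of atom i
        off = ~np.eye(n, dtype=bool)
        active = off & (p < d + s)          # buried neighbours contribute 0
        with np.errstate(divide="ignore", invalid="ignore"):
            u = d + s
            lo = np.maximum(p, np.abs(d - s))
            term = (
                (1.0 / lo - 1.0 / u)
                + 0.25 * d * (1.0 / u**2 - 1.0 / lo**2)
                + 0.5 / d * np.log(lo / u)
                + 0.25 * s**2 / d * (1.0 / lo**2 - 1.0 / u**2)
            )
            h = 0.5 * term
            engulf = active & (s > d + p)
            h = np.where(engulf, h + 1.0 / p - 1.0 / lo, h)
            h = np.where(active, h, 0.0)
        inv -= h.sum(axis=1)
    bad = inv <= 0
    if np.any(bad):
        warnings.warn(
            f"{bad.sum()} non-positive inverse Born radii clamped to "
            f"{_R_EFF_CEILING} Å",
            stacklevel=2,
        )
        inv[bad] = 1.0 / _R_EFF_CEILING
    return 1.0 / inv


def gb_polar(
    frame: Frame,
    topology: Topology,
    subset,
    radii: np.ndarray | None = None,
) -> float:
    """Still-form generalized-Born polar solvation energy of ``subset``.

    E = −(K/2)(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB with
    f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))); the i = j self term uses
    f_GB = R_i. The double sum runs over ordered pairs (off-diagonal terms
    counted twice), which for a single ion reduces to the Born formula.
    """
    idx = np.asarray(sorted(subset), dtype=int)
    if radii is None:
        radii = effective_born_radii(frame, topology, idx)
    q = topology.charges(idx)
    coords = frame.coordinates[idx]
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    rr = np.outer(radii, radii)
    f = np.sqrt(d2 + rr * np.exp(-d2 / (4.0 * rr)))
    pref = -0.5 * COULOMB_K * (
        1.0 / topology.interior_dielectric - 1.0 / topology.exterior_dielectric
    )
    return float(pref * np.sum(np.outer(q, q) / f))


# --- SASA -------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    frame: Frame,
    topology: Topology,
    subset,
    probe: float = DEFAULT_PROBE,
    n_points: int = SASA_POINTS,
    orientation: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area of ``subset``.

    Atomic radii are the LJ rmin/2 values (documented proxy) inflated by the
    probe radius. Returns (total Å², per-atom Å² aligned with the sorted
    subset); deterministic for a given ``n_points``. ``orientation`` (a 3×3
    rotation) rotates the quadrature point set; averaging over uniformly
    random orientations makes the quadrature unbiased, which the snapshot
    pipeline exploits by dithering the orientation across frames.
    """
    idx = np.asarray(sorted(subset), dtype=int)
    radii = []
    for i in idx:
        a = topology.atoms[i]
        if a.lj_rmin_half is None:
            raise ParameterizationError(f"atom {a.label()} lacks LJ radius for SASA")
        radii.append(a.lj_rmin_half + probe)
    radii = np.asarray(radii)
    coords = frame.coordinates[idx]
    sphere = _fibonacci_sphere(n_points)
    if orientation is not None:
        sphere = sphere @ np.asarray(orientation, dtype=float).T
    per_atom = np.zeros(len(idx))
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for k in range(len(idx)):
        # neighbours whose inflated sphere can occlude atom k's surface
        nb = np.nonzero((d[k] < radii[k] + radii) & (np.arange(len(idx)) != k))[0]
        pts = coords[k] + radii[k] * sphere
        if len(nb):
            dist = np.linalg.norm(pts[:, None, :] - coords[nb][None, :, :], axis=-1)
            exposed = np.all(dist >= radii[nb][None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        per_atom[k] = frac * 4.0 * np.pi * radii[k] ** 2
    return float(per_atom.sum()), per_atom


def nonpolar(
    sasa_total: float, gamma: float = DEFAULT_GAMMA, beta: float = DEFAULT_BETA
) -> float:
    """Surface-area nonpolar solvation term γ·SASA + β."""
    if sasa_total < 0:
        raise ValueError(f"SASA must be non-negative, got {sasa_total}")
    return gamma * sasa_total + beta


# --- snapshot assembly ------------------------------------------------------

def snapshot_breakdown(
    frame: Frame,
    topology: Topology,
    partition: ComplexPartition,
    gamma: float = DEFAULT_GAMMA,
    beta: float = DEFAULT_BETA,
    probe: float = DEFAULT_PROBE,
    n_points: int = SASA_POINTS,
    sasa_orientation: np.ndarray | None = None,
) -> EnergyBreakdown:
    """Single-trajectory binding enthalpy components for one snapshot."""
    e_ele, e_vdw = intermolecular_energy(frame, topology, partition)
    comp = partition.all_indices
    rec = partition.receptor_indices
    lig = partition.ligand_indices
    g_pol = (
        gb_polar(frame, topology, comp)
        - gb_polar(frame, topology, rec)
        - gb_polar(frame, topology, lig)
    )
    s_comp, _ = sasa(frame, topology, comp, probe, n_points, sasa_orientation)
    s_rec, _ = sasa(frame, topology, rec, probe, n_points, sasa_orientation)
    s_lig, _ = sasa(frame, topology, lig, probe, n_points, sasa_orientation)
    g_np = (
        nonpolar(s_comp, gamma, beta)
        - nonpolar(s_rec, gamma, beta)
        - nonpolar(s_lig, gamma, beta)
    )
    return EnergyBreakdown(e_ele=e_ele, e_vdw=e_vdw, g_pol=g_pol, g_nonpol=g_np)


def per_residue_decomposition(
    frame: Frame,
    topology: Topology,
    partition: ComplexPartition,
    gamma: float = DEFAULT_GAMMA,
    probe: float = DEFAULT_PROBE,
    n_points: int = SASA_POINTS,
    sasa_orientation: np.ndarray | None = None,
) -> list[ResidueContribution]:
    """Residue-level shares of the snapshot binding enthalpy.

    Every pairwise term is split half/half between the two atoms' residues
    (self terms go wholly to their atom); per-atom SASA differences go to
    the owning residue. The residue totals therefore reconcile exactly with
    :func:`snapshot_breakdown` (to numerical round-off).
    """
    topology.require_parameterized(partition.all_indices)
    comp = partition.all_indices
    rec = partition.receptor_indices
    lig = partition.ligand_indices
    pos_in_comp = {int(a): k for k, a in enumerate(comp)}
    reskeys: list[tuple] = []
    res_of_atom: dict[int, int] = {}
    for key, members in topology.residues().items():
        members = [m for m in members if m in pos_in_comp]
        if not members:
            continue
        reskeys.append(key)
        for m in members:
            res_of_atom[m] = len(reskeys) - 1
    nres = len(reskeys)
    acc = {c: np.zeros(nres) for c in ("e_ele", "e_vdw", "g_pol", "g_nonpol")}

    def put(comp_name: str, i: int, j: int, value: float) -> None:
        if i == j:
            acc[comp_name][res_of_atom[i]] += value
        else:
            acc[comp_name][res_of_atom[i]] += 0.5 * value
            acc[comp_name][res_of_atom[j]] += 0.5 * value

    coords = frame.coordinates
    # gas-phase cross terms
    for i in rec:
        for j in lig:
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r < _MIN_SEPARATION:
                raise SingularityError(
                    f"overlapping atoms {topology.atoms[i].label()} / "
                    f"{topology.atoms[j].label()}"
                )
            ai, aj = topology.atoms[i], topology.atoms[j]
            put("e_ele", i, j,
                coulomb_pair(ai.charge, aj.charge, r, topology.interior_dielectric))
            put("e_vdw", i, j, lj_pair(ai, aj, r))

    # polar: pairwise Still terms, complex minus isolated species
    pref = -0.5 * COULOMB_K * (
        1.0 / topology.interior_dielectric - 1.0 / topology.exterior_dielectric
    )

    def gb_pair_matrix(indices: np.ndarray) -> np.ndarray:
        radii = effective_born_radii(frame, topology, indices)
        q = topology.charges(indices)
        x = coords[indices]
        d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
        rr = np.outer(radii, radii)
        f = np.sqrt(d2 + rr * np.exp(-d2 / (4.0 * rr)))
        return pref * np.outer(q, q) / f

    m_comp = gb_pair_matrix(comp)
    m_rec = gb_pair_matrix(rec)
    m_lig = gb_pair_matrix(lig)
    # complex terms (all ordered pairs)
    for a, i in enumerate(comp):
        for b, j in enumerate(comp):
            if b < a:
                continue
            v = m_comp[a, b] if a == b else 2.0 * m_comp[a, b]
            put("g_pol", int(i), int(j), v)
    for sub, m in ((rec, m_rec), (lig, m_lig)):
        for a, i in enumerate(sub):
            for b, j in enumerate(sub):
                if b < a:
                    continue
                v = m[a, b] if a == b else 2.0 * m[a, b]
                put("g_pol", int(i), int(j), -v)

    # nonpolar: per-atom SASA differences
    _, sa_comp = sasa(frame, topology, comp, probe, n_points, sasa_orientation)
    _, sa_rec = sasa(frame, topology, rec, probe, n_points, sasa_orientation)
    _, sa_lig = sasa(frame, topology, lig, probe, n_points, sasa_orientation)
    delta = {int(i): gamma * sa_comp[k] for k, i in enumerate(comp)}
    for k, i in enumerate(rec):
        delta[int(i)] -= gamma * sa_rec[k]
    for k, i in enumerate(lig):
        delta[int(i)] -= gamma * sa_lig[k]
    for i, v in delta.items():
        acc["g_nonpol"][res_of_atom[i]] += v

    out = []
    for k, key in enumerate(reskeys):
        chain, seq, name = key
        out.append(
            ResidueContribution(
                label=f"{name}{seq}",
                e_ele=float(acc["e_ele"][k]),
                e_vdw=float(acc["e_vdw"][k]),
                g_pol=float(acc["g_pol"][k]),
                g_nonpol=float(acc["g_nonpol"][k]),
            )
        )
    return out
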