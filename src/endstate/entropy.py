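"""Normal-mode conformational entropy for toy systems.

The binding entropy term −TΔS is assembled from standard ideal-gas /
rigid-rotor / harmonic-oscillator absolute entropies at 1 atm, with
vibrational frequencies obtained from the mass-weighted Hessian of the toy
force field. Structures must be (near-)minimized first; rigid-body modes
are identified by a |ν| < 1 cm⁻¹ threshold and removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .core import Frame, Topology
from .toyff import energy_and_gradient

logger = logging.getLogger(__name__)

KB_KCAL = constants.k * constants.N_A / (constants.calorie * 1000.0)  # kcal/mol/K
ZERO_MODE_CM = 1.0      # |ν| below this (cm⁻¹) counts as rigid-body/zero
_FD_STEP = 1e-4         # Å, central-difference step for the Hessian

# eigenvalue (kcal/mol/Å²/amu) -> angular frequency² (s⁻²)
_LAMBDA_TO_OMEGA2 = (
    constants.calorie * 1000.0 / constants.N_A
) / (constants.atomic_mass * 1e-20)


@dataclass
class ModeSpectrum:
    """Vibrational frequencies (cm⁻¹, ascending) after zero-mode removal."""

    frequencies: np.ndarray
    n_zero_removed: int

    def __post_init__(self) -> None:
        self.frequencies = np.sort(np.asarray(self.frequencies, dtype=float))


def hessian(frame: Frame, topology: Topology, subset=None) -> np.ndarray:
    """Mass-unweighted 3N×3N Hessian (kcal/mol/Å²) by central finite
    differences of the analytic toy-FF gradient (step 1e-4 Å); symmetrized."""
    if subset is None:
        subset = np.arange(topology.n_atoms)
    subset = np.asarray(sorted(subset), dtype=int)
    x0 = frame.coordinates[subset].copy()
    n3 = x0.size
    h = np.empty((n3, n3))
    for col in range(n3):
        xp = x0.copy().ravel()
        xm = x0.copy().ravel()
        xp[col] += _FD_STEP
        xm[col] -= _FD_STEP
        _, gp = energy_and_gradient(xp.reshape(-1, 3), topology, subset)
        _, gm = energy_and_gradient(xm.reshape(-1, 3), topology, subset)
        h[:, col] = (gp.ravel() - gm.ravel()) / (2.0 * _FD_STEP)
    return 0.5 * (h + h.T)


def normal_modes(hess: np.ndarray, masses: np.ndarray) -> ModeSpectrum:
    """Vibrational spectrum from a mass-weighted Hessian.

    Near-zero modes (|ν| < 1 cm⁻¹, including negative-curvature modes that
    map to imaginary frequencies) are removed and counted. More than six
    removals triggers a not-at-minimum warning, as do surviving negative
    eigenvalues.
    """
    masses = np.asarray(masses, dtype=float)
    w = np.repeat(1.0 / np.sqrt(masses), 3)
    mw = hess * np.outer(w, w)
    evals = np.linalg.eigvalsh(mw)
    omega2 = evals * _LAMBDA_TO_OMEGA2
    nu_cm = (
        np.sign(omega2)
        * np.sqrt(np.abs(omega2))
        / (2.0 * np.pi * constants.c * 100.0)
    )
    keep = np.abs(nu_cm) >= ZERO_MODE_CM
    removed = int((~keep).sum())
    if removed > 6:
        warnings.warn(
            f"{removed} near-zero modes removed (>6): structure not at a minimum?",
            stacklevel=2,
        )
    kept = nu_cm[keep]
    negative = kept[kept < 0]
    if len(negative):
        warnings.warn(
            f"{len(negative)} imaginary modes discarded: structure not at a minimum",
            stacklevel=2,
        )
        kept = kept[kept > 0]
        removed += len(negative)
    return ModeSpectrum(frequencies=kept, n_zero_removed=removed)


def vibrational_entropy(spectrum: ModeSpectrum, T: float = 300.0) -> float:
    """Harmonic-oscillator S_vib in kcal/mol/K."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    nu = np.asarray(spectrum.frequencies, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("zero/negative frequencies must be removed before S_vib")
    if len(nu) == 0:
        return 0.0
    x = constants.h * nu * constants.c * 100.0 / (constants.k * T)
    # modes with h*nu >> kT contribute nothing; skip them to avoid overflow
    x = x[x < 500.0]
    if len(x) == 0:
        return 0.0
    s = np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x)))
    return float(KB_KCAL * s)


def translational_entropy(mass_total: float, T: float = 300.0,
                          pressure: float = constants.atm) -> float:
    """Sackur–Tetrode S_trans (kcal/mol/K) for mass in amu at 1 atm."""
    m = mass_total * constants.atomic_mass
    v = constants.k * T / pressure
    q = (2.0 * np.pi * m * constants.k * T / constants.h**2) ** 1.5 * v
    return float(KB_KCAL * (np.log(q) + 2.5))


def rotational_entropy(inertia, T: float = 300.0, symmetry_number: int = 1) -> float:
    """Rigid-rotor S_rot (kcal/mol/K); ``inertia`` is the principal-moment
    triple in amu·Å² (a single scalar or one non-zero moment => linear rotor;
    all (near-)zero => single atom, S_rot = 0)."""
    moments = np.atleast_1d(np.asarray(inertia, dtype=float))
    si = moments * constants.atomic_mass * 1e-20  # kg m²
    nonzero = si[si > 1e-60]
    if len(nonzero) == 0:
        return 0.0
    b = 8.0 * np.pi**2 * constants.k * T / constants.h**2
    if len(nonzero) < 3:  # linear rotor
        q = b * float(nonzero.max()) / symmetry_number
        return float(KB_KCAL * (np.log(q) + 1.0))
    q = np.sqrt(np.pi * np.prod(b * nonzero)) / symmetry_number
    return float(KB_KCAL * (np.log(q) + 1.5))


def principal_moments(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Principal moments of inertia (amu·Å²), ascending."""
    masses = np.asarray(masses, dtype=float)
    x = coords - np.average(coords, axis=0, weights=masses)
    tensor = np.zeros((3, 3))
    for m, r in zip(masses, x):
        tensor += m * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    return np.sort(np.linalg.eigvalsh(tensor))


def species_entropy(
    spectrum: ModeSpectrum,
    mass_total: float,
    inertia,
    T: float = 300.0,
    symmetry_number: int = 1,
) -> dict[str, float]:
    """Absolute entropy components (kcal/mol/K) and the −T·S term (kcal/mol)."""
    s_vib = vibrational_entropy(spectrum, T)
    s_trans = translational_entropy(mass_total, T)
    s_rot = rotational_entropy(inertia, T, symmetry_number)
    total = s_vib + s_trans + s_rot
    return {
        "s_trans": s_trans,
        "s_rot": s_rot,
        "s_vib": s_vib,
        "s_total": total,
        "minus_t_s": -T * total,
    }


def entropy_term(
    spectrum: ModeSpectrum,
    mass_total: float,
    inertia,
    T: float = 300.0,
    symmetry_number: int = 1,
) -> float:
    """−T·S (kcal/mol) for one species."""
    return species_entropy(spectrum, mass_total, inertia, T, symmetry_number)[
        "minus_t_s"
    ]


def binding_entropy_term(
    complex_species: dict[str, float],
    receptor_species: dict[str, float],
    ligand_species: dict[str, float],
    T: float = 300.0,
) -> float:
    """Binding −TΔS = −T(S_complex − S_receptor − S_ligand), positive when
    binding restricts motion. Inputs are :func:`species_entropy` dicts."""
    ds = (
        complex_species["s_total"]
        - receptor_species["s_total"]
        - ligand_species["s_total"]
    )
    return -T * ds


def snapshot_entropy_term(
    frame: Frame,
    topology: Topology,
    partition,
    T: float = 300.0,
    minimize: bool = True,
    minimize_tol: float = 1e-6,
) -> float:
    """Full −TΔS for one snapshot: minimize each species, normal-mode
    analysis, then the trans/rot/vib entropy difference."""
    from .toyff import minimize_structure

    def one(indices) -> dict[str, float]:
        idx = np.asarray(sorted(indices), dtype=int)
        fr = minimize_structure(frame, topology, idx, tol=minimize_tol) if minimize else frame
        hess = hessian(fr, topology, idx)
        masses = topology.masses(idx)
        spec = normal_modes(hess, masses)
        inertia = principal_moments(fr.coordinates[idx], masses)
        return species_entropy(spec, float(masses.sum()), inertia, T)

    sc = one(partition.all_indices)
    sr = one(partition.receptor_indices)
    sl = one(partition.ligand_indices)
    return binding_entropy_term(sc, sr, sl, T)
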