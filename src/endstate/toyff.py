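"""Toy molecular-mechanics force field: harmonic bonds and angles plus
intramolecular nonbonded (Coulomb + 12-6 LJ) terms.

Exists so that structures can be minimized and normal-mode entropies
computed on desk-scale systems. Pairs separated by one bond (1-2) or one
angle (1-3) are excluded from the nonbonded sum; there are no dihedrals.
Energies kcal/mol, gradients kcal/mol/Å.
"""

from __future__ import annotations

import numpy as np

from .core import Frame, Topology
from .exceptions import SingularityError
from .energetics import COULOMB_K


def _tables(topology: Topology, subset: np.ndarray) -> dict:
    """Vectorized term tables for a subset; cached on the topology object."""
    key = tuple(int(i) for i in subset)
    cache = getattr(topology, "_toyff_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(topology, "_toyff_cache", cache)
    if key in cache:
        return cache[key]
    pos = {g: k for k, g in enumerate(key)}
    bonds = [
        (pos[i], pos[j], kb, r0)
        for (i, j, kb, r0) in topology.bonds
        if i in pos and j in pos
    ]
    angles = [
        (pos[i], pos[j], pos[k], ka, th0)
        for (i, j, k, ka, th0) in topology.angles
        if i in pos and j in pos and k in pos
    ]
    excluded: set[tuple[int, int]] = set()
    for (i, j, *_r) in topology.bonds:
        excluded.add((min(i, j), max(i, j)))
    for (i, j, k, *_r) in topology.angles:
        for a, b in ((i, j), (j, k), (i, k)):
            excluded.add((min(a, b), max(a, b)))
    pairs = []
    for a in range(len(key)):
        for b in range(a + 1, len(key)):
            gk = (min(key[a], key[b]), max(key[a], key[b]))
            if gk not in excluded:
                pairs.append((a, b, key[a], key[b]))
    atoms = topology.atoms
    tab = {
        "bond_i": np.array([b[0] for b in bonds], dtype=int),
        "bond_j": np.array([b[1] for b in bonds], dtype=int),
        "bond_k": np.array([b[2] for b in bonds], dtype=float),
        "bond_r0": np.array([b[3] for b in bonds], dtype=float),
        "ang_i": np.array([a[0] for a in angles], dtype=int),
        "ang_j": np.array([a[1] for a in angles], dtype=int),
        "ang_k": np.array([a[2] for a in angles], dtype=int),
        "ang_ka": np.array([a[3] for a in angles], dtype=float),
        "ang_t0": np.array([a[4] for a in angles], dtype=float),
        "nb_i": np.array([p[0] for p in pairs], dtype=int),
        "nb_j": np.array([p[1] for p in pairs], dtype=int),
        "nb_qq": np.array(
            [
                COULOMB_K * atoms[p[2]].charge * atoms[p[3]].charge
                / topology.interior_dielectric
                for p in pairs
            ],
            dtype=float,
        ),
        "nb_eps": np.array(
            [np.sqrt(atoms[p[2]].lj_epsilon * atoms[p[3]].lj_epsilon) for p in pairs],
            dtype=float,
        ),
        "nb_rmin": np.array(
            [atoms[p[2]].lj_rmin_half + atoms[p[3]].lj_rmin_half for p in pairs],
            dtype=float,
        ),
    }
    cache[key] = tab
    return tab


def energy_and_gradient(
    coords: np.ndarray, topology: Topology, subset=None
) -> tuple[float, np.ndarray]:
    """Total toy-FF energy and its analytic gradient w.r.t. ``coords``.

    ``coords`` has one row per subset atom (subset defaults to all atoms,
    in index order). The gradient array matches the shape of ``coords``.
    """
    if subset is None:
        subset = np.arange(topology.n_atoms)
    subset = np.asarray(sorted(subset), dtype=int)
    t = _tables(topology, subset)
    coords = np.asarray(coords, dtype=float)
    energy = 0.0
    grad = np.zeros_like(coords)

    if len(t["bond_i"]):
        dv = coords[t["bond_i"]] - coords[t["bond_j"]]
        r = np.linalg.norm(dv, axis=1)
        if np.any(r < 1e-10):
            raise SingularityError("bonded atoms coincide")
        dr = r - t["bond_r0"]
        energy += float(np.sum(t["bond_k"] * dr * dr))
        g = (2.0 * t["bond_k"] * dr / r)[:, None] * dv
        np.add.at(grad, t["bond_i"], g)
        np.add.at(grad, t["bond_j"], -g)

    if len(t["ang_i"]):
        u = coords[t["ang_i"]] - coords[t["ang_j"]]
        v = coords[t["ang_k"]] - coords[t["ang_j"]]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        if np.any(nu < 1e-10) or np.any(nv < 1e-10):
            raise SingularityError("angle atoms degenerate")
        cos_t = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        dth = theta - t["ang_t0"]
        energy += float(np.sum(t["ang_ka"] * dth * dth))
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
        pref = (2.0 * t["ang_ka"] * dth) * (-1.0 / sin_t)
        dcos_du = v / (nu * nv)[:, None] - (cos_t / nu**2)[:, None] * u
        dcos_dv = u / (nu * nv)[:, None] - (cos_t / nv**2)[:, None] * v
        ga = pref[:, None] * dcos_du
        gc = pref[:, None] * dcos_dv
        np.add.at(grad, t["ang_i"], ga)
        np.add.at(grad, t["ang_k"], gc)
        np.add.at(grad, t["ang_j"], -(ga + gc))

    if len(t["nb_i"]):
        dv = coords[t["nb_i"]] - coords[t["nb_j"]]
        r = np.linalg.norm(dv, axis=1)
        if np.any(r < 1e-8):
            raise SingularityError("nonbonded atoms coincide")
        energy += float(np.sum(t["nb_qq"] / r))
        dEdr = -t["nb_qq"] / r**2
        lj = t["nb_eps"] > 0
        if np.any(lj):
            s6 = np.zeros_like(r)
            s6[lj] = (t["nb_rmin"][lj] / r[lj]) ** 6
            energy += float(np.sum(t["nb_eps"] * (s6 * s6 - 2.0 * s6)))
            dEdr += np.where(lj, 12.0 * t["nb_eps"] * (s6 - s6 * s6) / r, 0.0)
        g = (dEdr / r)[:, None] * dv
        np.add.at(grad, t["nb_i"], g)
        np.add.at(grad, t["nb_j"], -g)

    if not np.isfinite(energy):
        raise SingularityError("non-finite toy-FF energy")
    return float(energy), grad


def minimize_structure(
    frame: Frame,
    topology: Topology,
    subset=None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> Frame:
    """Minimize the toy-FF energy of ``subset`` (L-BFGS with analytic
    gradients; converged when the projected gradient falls below ``tol``
    kcal/mol/Å or the iteration cap is hit). Returns a new Frame with the
    subset's rows replaced by minimized coordinates."""
    from scipy.optimize import minimize

    if subset is None:
        subset = np.arange(topology.n_atoms)
    subset = np.asarray(sorted(subset), dtype=int)
    x0 = frame.coordinates[subset].ravel()

    def fun(x):
        e, g = energy_and_gradient(x.reshape(-1, 3), topology, subset)
        return e, g.ravel()

    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    out = frame.coordinates.copy()
    out[subset] = res.x.reshape(-1, 3)
    return frame.with_coordinates(out)
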