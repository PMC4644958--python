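"""Energetics oracles: Coulomb/LJ closed forms, HCT descreening against a
numerical integration oracle, the Born-ion limit, Shrake–Rupley
convergence, and decomposition conservation."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from endstate.core import ComplexPartition, Frame, Topology
from endstate.energetics import (
    COULOMB_K,
    GB_OFFSET,
    coulomb_pair,
    effective_born_radii,
    gb_polar,
    intermolecular_energy,
    lj_pair,
    nonpolar,
    per_residue_decomposition,
    sasa,
    snapshot_breakdown,
)
from endstate.exceptions import SingularityError

from conftest import plain_atom, two_particle_system


class TestCoulomb:
    @pytest.mark.parametrize(
        "qi,qj,r,dielectric,expected",
        [
            (0.0, 1.0, 3.0, 1.0, 0.0),
            (1.0, 1.0, 3.320637, 1.0, 100.0),
            (1.0, -1.0, 3.320637, 1.0, -100.0),
            (1.0, 1.0, 3.320637, 2.0, 50.0),
        ],
    )
    def test_values(self, qi, qj, r, dielectric, expected):
        assert coulomb_pair(qi, qj, r, dielectric) == pytest.approx(
            expected, abs=1e-4
        )

    def test_singularity(self):
        with pytest.raises(SingularityError):
            coulomb_pair(1.0, 1.0, 0.0)


class TestLennardJones:
    def test_minimum_is_minus_epsilon_at_rmin(self):
        a = plain_atom(1, epsilon=0.1, rmin_half=1.9)
        b = plain_atom(2, epsilon=0.1, rmin_half=1.9)
        assert lj_pair(a, b, 3.8) == pytest.approx(-0.1, abs=1e-12)

    def test_zero_epsilon_vanishes(self):
        a = plain_atom(1, epsilon=0.0)
        b = plain_atom(2, epsilon=0.3)
        assert lj_pair(a, b, 2.0) == 0.0

    def test_rmin_is_stationary_point(self):
        """Numerical derivative on a grid brackets the minimum at Rmin."""
        a = plain_atom(1, epsilon=0.21, rmin_half=1.66)
        b = plain_atom(2, epsilon=0.17, rmin_half=1.82)
        rmin = 1.66 + 1.82
        rs = np.linspace(rmin - 0.5, rmin + 0.5, 201)
        vals = np.array([lj_pair(a, b, r) for r in rs])
        assert rs[np.argmin(vals)] == pytest.approx(rmin, abs=0.01)
        assert vals.min() == pytest.approx(-np.sqrt(0.21 * 0.17), abs=1e-6)


class TestIntermolecular:
    def test_zero_parameters_give_zero(self):
        topo, frame, part = two_particle_system(q1=1.0, q2=0.0, eps=0.0)
        e_ele, e_vdw = intermolecular_energy(frame, topo, part)
        assert e_ele == 0.0 and e_vdw == 0.0

    def test_single_pair_closed_form(self):
        topo, frame, part = two_particle_system(q1=1.0, q2=-1.0,
                                                r=3.320637, eps=0.0)
        e_ele, e_vdw = intermolecular_energy(frame, topo, part)
        assert e_ele == pytest.approx(-100.0, abs=1e-4)
        assert e_vdw == 0.0

    def test_charge_linearity(self, host_guest):
        topo, frame, part = host_guest
        e1, _ = intermolecular_energy(frame, topo, part)
        for i in part.ligand:
            topo.atoms[i].charge *= 2.0
        e2, _ = intermolecular_energy(frame, topo, part)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_overlap_raises_naming_pair(self):
        topo, frame, part = two_particle_system(r=1e-9)
        with pytest.raises(SingularityError, match="REC1:A1"):
            intermolecular_energy(frame, topo, part)


def _hct_numerical(d, rho_i, s_j):
    """Numerical oracle: (1/4π) ∫ dV/r^4 over the part of the descreening
    sphere (radius s_j, centre distance d) outside the self-sphere rho_i,
    in spherical shells around atom i."""

    def shell(r):
        # fraction of the sphere of radius r (about i) lying inside sphere j
        if r + d <= s_j:
            frac = 1.0
        elif abs(r - d) >= s_j:
            frac = 0.0
        else:
            cos_t = (r * r + d * d - s_j * s_j) / (2.0 * r * d)
            frac = 0.5 * (1.0 - cos_t)
        return frac / (r * r)

    lo = max(rho_i, d - s_j)
    hi = d + s_j
    if hi <= lo:
        return 0.0
    val, _ = quad(shell, lo, hi, limit=200)
    return val


class TestBornRadii:
    def test_isolated_atom_offset(self):
        atoms = [plain_atom(1, gb_radius=1.5)]
        topo = Topology(atoms=atoms)
        frame = Frame(coordinates=np.zeros((1, 3)))
        radii = effective_born_radii(frame, topo, [0])
        assert radii[0] == pytest.approx(1.41, abs=1e-12)

    def test_distant_pair_is_asymptotically_isolated(self):
        topo, frame, _ = two_particle_system(r=100.0, gb_radius=1.5)
        radii = effective_born_radii(frame, topo, [0, 1])
        assert radii[0] == pytest.approx(1.41, abs=1e-3)

    def test_contact_pair_grows_radii(self):
        topo, frame, _ = two_particle_system(r=2.0, gb_radius=1.5)
        radii = effective_born_radii(frame, topo, [0, 1])
        assert radii[0] > 1.41 and radii[1] > 1.41

    @pytest.mark.parametrize("d", [2.0, 3.0, 6.0])
    def test_matches_descreening_integral_oracle(self, d):
        gb_radius, screen = 1.5, 0.8
        topo, frame, _ = two_particle_system(r=d, gb_radius=gb_radius)
        for a in topo.atoms:
            a.gb_screen = screen
        rho = gb_radius - GB_OFFSET
        expected_inv = 1.0 / rho - _hct_numerical(d, rho, screen * rho)
        radii = effective_born_radii(frame, topo, [0, 1])
        assert 1.0 / radii[0] == pytest.approx(expected_inv, abs=1e-8)


class TestGBPolar:
    def test_born_ion_closed_form(self):
        # intrinsic radius 2.09 -> effective radius 2.0 after the offset
        atoms = [plain_atom(1, charge=1.0, gb_radius=2.09)]
        topo = Topology(atoms=atoms)
        frame = Frame(coordinates=np.zeros((1, 3)))
        expected = -0.5 * COULOMB_K * (1.0 - 1.0 / 80.0) / 2.0
        assert gb_polar(frame, topo, [0]) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(-81.98, abs=0.005)

    def test_zero_charges_vanish(self, host_guest):
        topo, frame, part = host_guest
        for a in topo.atoms:
            a.charge = 0.0
        assert gb_polar(frame, topo, part.all_indices) == 0.0

    def test_quadratic_in_charge(self, host_guest):
        topo, frame, part = host_guest
        e1 = gb_polar(frame, topo, part.all_indices)
        for a in topo.atoms:
            a.charge = -a.charge
        e2 = gb_polar(frame, topo, part.all_indices)
        assert e2 == pytest.approx(e1, rel=1e-12)

    def test_rigid_motion_invariance(self, host_guest):
        topo, frame, part = host_guest
        e1 = gb_polar(frame, topo, part.all_indices)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = frame.with_coordinates(frame.coordinates @ rot.T + [5.0, -3.0, 1.0])
        e2 = gb_polar(moved, topo, part.all_indices)
        assert e2 == pytest.approx(e1, rel=1e-8)


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        atoms = [plain_atom(1, rmin_half=1.6)]
        topo = Topology(atoms=atoms)
        frame = Frame(coordinates=np.zeros((1, 3)))
        total, per_atom = sasa(frame, topo, [0])
        expected = 4.0 * np.pi * (1.6 + 1.4) ** 2
        assert expected == pytest.approx(113.10, abs=0.005)
        assert total == pytest.approx(expected, rel=0.005)
        assert per_atom.sum() == pytest.approx(total)

    def test_far_pair_additivity(self):
        topo, frame, _ = two_particle_system(r=50.0, rmin_half=1.6)
        total, _ = sasa(frame, topo, [0, 1])
        single = 4.0 * np.pi * (1.6 + 1.4) ** 2
        assert total == pytest.approx(2 * single, rel=0.005)

    def test_buried_atom_contributes_zero(self):
        atoms = [plain_atom(1, rmin_half=3.0),
                 plain_atom(2, rmin_half=0.4, res_seq=2)]
        topo = Topology(atoms=atoms)
        frame = Frame(coordinates=np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]))
        _, per_atom = sasa(frame, topo, [0, 1])
        assert per_atom[1] == 0.0

    def test_quadrature_convergence(self, host_guest):
        topo, frame, part = host_guest
        subset = part.all_indices[:10]
        t1, _ = sasa(frame, topo, subset, n_points=960)
        t2, _ = sasa(frame, topo, subset, n_points=1920)
        assert abs(t2 - t1) / t2 < 0.003

    def test_nonpolar_term(self):
        assert nonpolar(0.0) == 0.0
        assert nonpolar(113.10) == pytest.approx(0.5655, abs=1e-9)
        assert nonpolar(500.0, gamma=0.0, beta=1.25) == 1.25
        with pytest.raises(ValueError):
            nonpolar(-1.0)


class TestSnapshotBreakdown:
    def test_infinitely_separated_ligand_vanishes(self, host_guest):
        topo, frame, part = host_guest
        # the species carry net +/-2 charge, so the monopole tail decays
        # only as 1/r: push far enough that even it is below tolerance
        far = frame.coordinates.copy()
        far[sorted(part.ligand)] += np.array([1.0e7, 0.0, 0.0])
        bd = snapshot_breakdown(frame.with_coordinates(far), topo, part)
        for key, val in bd.as_dict().items():
            assert abs(val) < 1e-3, key

    def test_two_charge_gpol_matches_still_hand_formula(self):
        topo, frame, part = two_particle_system(q1=1.0, q2=-1.0, r=4.0,
                                                gb_radius=1.5)
        radii = effective_born_radii(frame, topo, [0, 1])
        pref = -0.5 * COULOMB_K * (1.0 - 1.0 / 80.0)
        # brute-force Still sum: two self terms + twice the cross term
        f_cross = np.sqrt(
            16.0 + radii[0] * radii[1]
            * np.exp(-16.0 / (4.0 * radii[0] * radii[1]))
        )
        e_complex = pref * (
            1.0 / radii[0] + 1.0 / radii[1] + 2.0 * (-1.0) / f_cross
        )
        iso = 1.5 - GB_OFFSET
        e_parts = pref * (1.0 / iso + 1.0 / iso)
        bd = snapshot_breakdown(frame, topo, part)
        assert bd.g_pol == pytest.approx(e_complex - e_parts, abs=1e-9)

    def test_ligand_charge_flip_flips_ele_only(self, host_guest):
        topo, frame, part = host_guest
        b1 = snapshot_breakdown(frame, topo, part)
        for i in part.ligand:
            topo.atoms[i].charge = -topo.atoms[i].charge
        b2 = snapshot_breakdown(frame, topo, part)
        assert b2.e_ele == pytest.approx(-b1.e_ele, rel=1e-12)
        assert b2.e_vdw == pytest.approx(b1.e_vdw, rel=1e-12)

    def test_composite_identities(self, host_guest):
        topo, frame, part = host_guest
        bd = snapshot_breakdown(frame, topo, part)
        assert bd.g_ele_pol == pytest.approx(bd.e_ele + bd.g_pol, abs=1e-9)
        assert bd.g_vdw_nonpol == pytest.approx(bd.e_vdw + bd.g_nonpol, abs=1e-9)
        assert bd.h == pytest.approx(
            bd.e_ele + bd.e_vdw + bd.g_pol + bd.g_nonpol, abs=1e-9
        )


class TestDecomposition:
    def test_conservation_on_host_guest(self, host_guest):
        topo, frame, part = host_guest
        bd = snapshot_breakdown(frame, topo, part)
        contribs = per_residue_decomposition(frame, topo, part)
        for key in ("e_ele", "e_vdw", "g_pol", "g_nonpol"):
            total = sum(getattr(c, key) for c in contribs)
            assert total == pytest.approx(bd.as_dict()[key], abs=1e-6), key
        assert sum(c.total for c in contribs) == pytest.approx(bd.h, abs=1e-6)

    def test_single_residue_receptor_gets_everything(self):
        topo, frame, part = two_particle_system(q1=1.0, q2=-1.0, r=4.0)
        bd = snapshot_breakdown(frame, topo, part)
        contribs = per_residue_decomposition(frame, topo, part)
        assert len(contribs) == 2  # one receptor residue + the ligand bucket
        assert sum(c.total for c in contribs) == pytest.approx(bd.h, abs=1e-9)

    def test_symmetric_residues_contribute_equally(self):
        """Two identical receptor atoms mirror-placed about a central ligand."""
        atoms = [
            plain_atom(1, name="A1", res_name="RES", res_seq=1, charge=0.5),
            plain_atom(2, name="A1", res_name="RES", res_seq=2, charge=0.5),
            plain_atom(3, name="L1", res_name="LIG", res_seq=9, charge=-1.0),
        ]
        topo = Topology(atoms=atoms)
        frame = Frame(coordinates=np.array([
            [-3.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 0.0, 0.0]
        ]))
        part = ComplexPartition(receptor=frozenset({0, 1}),
                                ligand=frozenset({2}))
        contribs = {c.label: c for c in
                    per_residue_decomposition(frame, topo, part)}
        for key in ("e_ele", "e_vdw", "g_pol"):
            assert getattr(contribs["RES1"], key) == pytest.approx(
                getattr(contribs["RES2"], key), abs=1e-9
            ), key
        # the deterministic SASA point set is not mirror-symmetric, so the
        # nonpolar split matches only to quadrature granularity
        assert contribs["RES1"].g_nonpol == pytest.approx(
            contribs["RES2"].g_nonpol, abs=0.02
        )
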