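"""Superposition/RMSD oracles (quaternion method, Monte-Carlo jitter) and
hydrogen-bond boundary behaviour."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endstate.core import Frame, Topology, Trajectory
from endstate.exceptions import StructureError
from endstate.structure import (
    distance_series,
    find_hbonds,
    hbond_count_profile,
    hbond_occupancy,
    kabsch_superpose,
    rmsd,
    rmsd_series,
)
from endstate.synthetic import GeneratorSpec, jitter_trajectory

from conftest import plain_atom


def _quaternion_rmsd(mobile, reference):
    """Independent optimal-superposition RMSD via the quaternion
    (Horn) eigenvalue method."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    sq = (np.sum(a * a) + np.sum(b * b) - 2.0 * lam) / len(a)
    return np.sqrt(max(sq, 0.0))


class TestKabsch:
    def test_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        rot, trans, fitted = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        assert rmsd(fitted, pts) == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        _, _, fitted = kabsch_superpose(pts + [5.0, 0.0, 0.0], pts)
        assert rmsd(fitted, pts) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        # a mirror image must still be fit with det=+1
        rot, _, _ = kabsch_superpose(pts * [-1, 1, 1], pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    def test_matches_quaternion_oracle(self):
        base = np.array([[0, 0, 0], [2, 0, 0], [0, 1.5, 0], [0.3, 0.2, 1.1]])
        mobile = base.copy()
        mobile[3] += [0.5, -0.2, 0.4]
        rot = Rotation.from_euler("zyx", [0.4, -0.9, 1.2]).as_matrix()
        mobile = mobile @ rot.T + [3.0, -1.0, 2.0]
        _, _, fitted = kabsch_superpose(mobile, base)
        assert rmsd(fitted, base) == pytest.approx(
            _quaternion_rmsd(mobile, base), abs=1e-6
        )

    def test_collinear_fit_set_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(StructureError, match="collinear|degenerate"):
            kabsch_superpose(line, line + 0.1)


class TestRMSDSeries:
    def _static_traj(self, host_guest, n=5, transform=None):
        topo, base, _ = host_guest
        frames = []
        for k in range(n):
            coords = base.coordinates
            if transform is not None:
                coords = transform(coords, k)
            frames.append(Frame(coordinates=coords, time=float(k + 1)))
        return Trajectory(topology=topo, frames=frames)

    def test_reference_vs_itself_is_zero(self, host_guest):
        traj = self._static_traj(host_guest)
        out = rmsd_series(traj, fit_subset=range(traj.topology.n_atoms))
        np.testing.assert_allclose(out["rmsd"], 0.0, atol=1e-12)

    def test_rigid_motion_invisible_after_fit(self, host_guest):
        def move(coords, k):
            rot = Rotation.from_euler("z", 0.1 * k).as_matrix()
            return coords @ rot.T + [0.5 * k, 0.0, 0.0]

        traj = self._static_traj(host_guest, transform=move)
        out = rmsd_series(traj, fit_subset=range(traj.topology.n_atoms))
        np.testing.assert_allclose(out["rmsd"], 0.0, atol=1e-9)

    def test_jittered_mean_matches_monte_carlo_oracle(self, host_guest):
        """Mean fitted RMSD under iid Gaussian jitter, vs an independent
        simulation using scipy's align_vectors."""
        topo, base, _ = host_guest
        sigma, n_frames = 0.3, 1000
        spec = GeneratorSpec(seed=11, jitter_sigma=sigma, n_frames=n_frames)
        traj = jitter_trajectory(base, topo, spec)
        out = rmsd_series(traj, fit_subset=range(topo.n_atoms))

        # reference frame 0 is itself jittered, so the oracle compares two
        # independently jittered copies of the pose
        rng = np.random.default_rng(99)
        ref = base.coordinates + rng.normal(0, sigma, base.coordinates.shape)
        vals = []
        for _ in range(1000):
            noisy = base.coordinates + rng.normal(0, sigma,
                                                  base.coordinates.shape)
            a = noisy - noisy.mean(axis=0)
            b = ref - ref.mean(axis=0)
            rot, rssd = Rotation.align_vectors(b, a)
            vals.append(rssd / np.sqrt(len(a)))
        # drop the zero self-RMSD of the reference frame itself
        assert out["rmsd"][1:].mean() == pytest.approx(np.mean(vals), rel=0.05)


def _hbond_system(acceptor_pos):
    atoms = [
        plain_atom(1, name="N", element="N", res_name="DON", res_seq=1),
        plain_atom(2, name="H", element="H", res_name="DON", res_seq=1),
        plain_atom(3, name="O", element="O", res_name="ACC", res_seq=2),
    ]
    topo = Topology(atoms=atoms, bonds=[(0, 1, 450.0, 1.0)])
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], list(acceptor_pos)])
    return topo, Frame(coordinates=coords)


class TestHBonds:
    def test_collinear_geometry_detected(self):
        topo, frame = _hbond_system((2.8, 0.0, 0.0))
        bonds = find_hbonds(frame, topo, donors=[0], acceptors=[2])
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.8)
        assert bonds[0].angle == pytest.approx(180.0)

    def test_distance_failure(self):
        topo, frame = _hbond_system((3.6, 0.0, 0.0))
        assert find_hbonds(frame, topo, [0], [2]) == []

    def test_angle_failure(self):
        # place the acceptor at 2.9 A from the donor with D-H-A = 119°
        theta = np.deg2rad(180.0 - 119.0)
        # solve for acceptor position: |DA| = 2.9, angle at H = 119°
        # H at (1,0,0); direction from H making 119° with H->D axis
        direction = np.array([np.cos(np.deg2rad(119.0)),
                              np.sin(np.deg2rad(119.0)), 0.0])
        for ha in np.linspace(0.5, 3.5, 2001):
            a = np.array([1.0, 0.0, 0.0]) - direction * ha
            if abs(np.linalg.norm(a) - 2.9) < 2e-3:
                break
        topo, frame = _hbond_system(tuple(a))
        assert find_hbonds(frame, topo, [0], [2]) == []

    @pytest.mark.parametrize(
        "acceptor,reason",
        [((3.5, 0.0, 0.0), "d == 3.5 exactly is excluded")],
    )
    def test_strict_distance_boundary(self, acceptor, reason):
        topo, frame = _hbond_system(acceptor)
        assert find_hbonds(frame, topo, [0], [2]) == [], reason

    def test_strict_angle_boundary(self):
        # exactly 120° at d < 3.5 must be excluded; slightly larger passes
        d_ha = 1.9
        for ang_deg, expect in [(120.0, 0), (120.5, 1)]:
            direction = np.array([np.cos(np.deg2rad(ang_deg)),
                                  np.sin(np.deg2rad(ang_deg)), 0.0])
            a = np.array([1.0, 0.0, 0.0]) - direction * d_ha
            topo, frame = _hbond_system(tuple(a))
            found = find_hbonds(frame, topo, [0], [2])
            assert len(found) == expect, ang_deg

    def test_angle_vertex_convention_is_overridable(self):
        # near-linear D-H...A passes the (default) hydrogen-vertex
        # convention but fails a donor-vertex H-D-A > 120 criterion
        topo, frame = _hbond_system((2.6, 0.6, 0.0))
        assert len(find_hbonds(frame, topo, [0], [2])) == 1
        assert find_hbonds(frame, topo, [0], [2], angle_at="donor") == []
        with pytest.raises(ValueError):
            find_hbonds(frame, topo, [0], [2], angle_at="acceptor")

    def test_donor_without_hydrogen_skipped(self):
        atoms = [
            plain_atom(1, name="N", element="N", res_name="DON", res_seq=1),
            plain_atom(2, name="O", element="O", res_name="ACC", res_seq=2),
        ]
        topo = Topology(atoms=atoms)
        frame = Frame(coordinates=np.array([[0.0, 0.0, 0.0], [2.8, 0.0, 0.0]]))
        assert find_hbonds(frame, topo, [0], [1]) == []


class TestOccupancy:
    def _make_traj(self, present_flags):
        topo, _ = _hbond_system((2.8, 0.0, 0.0))
        frames = []
        for k, present in enumerate(present_flags):
            x = 2.8 if present else 4.5
            frames.append(Frame(
                coordinates=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                                      [x, 0.0, 0.0]]),
                time=float(k + 1),
            ))
        return Trajectory(topology=topo, frames=frames)

    def test_always_present_is_100(self):
        traj = self._make_traj([True] * 10)
        stats = hbond_occupancy(traj, [0], [2])
        assert stats[0].occupancy == 100.0
        assert stats[0].mean_distance == pytest.approx(2.8)

    def test_684_of_1000_frames_is_68_4(self):
        flags = [True] * 684 + [False] * 316
        stats = hbond_occupancy(self._make_traj(flags), [0], [2])
        assert stats[0].occupancy == pytest.approx(68.4)

    def test_never_present_omitted(self):
        stats = hbond_occupancy(self._make_traj([False] * 5), [0], [2])
        assert stats == []

    def test_permutation_invariance_over_frames(self):
        rng = np.random.default_rng(3)
        flags = [bool(b) for b in rng.integers(0, 2, 50)]
        occ1 = hbond_occupancy(self._make_traj(flags), [0], [2])[0].occupancy
        rng.shuffle(flags)
        occ2 = hbond_occupancy(self._make_traj(flags), [0], [2])[0].occupancy
        assert occ1 == occ2


class TestDistanceSeries:
    def test_static_structure_exact(self, host_guest):
        topo, base, _ = host_guest
        traj = Trajectory(topology=topo, frames=[base])
        out = distance_series(traj, 0, 5)
        assert out["window_mean"] == pytest.approx(
            float(np.linalg.norm(base.coordinates[0] - base.coordinates[5]))
        )

    def test_two_frames_average(self):
        atoms = [plain_atom(1), plain_atom(2, res_seq=2)]
        topo = Topology(atoms=atoms)
        frames = [
            Frame(coordinates=np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]),
                  time=1.0),
            Frame(coordinates=np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]]),
                  time=2.0),
        ]
        out = distance_series(Trajectory(topology=topo, frames=frames), 0, 1)
        assert out["window_mean"] == pytest.approx(4.0)

    def test_jittered_planted_mean_recovered(self, host_guest):
        topo, base, _ = host_guest
        spec = GeneratorSpec(seed=21, jitter_sigma=0.05, n_frames=2000)
        traj = jitter_trajectory(base, topo, spec)
        out = distance_series(traj, 1, 6)
        truth = float(np.linalg.norm(base.coordinates[1] - base.coordinates[6]))
        sem = out["window_sd"] / np.sqrt(out["n_window"])
        # small positive transverse-jitter bias is below 3 sem at this sigma
        assert abs(out["window_mean"] - truth) < 3.0 * sem + 3e-3


class TestHbondCountProfile:
    def test_counts_decay_with_displacement(self):
        topo, _ = _hbond_system((2.8, 0.0, 0.0))
        frames = []
        disp = np.linspace(0.0, 5.0, 51)
        for k, d in enumerate(disp):
            frames.append(Frame(
                coordinates=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                                      [2.8 + d, 0.0, 0.0]]),
                time=float(k + 1),
            ))
        traj = Trajectory(topology=topo, frames=frames)
        prof = hbond_count_profile(traj, [0], [2], disp, bin_width=0.5)
        assert prof["mean_count"][0] == 1.0
        assert prof["mean_count"][-1] == 0.0
        assert all(b <= a + 1e-12 for a, b in
                   zip(prof["mean_count"], prof["mean_count"][1:]))
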