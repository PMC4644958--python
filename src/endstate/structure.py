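"""Structural analyses: Kabsch superposition, RMSD series, hydrogen bonds,
and distance time series.

Hydrogen bonds follow the geometric criterion used throughout: the
donor–acceptor distance must be strictly less than 3.5 Å and the
donor–H–acceptor angle (measured at the hydrogen) strictly greater than
120°. Hydrogens are assigned to donors via the topology bond table only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Frame, Topology, Trajectory
from .exceptions import StructureError, ConfigurationError

logger = logging.getLogger(__name__)

HBOND_DMAX = 3.5     # Å, donor-acceptor
HBOND_ANGLE_MIN = 120.0  # degrees at the hydrogen


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float   # donor-acceptor, Å
    angle: float      # donor-H-acceptor, degrees


@dataclass
class HBondStats:
    donor_label: str
    acceptor_label: str
    occupancy: float       # % of frames
    mean_distance: float   # Å over frames where the bond is present
    n_present: int


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_subset=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation (det = +1) and translation are computed on
    ``fit_subset`` (default: all rows) and applied to all of ``mobile``.
    Returns (rotation 3×3, translation 3, transformed mobile coordinates);
    the transform is x -> x·Rᵀ + t.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_subset is None:
        fit_subset = np.arange(len(mobile))
    fit = np.asarray(sorted(fit_subset), dtype=int)
    if len(fit) < 3:
        raise StructureError("need at least 3 fit atoms for superposition")
    a = mobile[fit]
    b = reference[fit]
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise StructureError("degenerate (collinear) fit atom set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cb - rot @ ca
    fitted = mobile @ rot.T + trans
    return rot, trans, fitted


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    diff = np.asarray(a) - np.asarray(b)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_series(
    trajectory: Trajectory,
    fit_subset,
    measure_subset=None,
    reference_frame: int = 0,
    window: tuple[float, float] | None = None,
) -> dict:
    """Per-frame RMSD after Kabsch fit, plus mean ± sd over a time window.

    Each frame is superposed onto ``reference_frame`` on ``fit_subset``
    (e.g. the protein backbone); the RMSD is then measured on
    ``measure_subset`` without refitting (defaults to the fit set). The
    window is (start, end] in ps; statistics use the n−1 denominator.
    """
    fit = np.asarray(sorted(fit_subset), dtype=int)
    if len(fit) == 0:
        raise StructureError("empty fit subset")
    measure = fit if measure_subset is None else np.asarray(sorted(measure_subset), dtype=int)
    if len(measure) == 0:
        raise StructureError("empty measure subset")
    ref = trajectory.frames[reference_frame].coordinates
    values = np.empty(trajectory.n_frames)
    times = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory.frames):
        _, _, fitted = kabsch_superpose(frame.coordinates, ref, fit)
        values[k] = rmsd(fitted[measure], ref[measure])
        times[k] = frame.time
    if window is not None:
        mask = (times > window[0]) & (times <= window[1])
        if not mask.any():
            raise ConfigurationError(f"no frames in window {window}")
    else:
        mask = np.ones_like(values, dtype=bool)
    sel = values[mask]
    return {
        "time_ps": times,
        "rmsd": values,
        "window_mean": float(sel.mean()),
        "window_sd": float(sel.std(ddof=1)) if len(sel) > 1 else 0.0,
        "n_window": int(mask.sum()),
    }


def _angle_deg(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at p2 in degrees."""
    u = p1 - p2
    v = p3 - p2
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def find_hbonds(
    frame: Frame,
    topology: Topology,
    donors,
    acceptors,
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
    angle_at: str = "hydrogen",
) -> list[HBond]:
    """All donor–H···acceptor triples passing the strict criteria
    (distance < d_max AND angle > angle_min; equality fails both).

    ``donors`` are heavy donor atoms; their hydrogens come from the bond
    table (donors without bonded hydrogens are skipped with a debug log).
    Donor-acceptor self pairs and acceptors bonded to the donor are ignored.
    The angle vertex defaults to the hydrogen (D–H–A, the common
    convention); ``angle_at="donor"`` measures H–D–A instead.
    """
    if angle_at not in ("hydrogen", "donor"):
        raise ValueError(f"angle_at must be hydrogen|donor, got {angle_at!r}")
    coords = frame.coordinates
    bonded = {tuple(sorted((i, j))) for (i, j, *_r) in topology.bonds}
    out: list[HBond] = []
    for d in sorted(donors):
        hydrogens = topology.bonded_hydrogens(d)
        if not hydrogens:
            logger.debug("donor %s has no bonded hydrogen; skipped",
                         topology.atoms[d].label())
            continue
        for a in sorted(acceptors):
            if a == d or tuple(sorted((a, d))) in bonded:
                continue
            dist = float(np.linalg.norm(coords[d] - coords[a]))
            if not dist < d_max:
                continue
            for h in hydrogens:
                if a == h:
                    continue
                if angle_at == "hydrogen":
                    ang = _angle_deg(coords[d], coords[h], coords[a])
                else:
                    ang = _angle_deg(coords[h], coords[d], coords[a])
                if ang > angle_min:
                    out.append(HBond(donor=d, hydrogen=h, acceptor=a,
                                     distance=dist, angle=ang))
    return out


def hbond_occupancy(
    trajectory: Trajectory,
    donors,
    acceptors,
    frames=None,
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
    angle_at: str = "hydrogen",
) -> list[HBondStats]:
    """Per donor/acceptor pair: occupancy (% of frames where any bonded
    hydrogen satisfies the criteria) and the mean donor-acceptor distance
    over those frames. Pairs never observed are omitted."""
    frame_list = list(trajectory.frames) if frames is None else [
        trajectory.frames[i] for i in frames
    ]
    if not frame_list:
        raise ConfigurationError("no frames for hydrogen-bond occupancy")
    counts: dict[tuple[int, int], int] = {}
    dsum: dict[tuple[int, int], float] = {}
    for frame in frame_list:
        seen = set()
        for hb in find_hbonds(frame, trajectory.topology, donors, acceptors,
                              d_max, angle_min, angle_at):
            key = (hb.donor, hb.acceptor)
            if key in seen:
                continue  # count a pair once per frame, whichever hydrogen
            seen.add(key)
            counts[key] = counts.get(key, 0) + 1
            dsum[key] = dsum.get(key, 0.0) + hb.distance
    n = len(frame_list)
    stats = []
    for (d, a), c in sorted(counts.items()):
        stats.append(
            HBondStats(
                donor_label=trajectory.topology.atoms[d].label(),
                acceptor_label=trajectory.topology.atoms[a].label(),
                occupancy=100.0 * c / n,
                mean_distance=dsum[(d, a)] / c,
                n_present=c,
            )
        )
    return stats


def hbond_count_profile(
    trajectory: Trajectory,
    donors,
    acceptors,
    displacements,
    bin_width: float = 0.5,
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> dict:
    """Average hydrogen-bond count as a function of ligand displacement.

    ``displacements`` gives each frame's pulling displacement (Å); frames
    are binned at ``bin_width`` and the per-frame donor-acceptor bond count
    is averaged within each bin. Used to track bond breaking/forming along
    an unbinding path.
    """
    displacements = np.asarray(displacements, dtype=float)
    if len(displacements) != trajectory.n_frames:
        raise ConfigurationError("one displacement per frame required")
    counts = np.array([
        len({(hb.donor, hb.acceptor) for hb in find_hbonds(
            frame, trajectory.topology, donors, acceptors, d_max, angle_min)})
        for frame in trajectory.frames
    ], dtype=float)
    edges = np.arange(displacements.min(), displacements.max() + bin_width,
                      bin_width)
    if len(edges) < 2:
        edges = np.array([displacements.min(), displacements.min() + bin_width])
    which = np.clip(np.digitize(displacements, edges) - 1, 0, len(edges) - 2)
    centers, means = [], []
    for b in range(len(edges) - 1):
        mask = which == b
        if mask.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(counts[mask].mean())
    return {
        "displacement": np.asarray(centers),
        "mean_count": np.asarray(means),
        "per_frame_count": counts,
    }


def distance_series(
    trajectory: Trajectory,
    atom_a: int,
    atom_b: int,
    window: tuple[float, float] | None = None,
) -> dict:
    """Pair-distance time series and its mean over a (start, end] ps window."""
    times = np.array([f.time for f in trajectory.frames])
    values = np.array([
        float(np.linalg.norm(f.coordinates[atom_a] - f.coordinates[atom_b]))
        for f in trajectory.frames
    ])
    mask = np.ones_like(values, dtype=bool) if window is None else (
        (times > window[0]) & (times <= window[1])
    )
    if not mask.any():
        raise ConfigurationError(f"no frames in window {window}")
    sel = values[mask]
    return {
        "time_ps": times,
        "distance": values,
        "window_mean": float(sel.mean()),
        "window_sd": float(sel.std(ddof=1)) if len(sel) > 1 else 0.0,
        "n_window": int(mask.sum()),
    }
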