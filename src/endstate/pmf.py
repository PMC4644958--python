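"""Potential of mean force from segmented bidirectional steered-work samples.

The primary estimator is the Brownian-dynamics fluctuation–dissipation
theorem (BD-FDT) half-exponential-average ratio

    ΔG(A→r) = −k_B T · ln( ⟨exp(−W_F/2k_BT)⟩_F / ⟨exp(−W_R/2k_BT)⟩_R )

where W_F is the work done steering the ligand forward from the segment
entry A to r, and W_R the work done steering it back from r to A along a
reverse path. For Crooks-consistent Gaussian work distributions with equal
forward/reverse variance the estimator is exact in expectation. Jarzynski
exponential averaging and Bennett's acceptance ratio (BAR) serve as
independent reference estimators; segment profiles are stitched by
cumulative offsetting into a single PMF anchored at zero displacement.

Reverse-path convention: a reverse WorkSample's displacement grid is
measured from the segment's far end B (its own pulling start), with
cumulative work zero there. ``segment_pmf`` re-indexes it so that the work
from r back to A is W_R(L) − W_R(L − r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .exceptions import ConfigurationError, ConvergenceError
from .entropy import KB_KCAL

logger = logging.getLogger(__name__)

DEFAULT_T = 300.0
BOOTSTRAP_RESAMPLES = 200


@dataclass
class WorkSample:
    """Cumulative work along one directed pulling path within one segment.

    ``displacement`` is the within-segment grid in Å measured from the
    path's own entry point (A for forward paths, B for reverse paths);
    ``work`` is the cumulative external work (kcal/mol), zero at entry.
    """

    segment_id: int
    direction: str              # "forward" | "reverse"
    path_id: int
    displacement: np.ndarray    # Å, monotone increasing from 0
    work: np.ndarray            # kcal/mol

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.work = np.asarray(self.work, dtype=float)
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward/reverse, got {self.direction!r}")
        if self.displacement.shape != self.work.shape:
            raise ValueError("displacement and work grids differ in length")
        if np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement grid must be strictly increasing")
        if abs(self.work[0]) > 1e-9 or abs(self.displacement[0]) > 1e-9:
            raise ValueError("work and displacement must start at 0 at segment entry")

    @property
    def length(self) -> float:
        return float(self.displacement[-1])


@dataclass
class SegmentProfile:
    """Within-segment free-energy profile ΔG(r) on the local grid."""

    segment_id: int
    displacement: np.ndarray    # local grid, 0..L
    delta_g: np.ndarray         # kcal/mol, 0 at entry
    stderr: np.ndarray | None = None


@dataclass
class PMFProfile:
    """Stitched free energy vs global displacement, anchored at 0."""

    displacement: np.ndarray
    free_energy: np.ndarray
    stderr: np.ndarray | None = None

    @property
    def endpoint(self) -> float:
        return float(self.free_energy[-1])

    def to_frame(self) -> pd.DataFrame:
        data = {"displacement_A": self.displacement,
                "pmf_kcal_mol": self.free_energy}
        if self.stderr is not None:
            data["stderr_kcal_mol"] = self.stderr
        return pd.DataFrame(data)


# --- estimators -------------------------------------------------------------

def _half_log_mean_exp(works: np.ndarray, beta_half: float) -> float:
    """log ⟨exp(−βW/2)⟩, log-sum-exp stabilized."""
    w = np.asarray(works, dtype=float)
    return float(logsumexp(-beta_half * w) - np.log(len(w)))


def bdfdt(forward_works, reverse_works, T: float = DEFAULT_T) -> float:
    """BD-FDT free-energy estimate (kcal/mol) from bidirectional works."""
    fw = np.asarray(forward_works, dtype=float)
    rw = np.asarray(reverse_works, dtype=float)
    if fw.size == 0 or rw.size == 0:
        raise ConfigurationError("bdfdt needs non-empty forward and reverse works")
    kbt = KB_KCAL * T
    bh = 1.0 / (2.0 * kbt)
    return -kbt * (_half_log_mean_exp(fw, bh) - _half_log_mean_exp(rw, bh))


def jarzynski(works, T: float = DEFAULT_T) -> float:
    """Unidirectional Jarzynski estimate ΔG = −k_BT ln⟨exp(−W/k_BT)⟩."""
    w = np.asarray(works, dtype=float)
    if w.size == 0:
        raise ConfigurationError("jarzynski needs non-empty works")
    kbt = KB_KCAL * T
    return float(-kbt * (logsumexp(-w / kbt) - np.log(w.size)))


def bar(forward_works, reverse_works, T: float = DEFAULT_T,
        tol: float = 1e-8) -> float:
    """Bennett acceptance-ratio estimate from bidirectional works.

    Reverse works follow the same convention as :func:`bdfdt` (work done
    along the reverse path, so the Crooks-conjugate forward value is −W_R).
    Solved by bracketing + Brent root finding to ``tol``.
    """
    fw = np.asarray(forward_works, dtype=float)
    rw = np.asarray(reverse_works, dtype=float)
    if fw.size == 0 or rw.size == 0:
        raise ConfigurationError("bar needs non-empty forward and reverse works")
    kbt = KB_KCAL * T
    m = np.log(fw.size / rw.size)

    def log_sigmoid(x):
        # log(1/(1+e^x)) = -log1p(e^x), stable for both signs
        return np.where(x > 0, -x - np.log1p(np.exp(-x)), -np.log1p(np.exp(x)))

    def residual(dg):
        lf = logsumexp(log_sigmoid(m + (fw - dg) / kbt))
        # reverse term: sigmoid of -(m + (w_conj - dg)/kbt) with w_conj = -W_R
        lr = logsumexp(log_sigmoid(-(m + (-rw - dg) / kbt)))
        return lf - lr

    lo = min(fw.min(), (-rw).min()) - 50.0 * kbt
    hi = max(fw.max(), (-rw).max()) + 50.0 * kbt
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0:
        raise ConvergenceError(
            f"BAR root not bracketed: residuals ({flo:.3g}, {fhi:.3g})"
        )
    return float(brentq(residual, lo, hi, xtol=tol))


# --- segment handling -------------------------------------------------------

def _common_grid(samples: list[WorkSample]) -> np.ndarray:
    grids = [s.displacement for s in samples]
    first = grids[0]
    if all(len(g) == len(first) and np.allclose(g, first) for g in grids[1:]):
        return first
    logger.info("inconsistent grids across paths; resampling linearly")
    lo = max(g[0] for g in grids)
    hi = min(g[-1] for g in grids)
    n = max(len(g) for g in grids)
    return np.linspace(lo, hi, n)


def _segment_matrices(samples: list[WorkSample]) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Common grid plus work matrices for one segment.

    Returns (segment_id, grid, fw, back): fw[p, k] is the forward work
    A→grid[k] of forward path p; back[p, k] is the reverse work
    grid[k]→A of reverse path p, i.e. W_R(L) − W_R(L − grid[k]) in the
    reverse path's own cumulative record.
    """
    fwd = [s for s in samples if s.direction == "forward"]
    rev = [s for s in samples if s.direction == "reverse"]
    if not fwd or not rev:
        raise ConfigurationError("segment needs >=1 forward and >=1 reverse path")
    seg_ids = {s.segment_id for s in samples}
    if len(seg_ids) != 1:
        raise ConfigurationError(f"segment_pmf got multiple segments {seg_ids}")
    grid = _common_grid(fwd + rev)
    length = grid[-1]
    fw = np.vstack([np.interp(grid, s.displacement, s.work) for s in fwd])
    back = np.vstack([
        np.interp(length, s.displacement, s.work)
        - np.interp(length - grid, s.displacement, s.work)
        for s in rev
    ])
    return next(iter(seg_ids)), grid, fw, back


def _bdfdt_columns(fw: np.ndarray, back: np.ndarray, T: float) -> np.ndarray:
    """Column-wise BD-FDT over work matrices (vectorized log-sum-exp)."""
    kbt = KB_KCAL * T
    bh = 1.0 / (2.0 * kbt)
    lf = logsumexp(-bh * fw, axis=0) - np.log(fw.shape[0])
    lr = logsumexp(-bh * back, axis=0) - np.log(back.shape[0])
    return -kbt * (lf - lr)


def segment_pmf(samples: list[WorkSample], T: float = DEFAULT_T,
                estimator: str = "bdfdt") -> SegmentProfile:
    """Within-segment ΔG(r) from that segment's forward and reverse paths.

    At each grid point r the chosen bidirectional estimator combines the
    forward works W_F(A→r) with the reverse works W_R(r→A) (re-indexed from
    the reverse paths' cumulative records). Paths on differing grids are
    linearly resampled onto a common grid.
    """
    seg_id, grid, fw, back = _segment_matrices(samples)
    if estimator == "bdfdt":
        dg = _bdfdt_columns(fw, back, T)
        dg[0] = 0.0
    elif estimator == "bar":
        dg = np.zeros_like(grid)
        for k in range(1, len(grid)):
            dg[k] = bar(fw[:, k], back[:, k], T)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return SegmentProfile(segment_id=seg_id, displacement=grid, delta_g=dg)


def stitch(segments: list[SegmentProfile]) -> PMFProfile:
    """Concatenate contiguous within-segment profiles into one PMF.

    Segments must carry consecutive ids (a gap raises, as does a duplicate);
    each segment's profile is offset so it starts where the previous ended,
    and the stitched profile is anchored at 0 at zero displacement.
    """
    if not segments:
        raise ConfigurationError("no segments to stitch")
    ordered = sorted(segments, key=lambda s: s.segment_id)
    ids = [s.segment_id for s in ordered]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate segment ids: {ids}")
    if any(b - a != 1 for a, b in zip(ids, ids[1:])):
        raise ConfigurationError(f"segment ids not contiguous: {ids}")
    disp = [np.array([0.0])]
    free = [np.array([0.0])]
    err = [np.array([0.0])]
    offset_x = 0.0
    offset_g = 0.0
    any_err = any(s.stderr is not None for s in ordered)
    for s in ordered:
        disp.append(offset_x + s.displacement[1:])
        free.append(offset_g + s.delta_g[1:])
        if any_err:
            e = s.stderr if s.stderr is not None else np.zeros_like(s.delta_g)
            err.append(e[1:])
        offset_x += s.displacement[-1]
        offset_g += s.delta_g[-1]
    return PMFProfile(
        displacement=np.concatenate(disp),
        free_energy=np.concatenate(free),
        stderr=np.concatenate(err) if any_err else None,
    )


# --- samples <-> tidy table -------------------------------------------------

def samples_to_frame(samples: list[WorkSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for x, w in zip(s.displacement, s.work):
            rows.append((s.segment_id, s.direction, s.path_id, x, w))
    return pd.DataFrame(
        rows, columns=["segment", "direction", "path", "displacement_A",
                       "work_kcal_mol"]
    )


def frame_to_samples(df: pd.DataFrame) -> list[WorkSample]:
    out = []
    for (seg, direction, path), grp in df.groupby(
        ["segment", "direction", "path"], sort=True
    ):
        grp = grp.sort_values("displacement_A")
        out.append(
            WorkSample(
                segment_id=int(seg),
                direction=str(direction),
                path_id=int(path),
                displacement=grp["displacement_A"].to_numpy(),
                work=grp["work_kcal_mol"].to_numpy(),
            )
        )
    return out


# --- model / results --------------------------------------------------------

class BidirectionalWorkPMF:
    """PMF model over segmented bidirectional work samples.

    Parameters
    ----------
    samples : list of WorkSample
        Forward and reverse paths for each 1 Å (or other) segment.
    temperature : float
        Kelvin; enters every exponential average.
    """

    def __init__(self, samples: list[WorkSample], temperature: float = DEFAULT_T):
        if not samples:
            raise ConfigurationError("no work samples supplied")
        self.samples = list(samples)
        self.temperature = float(temperature)

    @classmethod
    def from_tsv(cls, path, temperature: float = DEFAULT_T) -> "BidirectionalWorkPMF":
        from .io import read_work_tsv

        return cls(frame_to_samples(read_work_tsv(path)), temperature)

    def _by_segment(self) -> dict[int, list[WorkSample]]:
        by: dict[int, list[WorkSample]] = {}
        for s in self.samples:
            by.setdefault(s.segment_id, []).append(s)
        return by

    def fit(
        self,
        estimator: str = "bdfdt",
        n_bootstrap: int = BOOTSTRAP_RESAMPLES,
        seed: int | None = None,
    ) -> "PMFResults":
        """Estimate per-segment profiles, stitch, and bootstrap uncertainties.

        The bootstrap resamples whole paths within each segment (with
        replacement, per direction), ``n_bootstrap`` times; per-point
        standard errors are the bootstrap standard deviations of the
        stitched profile. Set ``n_bootstrap=0`` to skip.
        """
        by = self._by_segment()
        mats = {k: _segment_matrices(by[k]) for k in sorted(by)}
        profiles = [segment_pmf(by[k], self.temperature, estimator)
                    for k in sorted(by)]
        profile = stitch(profiles)
        boot_sd = None
        endpoint_ci = None
        if n_bootstrap:
            rng = np.random.default_rng(seed)
            reps = np.empty((n_bootstrap, len(profile.free_energy)))
            for b in range(n_bootstrap):
                resampled: list[SegmentProfile] = []
                for k in sorted(by):
                    seg_id, grid, fw, back = mats[k]
                    fw_b = fw[rng.integers(0, fw.shape[0], fw.shape[0])]
                    back_b = back[rng.integers(0, back.shape[0], back.shape[0])]
                    if estimator == "bdfdt":
                        dg = _bdfdt_columns(fw_b, back_b, self.temperature)
                        dg[0] = 0.0
                    else:
                        dg = np.zeros_like(grid)
                        for c in range(1, len(grid)):
                            dg[c] = bar(fw_b[:, c], back_b[:, c],
                                        self.temperature)
                    resampled.append(SegmentProfile(
                        segment_id=seg_id, displacement=grid, delta_g=dg))
                reps[b] = stitch(resampled).free_energy
            boot_sd = reps.std(axis=0, ddof=1)
            lo, hi = np.percentile(reps[:, -1], [2.5, 97.5])
            endpoint_ci = (float(lo), float(hi))
            profile = PMFProfile(
                displacement=profile.displacement,
                free_energy=profile.free_energy,
                stderr=boot_sd,
            )
        return PMFResults(self, estimator, profile, endpoint_ci)


class PMFResults:
    """Fitted PMF: the stitched profile, its uncertainty, and summaries."""

    def __init__(self, model: BidirectionalWorkPMF, estimator: str,
                 profile: PMFProfile, endpoint_ci: tuple[float, float] | None):
        self.model = model
        self.estimator = estimator
        self.profile = profile
        self.endpoint_ci = endpoint_ci

    @property
    def endpoint(self) -> float:
        """PMF at the final displacement, relative to the bound state."""
        return self.profile.endpoint

    def to_frame(self) -> pd.DataFrame:
        return self.profile.to_frame()

    def summary(self) -> str:
        n_seg = len({s.segment_id for s in self.model.samples})
        n_paths = len(self.model.samples)
        lines = [
            "Bidirectional-work PMF",
            f"  estimator      : {self.estimator}",
            f"  temperature    : {self.model.temperature:.1f} K",
            f"  segments       : {n_seg}",
            f"  paths (total)  : {n_paths}",
            f"  displacement   : {self.profile.displacement[-1]:.2f} A",
            f"  PMF endpoint   : {self.endpoint:.3f} kcal/mol",
        ]
        if self.endpoint_ci is not None:
            lines.append(
                f"  endpoint 95% CI: [{self.endpoint_ci[0]:.3f}, "
                f"{self.endpoint_ci[1]:.3f}] kcal/mol (bootstrap)"
            )
        return "\n".join(lines)
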