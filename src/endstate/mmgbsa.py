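"""MM-GBSA pipeline: snapshot selection, per-snapshot evaluation,
aggregation with the standard-error-of-the-mean convention, cross-compound
statistics, and correlation with experiment.

The central object is :class:`BindingFreeEnergyModel`, built from a
trajectory and a receptor/ligand partition; its :meth:`fit` evaluates the
single-trajectory binding-enthalpy components on every selected snapshot,
the normal-mode entropy term on a sparser subset (default every 4th
snapshot, i.e. 125 of 500), and aggregates them into a
:class:`BindingFreeEnergyResults`.

Component vocabulary (kcal/mol): e_ele, e_vdw, g_pol, g_nonpol, and the
composites g_ele_pol = e_ele + g_pol, g_vdw_nonpol = e_vdw + g_nonpol,
h = ΔH, neg_t_ds = −TΔS, g_bind = ΔH + (−TΔS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ComplexPartition, Frame, Trajectory
from .energetics import (
    DEFAULT_BETA,
    DEFAULT_GAMMA,
    SASA_POINTS,
    EnergyBreakdown,
    per_residue_decomposition,
    snapshot_breakdown,
)
from .entropy import KB_KCAL, snapshot_entropy_term
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

COMPONENTS = (
    "e_ele", "e_vdw", "g_pol", "g_nonpol",
    "g_ele_pol", "g_vdw_nonpol", "h",
)
ALL_ROWS = COMPONENTS + ("neg_t_ds", "g_bind")

# component key -> conventional display label
DISPLAY_LABELS = {
    "e_ele": "dE_ele",
    "e_vdw": "dE_vdw",
    "g_pol": "dG_pol",
    "g_nonpol": "dG_nonpol",
    "g_ele_pol": "dG_ele+pol",
    "g_vdw_nonpol": "dG_vdw+nonpol",
    "h": "dH",
    "neg_t_ds": "-TdS",
    "g_bind": "dG_bind",
    "exp": "dG_exp",
}


@dataclass
class AggregateResult:
    """Snapshot-averaged components with standard errors (sd(n−1)/√n)."""

    mean: dict[str, float]
    sem: dict[str, float]
    n_snapshots: int
    n_entropy: int | None = None
    exp: float | None = None

    def __post_init__(self) -> None:
        m = self.mean
        checks = [
            ("g_ele_pol", m.get("e_ele", 0) + m.get("g_pol", 0)),
            ("g_vdw_nonpol", m.get("e_vdw", 0) + m.get("g_nonpol", 0)),
            ("h", sum(m.get(k, 0) for k in ("e_ele", "e_vdw", "g_pol", "g_nonpol"))),
        ]
        for key, expected in checks:
            if key in m and abs(m[key] - expected) > 1e-9:
                raise ValueError(
                    f"composite identity violated for {key}: "
                    f"{m[key]} != {expected}"
                )
        if "g_bind" in m and "neg_t_ds" in m and "h" in m:
            if abs(m["g_bind"] - (m["h"] + m["neg_t_ds"])) > 1e-9:
                raise ValueError("g_bind != h + (-TdS)")

    @property
    def g_bind(self) -> float:
        return self.mean["g_bind"]


def select_snapshots(
    trajectory: Trajectory,
    window_ns: tuple[float, float],
    interval_ps: float,
    expected_n: int | None = None,
) -> list[int]:
    """Indices of frames taken evenly at ``interval_ps`` within
    ``window_ns`` = (start, end] (e.g. the last 5 ns at 10 ps -> 500).

    Raises ConfigurationError when the window is not covered, the span is
    not an integer number of intervals, or the count mismatches
    ``expected_n``.
    """
    start_ps = window_ns[0] * 1000.0
    end_ps = window_ns[1] * 1000.0
    span = end_ps - start_ps
    if span <= 0:
        raise ConfigurationError(f"empty snapshot window {window_ns}")
    n = span / interval_ps
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(
            f"window span {span} ps is not a multiple of interval {interval_ps} ps"
        )
    n = int(round(n))
    times = np.array([f.time for f in trajectory.frames])
    targets = start_ps + interval_ps * np.arange(1, n + 1)
    if targets[-1] > times[-1] + 1e-9 or targets[0] < times[0] - 1e-9:
        raise ConfigurationError(
            f"trajectory ({times[0]}..{times[-1]} ps) does not cover "
            f"window {window_ns} ns"
        )
    idx = []
    for t in targets:
        k = int(np.argmin(np.abs(times - t)))
        if abs(times[k] - t) > 1e-6:
            raise ConfigurationError(f"no frame at {t} ps (nearest {times[k]} ps)")
        idx.append(k)
    if expected_n is not None and len(idx) != expected_n:
        raise ConfigurationError(
            f"selected {len(idx)} snapshots, expected {expected_n}"
        )
    return idx


def aggregate(
    breakdowns: list[EnergyBreakdown],
    entropy_terms: list[float] | None = None,
) -> AggregateResult:
    """Means and standard errors (σ = sd(n−1)/√n) over snapshots.

    ``entropy_terms`` is the per-snapshot −TΔS list (possibly shorter than
    the breakdown list, per the sparser entropy protocol). g_bind is the
    ΔH mean plus the −TΔS mean.
    """
    if not breakdowns:
        raise ConfigurationError("no breakdowns to aggregate")
    if len(breakdowns) < 2:
        raise ConfigurationError("need >=2 snapshots for a standard error")
    table = pd.DataFrame([b.as_dict() for b in breakdowns])
    mean = {k: float(table[k].mean()) for k in COMPONENTS}
    sem = {
        k: float(table[k].std(ddof=1) / np.sqrt(len(table))) for k in COMPONENTS
    }
    n_entropy = None
    if entropy_terms is not None and len(entropy_terms) > 0:
        ent = np.asarray(entropy_terms, dtype=float)
        mean["neg_t_ds"] = float(ent.mean())
        sem["neg_t_ds"] = (
            float(ent.std(ddof=1) / np.sqrt(len(ent))) if len(ent) > 1 else 0.0
        )
        mean["g_bind"] = mean["h"] + mean["neg_t_ds"]
        sem["g_bind"] = float(np.hypot(sem["h"], sem["neg_t_ds"]))
        n_entropy = len(ent)
    return AggregateResult(
        mean=mean, sem=sem, n_snapshots=len(breakdowns), n_entropy=n_entropy
    )


class CompoundTable:
    """Ordered map of compound label -> AggregateResult (plus optional
    experimental ΔG stored on each result)."""

    def __init__(self, results: dict[str, AggregateResult] | None = None):
        self.results: dict[str, AggregateResult] = dict(results or {})
        if len(set(self.results)) != len(self.results):
            raise ValueError("duplicate compound labels")

    def __getitem__(self, label: str) -> AggregateResult:
        return self.results[label]

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    @property
    def labels(self) -> list[str]:
        return list(self.results)

    def add(self, label: str, result: AggregateResult) -> None:
        if label in self.results:
            raise ValueError(f"duplicate compound label {label!r}")
        self.results[label] = result

    def component_values(self, component: str, compounds=None) -> np.ndarray:
        labels = compounds if compounds is not None else self.labels
        return np.array([self.results[c].mean[component] for c in labels])

    def exp_values(self, compounds=None) -> np.ndarray:
        labels = compounds if compounds is not None else self.labels
        out = []
        for c in labels:
            if self.results[c].exp is None:
                raise ConfigurationError(f"compound {c} has no experimental value")
            out.append(self.results[c].exp)
        return np.array(out)

    def to_frame(self) -> pd.DataFrame:
        """Rows = components, columns = (compound, mean|sem)."""
        cols = {}
        for label, res in self.results.items():
            cols[(label, "mean")] = {k: res.mean.get(k) for k in ALL_ROWS}
            cols[(label, "sem")] = {k: res.sem.get(k) for k in ALL_ROWS}
            cols[(label, "mean")]["exp"] = res.exp
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        return df.reindex(list(ALL_ROWS) + ["exp"])


def summarize_across_compounds(
    table: CompoundTable, component: str, compounds=None
) -> tuple[float, float]:
    """Mean and sd (n−1 denominator) of a component across compounds."""
    if len(table) < 2:
        raise ConfigurationError("need >=2 compounds to summarize")
    vals = table.component_values(component, compounds)
    if len(vals) < 2:
        raise ConfigurationError("need >=2 compounds to summarize")
    return float(vals.mean()), float(vals.std(ddof=1))


def correlate(x, y, mode: str = "signed") -> float:
    """Pearson product-moment correlation of two per-compound vectors;
    ``mode="absolute"`` returns |r|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ConfigurationError("correlate needs equal-length vectors, n >= 3")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ConfigurationError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if mode == "absolute":
        return abs(r)
    if mode != "signed":
        raise ValueError(f"mode must be signed|absolute, got {mode!r}")
    return r


def g_exp_from_kd(kd: float, T: float = 300.0) -> float:
    """Experimental ΔG = RT ln(Kd) in kcal/mol (Kd in M)."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return KB_KCAL * T * float(np.log(kd))


# --- model / results --------------------------------------------------------

class BindingFreeEnergyModel:
    """Single-trajectory MM-GBSA model for one complex.

    Parameters
    ----------
    trajectory : Trajectory
        Fully parameterized complex trajectory (solvent already stripped).
    partition : ComplexPartition
        Receptor/ligand atom-index split.
    window_ns, interval_ps :
        Snapshot protocol; ``None`` uses every frame.
    entropy_every : int
        Normal-mode entropy is evaluated on every k-th selected snapshot
        (4 turns 500 enthalpy snapshots into 125 entropy snapshots).
    sasa_dither : bool
        Rotate the SASA quadrature point set by a deterministic per-snapshot
        random orientation (fixed internal seed). Orientation-averaged
        Shrake–Rupley quadrature is exactly unbiased, so dithering removes
        the fixed-grid bias from ensemble averages while keeping the fit
        fully reproducible.
    """

    _DITHER_SEED = 1163


    def __init__(
        self,
        trajectory: Trajectory,
        partition: ComplexPartition,
        temperature: float = 300.0,
        window_ns: tuple[float, float] | None = None,
        interval_ps: float | None = None,
        expected_n: int | None = None,
        entropy_every: int = 4,
        compute_entropy: bool = True,
        gamma: float = DEFAULT_GAMMA,
        beta: float = DEFAULT_BETA,
        sasa_points: int = SASA_POINTS,
        sasa_dither: bool = True,
    ):
        self.trajectory = trajectory
        self.partition = partition
        self.temperature = float(temperature)
        self.window_ns = window_ns
        self.interval_ps = interval_ps
        self.expected_n = expected_n
        self.entropy_every = int(entropy_every)
        self.compute_entropy = compute_entropy
        self.gamma = gamma
        self.beta = beta
        self.sasa_points = sasa_points
        self.sasa_dither = sasa_dither

    @classmethod
    def from_files(
        cls,
        traj_path,
        topology_path,
        ligand_selection: str,
        **kwargs,
    ) -> "BindingFreeEnergyModel":
        """Build from a multi-model PDB plus topology sidecar; the ligand is
        given as a selection expression, the receptor is everything else."""
        from .io import merge_topology, read_pdb
        from .selection import select

        structure = read_pdb(traj_path, model_policy="all")
        traj = merge_topology(structure, topology_path)
        lig = select(traj.topology, ligand_selection, frame=traj.frames[0])
        if not lig:
            raise ConfigurationError(
                f"ligand selection {ligand_selection!r} matched no atoms"
            )
        rec = frozenset(range(traj.topology.n_atoms)) - lig
        return cls(traj, ComplexPartition(receptor=rec, ligand=lig), **kwargs)

    def snapshot_indices(self) -> list[int]:
        if self.window_ns is None or self.interval_ps is None:
            return list(range(self.trajectory.n_frames))
        return select_snapshots(
            self.trajectory, self.window_ns, self.interval_ps, self.expected_n
        )

    def sasa_orientations(self, n: int) -> list[np.ndarray] | None:
        """The deterministic per-snapshot quadrature orientations."""
        if not self.sasa_dither:
            return None
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(self._DITHER_SEED)
        quats = rng.normal(size=(n, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        return [Rotation.from_quat(q).as_matrix() for q in quats]

    def fit(self) -> "BindingFreeEnergyResults":
        idx = self.snapshot_indices()
        logger.info("evaluating %d snapshots", len(idx))
        orients = self.sasa_orientations(len(idx))
        breakdowns = [
            snapshot_breakdown(
                self.trajectory.frames[i],
                self.trajectory.topology,
                self.partition,
                gamma=self.gamma,
                beta=self.beta,
                n_points=self.sasa_points,
                sasa_orientation=None if orients is None else orients[k],
            )
            for k, i in enumerate(idx)
        ]
        entropy_terms: list[float] | None = None
        entropy_idx: list[int] = []
        if self.compute_entropy:
            entropy_idx = idx[:: self.entropy_every]
            logger.info("normal-mode entropy on %d snapshots", len(entropy_idx))
            entropy_terms = [
                snapshot_entropy_term(
                    self.trajectory.frames[i],
                    self.trajectory.topology,
                    self.partition,
                    T=self.temperature,
                )
                for i in entropy_idx
            ]
        agg = aggregate(breakdowns, entropy_terms)
        return BindingFreeEnergyResults(
            self, agg, breakdowns, idx, entropy_terms, entropy_idx
        )


class BindingFreeEnergyResults:
    """Fitted MM-GBSA results: aggregate, per-snapshot table, summaries."""

    def __init__(self, model, aggregate_result, breakdowns, snapshot_indices,
                 entropy_terms, entropy_indices):
        self.model = model
        self.aggregate = aggregate_result
        self.breakdowns = breakdowns
        self.snapshot_indices = snapshot_indices
        self.entropy_terms = entropy_terms
        self.entropy_indices = entropy_indices

    @property
    def g_bind(self) -> float | None:
        return self.aggregate.mean.get("g_bind")

    def per_snapshot_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([b.as_dict() for b in self.breakdowns])
        df.insert(0, "frame", self.snapshot_indices)
        return df

    def residue_table(self, max_frames: int = 25) -> pd.DataFrame:
        """Per-residue contributions averaged over (a thinned subset of)
        the fitted snapshots."""
        idx = self.snapshot_indices
        step = max(1, len(idx) // max_frames)
        rows: dict[str, list[dict]] = {}
        for i in idx[::step]:
            for contrib in per_residue_decomposition(
                self.model.trajectory.frames[i],
                self.model.trajectory.topology,
                self.model.partition,
                gamma=self.model.gamma,
                n_points=self.model.sasa_points,
            ):
                rows.setdefault(contrib.label, []).append(
                    {
                        "e_ele": contrib.e_ele,
                        "e_vdw": contrib.e_vdw,
                        "g_pol": contrib.g_pol,
                        "g_nonpol": contrib.g_nonpol,
                        "total": contrib.total,
                    }
                )
        out = {
            label: pd.DataFrame(vals).mean() for label, vals in rows.items()
        }
        return pd.DataFrame(out).T

    def summary(self) -> str:
        agg = self.aggregate
        lines = [
            "MM-GBSA binding free energy (single-trajectory)",
            f"  snapshots          : {agg.n_snapshots}"
            + (f" (entropy on {agg.n_entropy})" if agg.n_entropy else ""),
            f"  temperature        : {self.model.temperature:.1f} K",
            "",
            f"  {'component':<16s}{'mean':>10s}{'sem':>10s}   kcal/mol",
        ]
        for key in ALL_ROWS:
            if key not in agg.mean:
                continue
            lines.append(
                f"  {DISPLAY_LABELS[key]:<16s}{agg.mean[key]:>10.2f}"
                f"{agg.sem.get(key, float('nan')):>10.2f}"
            )
        return "\n".join(lines)
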