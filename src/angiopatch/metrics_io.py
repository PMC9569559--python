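"""Vessel measurement, growth curves, replicate summaries and file I/O.

Measurement mirrors the histology protocol: under the microscope a "new
blood vessel" is the whole branched structure sprouting from one point on
an arteriole, and its length is the straight-line distance from that
sprouting point to the structure's farthest point.  Accordingly a vessel
here is an initial-sprout *lineage* — the founding tip plus every branch
descended from it — and its extent is the distance from the lineage
origin to the farthest cell-centre any member ever visited, converted to
millimetres with the physical size of the unit domain (the
patch-to-vessel distance, 3 mm by default).  The total arc length of the
lineage tree (path) is reported alongside; meandering and branching make
path exceed extent, which is itself a signature of the pathological
growth the model produces.  Per-branch measurement (each tip its own
vessel) remains available for inspecting individual branches.

Also houses the synthetic concentration-series generator used to exercise
the kinetic fitting routine: a damped sinusoid sampled at the in vivo
design (1, 3, 6, 12, 18 h, then daily to day 7), three replicates per time
point, multiplicative Gaussian noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hybrid_sim import SimConfig, SimulationResult, TipAgent
from .vegf_field import ConcentrationSeries, VegfParams, temporal_factor

__all__ = [
    "VesselMeasurement",
    "GrowthCurve",
    "IN_VIVO_TIMES_DAYS",
    "vessel_extent",
    "measure_all",
    "final_vessel_lengths",
    "growth_curve",
    "summarize_replicates",
    "generate_fixture_series",
    "write_run",
    "read_trajectories",
    "measurements_from_trajectories",
]

#: Sampling design of the in vivo concentration series:
#: 1, 3, 6, 12, 18 hours, then days 1..7.
IN_VIVO_TIMES_DAYS = tuple(h / 24.0 for h in (1, 3, 6, 12, 18)) + tuple(
    float(d) for d in range(1, 8))


@dataclass(frozen=True)
class VesselMeasurement:
    """Extent and path length of one vessel at one day, in mm."""

    vessel_id: int
    day: float
    extent_mm: float
    path_mm: float

    def __post_init__(self) -> None:
        if self.extent_mm < 0 or self.path_mm < 0:
            raise ValueError("lengths must be nonnegative")
        if self.extent_mm > self.path_mm + 1e-9:
            raise ValueError("extent cannot exceed path length")


@dataclass
class GrowthCurve:
    """Mean vessel extent per day with dispersion and vessel count."""

    days: np.ndarray
    mean_mm: np.ndarray
    sd_mm: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "mean_mm": self.mean_mm,
                             "sd_mm": self.sd_mm, "n": self.n})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _traj_points(trajectory, h: float, day: float) -> np.ndarray:
    """Physical cell-centre coordinates of trajectory entries up to ``day``."""
    pts = [((i + 0.5) * h, (j + 0.5) * h)
           for t, i, j in trajectory if t <= day + 1e-12]
    return np.asarray(pts, dtype=float)


def vessel_extent(trajectory, h: float, length_scale_mm: float,
                  day: float = math.inf, vessel_id: int = 0) -> VesselMeasurement:
    """Measure one trajectory at a given day.

    extent = max distance of any visited cell centre from the origin,
    path = total arc length of the recorded moves; both scaled to mm.
    ``trajectory`` is a sequence of (time, i, j) site records.
    """
    if not trajectory:
        raise ValueError("trajectory must be nonempty")
    pts = _traj_points(trajectory, h, day)
    if pts.size == 0:
        raise ValueError(f"trajectory starts after day {day}")
    deltas = np.diff(pts, axis=0)
    path = float(np.hypot(deltas[:, 0], deltas[:, 1]).sum()) if len(pts) > 1 else 0.0
    extent = float(np.hypot(*(pts - pts[0]).T).max())
    day_out = day if math.isfinite(day) else float(trajectory[-1][0])
    return VesselMeasurement(vessel_id=vessel_id, day=day_out,
                             extent_mm=extent * length_scale_mm,
                             path_mm=path * length_scale_mm)


def lineage_roots(tips: list[TipAgent]) -> dict[int, int]:
    """Map each tip id to the id of its founding (parentless) ancestor."""
    parent = {tip.id: tip.parent_id for tip in tips}
    root: dict[int, int] = {}

    def find(i: int) -> int:
        chain = []
        while parent[i] is not None and i not in root:
            chain.append(i)
            i = parent[i]
        r = root.get(i, i)
        for c in chain:
            root[c] = r
        root[i] = r
        return r

    for tip in tips:
        find(tip.id)
    return root


def measure_all(tips: list[TipAgent], config: SimConfig, day: float,
                per_branch: bool = False) -> list[VesselMeasurement]:
    """Measurements for every vessel already born by ``day``.

    By default vessels are initial-sprout lineages (the histology-protocol
    reading); with ``per_branch=True`` each tip is its own vessel measured
    from its branch point.
    """
    h = 1.0 / config.n_cells
    if per_branch:
        return [vessel_extent(tip.trajectory, h, config.length_scale_mm,
                              day=day, vessel_id=tip.id)
                for tip in tips if tip.birth_time <= day + 1e-12]
    roots = lineage_roots(tips)
    by_id = {tip.id: tip for tip in tips}
    out = []
    for root_id in sorted({roots[t.id] for t in tips
                           if by_id[roots[t.id]].birth_time <= day + 1e-12}):
        members = [t for t in tips
                   if roots[t.id] == root_id and t.birth_time <= day + 1e-12]
        origin = np.asarray(_traj_points(by_id[root_id].trajectory, h, day)[0])
        extent = 0.0
        path = 0.0
        for t in members:
            pts = _traj_points(t.trajectory, h, day)
            if pts.size == 0:
                continue
            extent = max(extent, float(np.hypot(*(pts - origin).T).max()))
            if len(pts) > 1:
                d = np.diff(pts, axis=0)
                path += float(np.hypot(d[:, 0], d[:, 1]).sum())
        out.append(VesselMeasurement(
            vessel_id=root_id, day=day,
            extent_mm=extent * config.length_scale_mm,
            path_mm=path * config.length_scale_mm))
    return out


def final_vessel_lengths(result: SimulationResult,
                         per_branch: bool = False) -> np.ndarray:
    """Final extents (mm) of all vessels at the end of the run."""
    ms = measure_all(result.tips, result.config, day=result.config.horizon,
                     per_branch=per_branch)
    return np.array([m.extent_mm for m in ms])


def growth_curve(result: SimulationResult, config: SimConfig | None = None) -> GrowthCurve:
    """Per-day mean vessel extent over all vessels existing by each day.

    Requires integer-day snapshots in the result.  Because the extent is a
    running maximum, each vessel's curve — and hence the per-day mean over
    a fixed cohort — never decreases between days in which no new vessel
    is born.
    """
    config = config or result.config
    days = sorted({s.t for s in result.snapshots if float(s.t).is_integer()})
    if not days:
        raise ValueError("result holds no integer-day snapshots")
    mean, sd, count = [], [], []
    for day in days:
        extents = [m.extent_mm for m in measure_all(result.tips, config, day)]
        arr = np.asarray(extents, dtype=float)
        mean.append(arr.mean() if arr.size else 0.0)
        sd.append(arr.std(ddof=1) if arr.size > 1 else 0.0)
        count.append(arr.size)
    return GrowthCurve(days=np.asarray(days, dtype=float),
                       mean_mm=np.asarray(mean), sd_mm=np.asarray(sd),
                       n=np.asarray(count, dtype=int))


def summarize_replicates(values) -> tuple[float, float, int]:
    """Sample mean, sample SD (n-1 denominator) and n of pooled lengths."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values for a sample SD")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def generate_fixture_series(params: VegfParams,
                            times=IN_VIVO_TIMES_DAYS,
                            noise_level: float = 0.05,
                            replicates: int = 3,
                            seed: int = 0) -> ConcentrationSeries:
    """Synthetic concentration series emulating the in vivo sampling design.

    Values follow the damped-sinusoid temporal factor at the given times,
    replicated and perturbed with multiplicative Gaussian noise of the
    given relative level.  Deterministic for a fixed seed.
    """
    if noise_level < 0:
        raise ValueError("noise level must be nonnegative")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    t = np.tile(np.asarray(times, dtype=float), replicates)
    rep = np.repeat(np.arange(replicates), len(times))
    clean = temporal_factor(t, params)
    noisy = clean * (1.0 + noise_level * rng.standard_normal(t.size))
    return ConcentrationSeries(times=t, values=noisy, replicate=rep)


# ---------------------------------------------------------------------------
# Run directory I/O
# ---------------------------------------------------------------------------

def _trajectories_frame(result: SimulationResult) -> pd.DataFrame:
    rows = []
    for tip in result.tips:
        parent = -1 if tip.parent_id is None else tip.parent_id
        for step, (t, i, j) in enumerate(tip.trajectory):
            rows.append((tip.id, step, t, i + 1, j + 1, tip.state, parent))
    return pd.DataFrame(rows, columns=["tip_id", "step", "t", "i", "j",
                                       "state", "parent_id"])


def _events_frame(result: SimulationResult) -> pd.DataFrame:
    rows = []
    for tip in result.tips:
        if tip.parent_id is not None:
            rows.append(("branching", tip.id, tip.parent_id, tip.birth_time))
        if tip.state == "anastomosed":
            rows.append(("anastomosis", tip.id, None, tip.trajectory[-1][0]))
        if tip.arrival_time is not None:
            rows.append(("arrival", tip.id, None, tip.arrival_time))
    return pd.DataFrame(rows, columns=["event", "tip_id", "parent_id", "t"])


def write_run(result: SimulationResult, out_dir: str | Path) -> Path:
    """Write trajectories, events, per-day measurements and a config echo.

    Lattice sites in the CSVs are 1-based (i along x, origin lower-left).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _trajectories_frame(result).to_csv(out / "trajectories.csv", index=False)
    _events_frame(result).to_csv(out / "events.csv", index=False)
    config = result.config
    rows = []
    for day in sorted({s.t for s in result.snapshots if float(s.t).is_integer()}):
        rows.extend(measure_all(result.tips, config, day))
    pd.DataFrame([(m.vessel_id, m.day, m.extent_mm, m.path_mm) for m in rows],
                 columns=["vessel_id", "day", "extent_mm", "path_mm"]
                 ).to_csv(out / "measurements.csv", index=False)
    growth_curve(result).to_csv(out / "growth_curve.csv")
    (out / "config.json").write_text(
        json.dumps({"config": config.to_dict(), "seed": result.seed,
                    "n_steps": result.n_steps}, indent=2) + "\n")
    return out


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a trajectories.csv written by :func:`write_run`."""
    return pd.read_csv(Path(path))


def measurements_from_trajectories(df: pd.DataFrame, n_cells: int,
                                   length_scale_mm: float,
                                   day: float = math.inf,
                                   per_branch: bool = False) -> list[VesselMeasurement]:
    """Recompute vessel measurements from a trajectories table.

    Bit-exact round trip with the in-memory measurements: the CSV stores
    the same (time, site) records and parent links the in-memory tips hold.
    """
    tips = []
    for tip_id, group in df.groupby("tip_id"):
        group = group.sort_values("step")
        traj = [(float(t), int(i) - 1, int(j) - 1)
                for t, i, j in zip(group["t"], group["i"], group["j"])]
        parent = None
        if "parent_id" in group.columns:
            p = int(group["parent_id"].iloc[0])
            parent = None if p < 0 else p
        tips.append(TipAgent(id=int(tip_id), site=traj[-1][1:],
                             birth_time=traj[0][0], trajectory=traj,
                             parent_id=parent,
                             state=str(group["state"].iloc[0])))
    cfg = SimConfig(n_cells=n_cells, length_scale_mm=length_scale_mm, n_tips=1)
    if not math.isfinite(day):
        day = max(t.trajectory[-1][0] for t in tips)
    return measure_all(tips, cfg, day=day, per_branch=per_branch)
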