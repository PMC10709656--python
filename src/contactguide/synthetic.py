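"""Synthetic nucleus tracks and cell outlines with the study's data structure.

The raw recordings behind the analysis are not public, so this module
generates cohorts that carry the same statistical signatures the pipeline
assumes: nucleus positions sampled every 10 min for >= 10 h, mean path
speeds in the 0.25-0.4 µm/min range, headings that concentrate around the
groove axis as guidance strengthens, and outline orientation/elongation
distributions that sharpen with groove depth.  Ground truth is always
available, so parameter-recovery tests need no bookkeeping.

Walk model
----------
Let phi_t be the heading.  The deviation ``delta = phi - psi`` from the
nearer of the two groove-axis directions (psi = +y or -y) follows an AR(1):

    delta' = rho * delta + s * eps,     eps ~ N(0, 1)

with ``rho = persistence`` and stationary sd ``s / sqrt(1 - rho^2)`` set to
``1 / (2 sqrt(axis_bias))`` — the small-angle match to an axial von Mises
with concentration ``axis_bias`` on the doubled angle.  At ``axis_bias = 0``
the reversion vanishes and the heading performs a wrapped-normal random walk
with ``E[cos(increment)] = persistence``, so the step-to-step velocity
autocorrelation equals the persistence parameter.  ``persistence = 0`` draws
independent headings (exact doubled-angle von Mises).  Both +y and -y are
equally likely, which produces the back-and-forth motion seen along grooves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .conditions import (
    CONTROL,
    DEFAULT_DEPTHS_NM,
    SubstrateCondition,
    format_condition_label,
)

_TWO31 = 2**31


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort generator.

    The defaults are the study conditions: 10-min sampling over 10 h,
    cohorts of 30 cells, speeds around 0.3 µm/min, and an isotropic
    (control-like) regime — ``axis_bias = 0`` and
    ``outline_orientation_concentration = 0`` mean no directional guidance.
    """

    n_cells: int = 30
    duration_min: float = 600.0
    dt_min: float = 10.0
    base_speed_um_per_min: float = 0.3
    speed_sd: float = 0.05
    persistence: float = 0.5
    axis_bias: float = 0.0
    outline_mean_aspect: float = 4.8
    outline_aspect_sd: float = 3.0
    outline_orientation_concentration: float = 0.0
    outline_area_mean_um2: float = 2400.0
    outline_area_sd_um2: float = 600.0
    outline_noise: float = 0.03
    outline_vertices: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.duration_min <= 0 or self.dt_min <= 0:
            raise ValueError("duration_min and dt_min must be positive")
        if self.base_speed_um_per_min <= 0:
            raise ValueError("base_speed_um_per_min must be positive")
        if self.speed_sd < 0 or self.axis_bias < 0:
            raise ValueError("speed_sd and axis_bias must be nonnegative")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must lie in [0, 1)")
        if self.outline_mean_aspect < 1:
            raise ValueError("outline_mean_aspect must be >= 1")
        if self.outline_orientation_concentration < 0:
            raise ValueError("outline_orientation_concentration must be nonnegative")
        if self.outline_vertices < 3:
            raise ValueError("outline_vertices must be >= 3")


@dataclass
class Trajectory:
    """One cell's nucleus track on a regular time grid (µm, minutes)."""

    cell_id: str
    times_min: np.ndarray
    positions_um: np.ndarray
    condition: SubstrateCondition
    on_pattern: bool = True

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.times_min.ndim != 1 or len(self.times_min) < 2:
            raise ValueError(f"track {self.cell_id}: need >= 2 samples")
        if self.positions_um.shape != (len(self.times_min), 2):
            raise ValueError(f"track {self.cell_id}: positions must be (n, 2)")
        if not np.all(np.isfinite(self.positions_um)):
            raise ValueError(f"track {self.cell_id}: non-finite positions")
        steps = np.diff(self.times_min)
        if np.any(steps <= 0):
            raise ValueError(f"track {self.cell_id}: times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-6):
            raise ValueError(f"track {self.cell_id}: irregular sampling interval")

    @property
    def dt_min(self) -> float:
        return float(self.times_min[1] - self.times_min[0])

    @property
    def duration_min(self) -> float:
        return float(self.times_min[-1] - self.times_min[0])


@dataclass
class CellOutline:
    """Closed planar polygon of one traced cell with its exclusion flags."""

    cell_id: str
    vertices_um: np.ndarray
    condition: SubstrateCondition
    flag_mitosis: bool = False
    flag_spans_flat_and_pattern: bool = False

    def __post_init__(self) -> None:
        self.vertices_um = np.asarray(self.vertices_um, dtype=float)
        if self.vertices_um.ndim != 2 or self.vertices_um.shape[0] < 3 or self.vertices_um.shape[1] != 2:
            raise ValueError(f"outline {self.cell_id}: need >= 3 planar vertices")


def _heading_stationary_sd(axis_bias: float) -> float:
    # small-angle sd of an axial von Mises with concentration kappa on 2*delta
    return 1.0 / (2.0 * math.sqrt(axis_bias))


def _draw_axial_deviation(rng: np.random.Generator, kappa: float, size: int) -> np.ndarray:
    """Deviations from the axis under an axial (period-pi) von Mises law."""
    if kappa == 0:
        return rng.uniform(-np.pi / 2, np.pi / 2, size=size)
    return rng.vonmises(0.0, kappa, size=size) / 2.0


def _nearest_axis(phi: float, axis_rad: float) -> float:
    """The nearer of the two (anti)parallel axis directions to heading phi."""
    d = (phi - axis_rad + np.pi) % (2 * np.pi) - np.pi
    return axis_rad if abs(d) <= np.pi / 2 else axis_rad + np.pi


def _simulate_headings(
    rng: np.random.Generator, n_steps: int, persistence: float, axis_bias: float, axis_rad: float
) -> np.ndarray:
    psi0 = axis_rad if rng.random() < 0.5 else axis_rad + np.pi
    if persistence == 0.0:
        psi = np.where(rng.random(n_steps) < 0.5, axis_rad, axis_rad + np.pi)
        return psi + _draw_axial_deviation(rng, axis_bias, n_steps)
    if axis_bias == 0.0:
        # wrapped-normal heading random walk, E[cos(increment)] = persistence
        sd = math.sqrt(-2.0 * math.log(persistence))
        phi0 = psi0 + rng.uniform(-np.pi / 2, np.pi / 2)
        return phi0 + np.concatenate(([0.0], np.cumsum(rng.normal(0.0, sd, n_steps - 1))))
    sd_st = _heading_stationary_sd(axis_bias)
    noise_sd = sd_st * math.sqrt(1.0 - persistence**2)
    phi = np.empty(n_steps)
    phi[0] = psi0 + rng.normal(0.0, sd_st)
    eps = rng.normal(0.0, noise_sd, n_steps - 1)
    for i in range(1, n_steps):
        psi = _nearest_axis(phi[i - 1], axis_rad)
        delta = (phi[i - 1] - psi + np.pi) % (2 * np.pi) - np.pi
        phi[i] = psi + persistence * delta + eps[i - 1]
    return phi


def _gamma_mean_sd(rng: np.random.Generator, mean: float, sd: float, size=None):
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    shape = (mean / sd) ** 2
    return rng.gamma(shape, mean / shape, size=size)


#: shape of the per-step length jitter (gamma, mean 1); CV = 1/4
_STEP_JITTER_SHAPE = 16.0


def simulate_trajectories(
    params: SimulationParams, condition: SubstrateCondition = CONTROL
) -> list[Trajectory]:
    """Simulate a cohort of nucleus tracks under the heading model above.

    Step lengths are gamma-distributed with a per-cell mean speed drawn
    around ``base_speed_um_per_min`` (sd ``speed_sd``), so the cohort mean
    path speed is calibrated to the base speed.  Identical params give
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.duration_min / params.dt_min))
    if n_steps < 1:
        raise ValueError("duration_min must cover at least one sampling interval")
    times = np.arange(n_steps + 1) * params.dt_min
    axis_rad = math.radians(condition.groove_axis_deg)
    tracks = []
    for i in range(params.n_cells):
        speed = float(
            _gamma_mean_sd(rng, params.base_speed_um_per_min, params.speed_sd)
        )
        lengths = speed * params.dt_min * rng.gamma(
            _STEP_JITTER_SHAPE, 1.0 / _STEP_JITTER_SHAPE, size=n_steps
        )
        phi = _simulate_headings(rng, n_steps, params.persistence, params.axis_bias, axis_rad)
        steps = lengths[:, None] * np.column_stack([np.cos(phi), np.sin(phi)])
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tracks.append(
            Trajectory(
                cell_id=f"{format_condition_label(condition)}_c{i:03d}",
                times_min=times,
                positions_um=pos,
                condition=condition,
            )
        )
    return tracks


def make_ellipse_outline(
    area_um2: float,
    aspect: float,
    orientation_deg: float,
    n_vertices: int = 64,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
    cell_id: str = "ellipse",
    condition: SubstrateCondition = CONTROL,
    center_um=(0.0, 0.0),
) -> CellOutline:
    """A discretized ellipse polygon of given area, aspect ratio and
    major-axis orientation, with optional multiplicative radial noise.

    The polygon is star-shaped about its centre, so small radial noise
    cannot introduce self-intersections.
    """
    if area_um2 <= 0 or aspect < 1:
        raise ValueError("area must be positive and aspect >= 1")
    b = math.sqrt(area_um2 / (math.pi * aspect))  # semi-minor
    a = aspect * b
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        r = rng.normal(1.0, noise, size=n_vertices)
        r = np.clip(r, 0.2, None)
        x, y = x * r, y * r
    th = math.radians(orientation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    verts = np.column_stack([x, y]) @ rot.T + np.asarray(center_um, dtype=float)
    return CellOutline(cell_id=cell_id, vertices_um=verts, condition=condition)


def simulate_outlines(
    params: SimulationParams, condition: SubstrateCondition = CONTROL
) -> list[CellOutline]:
    """Simulate traced cell outlines as noisy discretized ellipses.

    Orientation is axial (period pi) about the groove axis with
    concentration ``outline_orientation_concentration``; aspect ratios are
    gamma-distributed above 1 with mean ``outline_mean_aspect``; areas are
    gamma-distributed with the configured mean/sd.
    """
    rng = np.random.default_rng(params.seed + 1)
    outlines = []
    for i in range(params.n_cells):
        area = float(_gamma_mean_sd(rng, params.outline_area_mean_um2, params.outline_area_sd_um2))
        excess = params.outline_mean_aspect - 1.0
        if excess > 0 and params.outline_aspect_sd > 0:
            aspect = 1.0 + float(_gamma_mean_sd(rng, excess, params.outline_aspect_sd))
        else:
            aspect = params.outline_mean_aspect
        dev = float(
            _draw_axial_deviation(rng, params.outline_orientation_concentration, 1)[0]
        )
        orientation = condition.groove_axis_deg + math.degrees(dev)
        outlines.append(
            make_ellipse_outline(
                area,
                aspect,
                orientation,
                n_vertices=params.outline_vertices,
                noise=params.outline_noise,
                rng=rng,
                cell_id=f"{format_condition_label(condition)}_m{i:03d}",
                condition=condition,
            )
        )
    return outlines


# Depth-keyed parameter maps emulating the study's reported trends: guidance
# strengthens from 330 to 725 nm and saturates (weakly reverses for shape,
# roughly plateaus for migration) at 1000 nm; speed dips at 725 nm.  Lateral
# widths damp the guidance mildly; depth is the dominant modeled effect.
_DEPTH_AXIS_BIAS = {0.0: 0.0, 330.0: 1.2, 725.0: 5.0, 1000.0: 5.5}
_DEPTH_SPEED = {0.0: 0.39, 330.0: 0.35, 725.0: 0.25, 1000.0: 0.29}
_DEPTH_ASPECT = {0.0: 4.81, 330.0: 5.92, 725.0: 8.66, 1000.0: 7.64}
_DEPTH_ORIENT_CONC = {0.0: 0.0, 330.0: 1.4, 725.0: 10.0, 1000.0: 6.0}
_DEPTH_AREA = {0.0: 2816.8, 330.0: 2365.3, 725.0: 2115.3, 1000.0: 2259.4}


def _interp_map(table: dict, depth: float) -> float:
    xs = np.array(sorted(table))
    ys = np.array([table[x] for x in xs])
    return float(np.interp(depth, xs, ys))


def study_params(
    condition: SubstrateCondition,
    n_cells: int = 30,
    seed: int = 0,
    base: SimulationParams | None = None,
) -> SimulationParams:
    """Generator parameters emulating the study cohort for one condition.

    Depth sets the guidance strength, migration speed, and outline shape
    statistics; wider ridges/grooves mildly weaken guidance (widths beyond
    2 µm damp the heading bias and orientation concentration).
    """
    base = base if base is not None else SimulationParams()
    d = condition.groove_depth_nm
    damp = 1.0
    if not condition.is_control:
        damp = max(
            0.35,
            1.0
            - 0.05 * (condition.ridge_width_um - 2.0)
            - 0.02 * (condition.groove_width_um - 2.0),
        )
    return replace(
        base,
        n_cells=n_cells,
        seed=seed % _TWO31,
        axis_bias=_interp_map(_DEPTH_AXIS_BIAS, d) * damp,
        base_speed_um_per_min=_interp_map(_DEPTH_SPEED, d),
        outline_mean_aspect=1.0 + (_interp_map(_DEPTH_ASPECT, d) - 1.0) * (0.5 + 0.5 * damp),
        outline_orientation_concentration=_interp_map(_DEPTH_ORIENT_CONC, d) * damp,
        outline_area_mean_um2=_interp_map(_DEPTH_AREA, d),
    )


@dataclass
class FixtureManifest:
    """What :func:`write_fixture_set` produced, with seeds and file paths
    (relative to the output directory)."""

    seed: int
    conditions: list[str]
    trajectory_files: dict[str, str]
    outline_files: dict[str, str]
    flags_files: dict[str, str]
    ground_truth_file: str
    cell_ids: dict[str, list[str]] = field(default_factory=dict)


def write_fixture_set(conditions, params, out_dir) -> FixtureManifest:
    """Write a complete synthetic dataset: per-condition trajectory and
    outline CSVs, a per-condition flags CSV, a ground-truth parameter table
    and a key-value manifest.

    ``params`` is either one :class:`SimulationParams` applied to every
    condition (with per-condition seeds ``params.seed + k``) or a mapping
    ``{condition: SimulationParams}`` whose entries are used as-is.
    Re-running with identical arguments produces byte-identical files.
    """
    from . import io as cgio  # local import: io depends on types above

    import pathlib

    if isinstance(params, SimulationParams):
        base_seed = params.seed
        params_for = {
            cond: replace(params, seed=(params.seed + k) % _TWO31)
            for k, cond in enumerate(conditions)
        }
    else:
        params_for = dict(params)
        missing = [c for c in conditions if c not in params_for]
        if missing:
            raise ValueError(f"no simulation params for conditions: {missing}")
        base_seed = min(p.seed for p in params_for.values()) if params_for else 0

    out = pathlib.Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    manifest = FixtureManifest(
        seed=base_seed,
        conditions=[],
        trajectory_files={},
        outline_files={},
        flags_files={},
        ground_truth_file="ground_truth.csv",
    )
    truth_rows = []
    for cond in conditions:
        label = format_condition_label(cond)
        p = params_for[cond]
        rng = np.random.default_rng(p.seed + 2)
        tracks = simulate_trajectories(p, cond)
        # a small fraction of tracks drifts off the pattern; control exempt
        if not cond.is_control:
            for tr in tracks:
                tr.on_pattern = bool(rng.random() >= 0.05)
        outlines = simulate_outlines(p, cond)
        for ol in outlines:
            ol.flag_mitosis = bool(rng.random() < 0.04)
            ol.flag_spans_flat_and_pattern = bool(
                (not cond.is_control) and rng.random() < 0.04
            )
        traj_file = f"tracks_{label}.csv"
        outl_file = f"outlines_{label}.csv"
        flag_file = f"flags_{label}.csv"
        cgio.write_trajectories(tracks, out / traj_file)
        cgio.write_outlines(outlines, out / outl_file, out / flag_file)
        manifest.conditions.append(label)
        manifest.trajectory_files[label] = traj_file
        manifest.outline_files[label] = outl_file
        manifest.flags_files[label] = flag_file
        manifest.cell_ids[label] = [t.cell_id for t in tracks]
        truth_rows.append(
            {
                "condition": label,
                "seed": p.seed,
                "n_cells": p.n_cells,
                "base_speed_um_per_min": p.base_speed_um_per_min,
                "persistence": p.persistence,
                "axis_bias": p.axis_bias,
                "outline_mean_aspect": p.outline_mean_aspect,
                "outline_orientation_concentration": p.outline_orientation_concentration,
                "outline_area_mean_um2": p.outline_area_mean_um2,
            }
        )

    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(
        out / manifest.ground_truth_file, index=False, float_format="%.6f"
    )
    lines = [f"seed: {base_seed}", f"ground_truth: {manifest.ground_truth_file}"]
    for label in manifest.conditions:
        lines.append(f"condition: {label}")
        lines.append(f"  tracks: {manifest.trajectory_files[label]}")
        lines.append(f"  outlines: {manifest.outline_files[label]}")
        lines.append(f"  flags: {manifest.flags_files[label]}")
        lines.append(f"  cells: {','.join(manifest.cell_ids[label])}")
    (out / "manifest.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest
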