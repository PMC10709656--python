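"""Dynamic analysis of nucleus tracks.

All directional quantities are measured against the groove axis (+y by
convention; x is the perpendicular).  Implements the study's migration
statistics:

* directional orientation — angle between the net start-to-end displacement
  and the groove axis, folded to [0, 90] deg (tracks of at least 10 h);
* angular displacement ``dtheta(t, delta)`` — angle between displacement
  vectors over consecutive intervals of length ``delta``, in [0, 180] deg,
  with its 15-degree-bin occurrence distribution;
* average speed ``v_bar`` (total travel distance over total travel time)
  and its decomposition into groove-parallel ``v_y`` and perpendicular
  ``v_x`` components;
* directional displacement ratio ``d_y/D`` — signed groove-axis projection
  of the net displacement over the 10-min-sampled path length up to a time
  interval ``Delta`` — and the classical directionality ratio ``d/D``;
* mean squared displacement and the velocity autocorrelation (mean cosine
  similarity between step vectors at a lag, 1 at lag 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .histogram import OccurrenceHistogram, occurrence_histogram
from .synthetic import Trajectory

logger = logging.getLogger(__name__)

#: dynamic-analysis inclusion gate: cells must migrate more than 6 h
MIN_TRACK_MIN = 360.0
#: directional-orientation gate: at least 10 h of track
MIN_ORIENTATION_MIN = 600.0


def _axis_vectors(track: Trajectory):
    """Unit vectors along (y) and perpendicular to (x) the groove axis."""
    a = math.radians(track.condition.groove_axis_deg)
    along = np.array([math.cos(a), math.sin(a)])
    perp = np.array([-math.sin(a), math.cos(a)])
    # snap rounding residue of cos(pi/2) so axial motion decomposes exactly
    along[np.abs(along) < 1e-12] = 0.0
    perp[np.abs(perp) < 1e-12] = 0.0
    return along, perp


def _steps(track: Trajectory) -> np.ndarray:
    return np.diff(track.positions_um, axis=0)


def _check_on_grid(track: Trajectory, interval_min: float, name: str) -> int:
    k = interval_min / track.dt_min
    if interval_min <= 0 or abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"{name}={interval_min} min is not a positive multiple of the "
            f"{track.dt_min}-min sampling interval"
        )
    return int(round(k))


@dataclass
class TrackExclusionLog:
    n_input: int = 0
    n_included: int = 0
    too_short: list[str] = field(default_factory=list)
    off_pattern: list[str] = field(default_factory=list)


def filter_trajectories(
    tracks, min_duration_min: float = MIN_TRACK_MIN
) -> tuple[list[Trajectory], TrackExclusionLog]:
    """Keep tracks longer than ``min_duration_min`` whose nucleus stays on
    the topographic pattern (control tracks are exempt from the on-pattern
    flag).  Exclusions are logged per reason."""
    log = TrackExclusionLog(n_input=len(tracks))
    kept = []
    for t in tracks:
        if t.on_pattern is None:
            raise ValueError(f"track {t.cell_id}: missing on_pattern flag")
        if t.duration_min <= min_duration_min:
            log.too_short.append(t.cell_id)
        elif not t.condition.is_control and not t.on_pattern:
            log.off_pattern.append(t.cell_id)
        else:
            kept.append(t)
    log.n_included = len(kept)
    if log.n_input != log.n_included:
        logger.info(
            "excluded %d/%d tracks (short: %d, off-pattern: %d)",
            log.n_input - log.n_included,
            log.n_input,
            len(log.too_short),
            len(log.off_pattern),
        )
    return kept, log


def directional_orientation(
    track: Trajectory, min_duration_min: float | None = MIN_ORIENTATION_MIN
) -> float:
    """Angle (deg, in [0, 90]) between the net start-to-end displacement and
    the groove axis.  Undefined for zero net displacement or tracks shorter
    than the 10-h gate (pass ``min_duration_min=None`` to disable)."""
    if min_duration_min is not None and track.duration_min < min_duration_min:
        raise ValueError(
            f"track {track.cell_id}: duration {track.duration_min} min is below the "
            f"{min_duration_min}-min directional-orientation gate"
        )
    net = track.positions_um[-1] - track.positions_um[0]
    norm = np.linalg.norm(net)
    if norm == 0:
        raise ValueError(f"track {track.cell_id}: zero net displacement, orientation undefined")
    along, _ = _axis_vectors(track)
    cosang = abs(float(np.dot(net, along))) / norm
    return math.degrees(math.acos(min(1.0, cosang)))


@dataclass
class AngularDisplacements:
    """Turning angles dtheta (deg, [0, 180]) plus the count of skipped pairs
    where either displacement vector had zero magnitude."""

    values_deg: np.ndarray
    n_skipped: int
    delta_min: float


def angular_displacement(track: Trajectory, delta_min: float) -> AngularDisplacements:
    """Angles between the displacement over [t, t+delta] and over
    [t+delta, t+2*delta] for every valid start time t on the sampling grid
    (overlapping windows).  Zero-magnitude pairs are skipped and counted,
    never imputed."""
    m = _check_on_grid(track, delta_min, "delta")
    pos = track.positions_um
    n = len(pos)
    if n < 2 * m + 1:
        raise ValueError(
            f"track {track.cell_id}: too short for delta={delta_min} min "
            f"(needs {2 * m + 1} samples, has {n})"
        )
    v1 = pos[m : n - m] - pos[: n - 2 * m]
    v2 = pos[2 * m :] - pos[m : n - m]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > 0) & (n2 > 0)
    cosang = np.sum(v1[ok] * v2[ok], axis=1) / (n1[ok] * n2[ok])
    values = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return AngularDisplacements(
        values_deg=values, n_skipped=int(np.sum(~ok)), delta_min=float(delta_min)
    )


def turning_histogram(dthetas, bin_deg: float = 15.0, delta_min: float | None = None) -> OccurrenceHistogram:
    """Occurrence distribution of angular displacements over [0, 180] deg
    (12 bins at the default 15-degree width)."""
    values = dthetas.values_deg if isinstance(dthetas, AngularDisplacements) else dthetas
    if isinstance(dthetas, AngularDisplacements) and delta_min is None:
        delta_min = dthetas.delta_min
    return occurrence_histogram(values, bin_deg, (0.0, 180.0), delta_min=delta_min)


def average_speed(track: Trajectory) -> float:
    """v_bar: total travel distance over total travel time (µm/min)."""
    lengths = np.linalg.norm(_steps(track), axis=1)
    return float(np.sum(lengths) / track.duration_min)


@dataclass(frozen=True)
class DirectionalSpeeds:
    v_x_um_per_min: float
    v_y_um_per_min: float
    ratio_y_over_x: float  # inf when v_x == 0
    ratio_defined: bool


def directional_speeds(track: Trajectory) -> DirectionalSpeeds:
    """Decompose travel into groove-parallel (y) and perpendicular (x)
    distances over total time: v_x = sum|dx|/T, v_y = sum|dy|/T.  The y/x
    ratio is flagged undefined (inf) for purely axial motion."""
    along, perp = _axis_vectors(track)
    steps = _steps(track)
    t = track.duration_min
    vy = float(np.sum(np.abs(steps @ along)) / t)
    vx = float(np.sum(np.abs(steps @ perp)) / t)
    if vx == 0.0:
        return DirectionalSpeeds(vx, vy, math.inf, ratio_defined=False)
    return DirectionalSpeeds(vx, vy, vy / vx, ratio_defined=True)


def _path_length_upto(track: Trajectory, k: int) -> float:
    steps = np.diff(track.positions_um[: k + 1], axis=0)
    return float(np.sum(np.linalg.norm(steps, axis=1)))


def directional_displacement_ratio(track: Trajectory, delta_upper_min: float) -> float:
    """d_y(0, Delta)/D(0, Delta): signed groove-axis displacement over the
    summed 10-min step lengths up to ``Delta``.  In [-1, 1]."""
    k = _check_on_grid(track, delta_upper_min, "Delta")
    if k >= len(track.positions_um):
        raise ValueError(
            f"track {track.cell_id}: Delta={delta_upper_min} min exceeds track duration"
        )
    d = _path_length_upto(track, k)
    if d == 0.0:
        raise ValueError(f"track {track.cell_id}: zero path length over [0, {delta_upper_min}] min")
    along, _ = _axis_vectors(track)
    dy = float(np.dot(track.positions_um[k] - track.positions_um[0], along))
    return float(np.clip(dy / d, -1.0, 1.0))


def directionality_ratio(track: Trajectory, delta_upper_min: float) -> float:
    """d/D: straight-line start-to-end distance over path length on
    [0, Delta].  In [0, 1]."""
    k = _check_on_grid(track, delta_upper_min, "Delta")
    if k >= len(track.positions_um):
        raise ValueError(
            f"track {track.cell_id}: Delta={delta_upper_min} min exceeds track duration"
        )
    d_path = _path_length_upto(track, k)
    if d_path == 0.0:
        raise ValueError(f"track {track.cell_id}: zero path length over [0, {delta_upper_min}] min")
    d_net = float(np.linalg.norm(track.positions_um[k] - track.positions_um[0]))
    return min(1.0, d_net / d_path)


def cohort_ratio_curve(tracks, delta_grid_min, signed: bool = True):
    """Mean +/- SEM of the directional displacement ratio per time interval.

    Cells shorter than a given Delta drop out of that point (logged).  With
    ``signed=False`` the absolute ratio |d_y|/D is averaged instead.
    Returns a DataFrame with columns Delta_min, mean, sem, n.
    """
    import pandas as pd

    if not tracks:
        raise ValueError("cohort_ratio_curve: empty cohort")
    rows = []
    for delta in delta_grid_min:
        vals = []
        dropped = 0
        for t in tracks:
            try:
                r = directional_displacement_ratio(t, delta)
            except ValueError:
                dropped += 1
                continue
            vals.append(r if signed else abs(r))
        if dropped:
            logger.info("Delta=%g min: %d tracks too short, dropped", delta, dropped)
        if not vals:
            continue
        v = np.asarray(vals)
        sem = float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
        rows.append({"Delta_min": float(delta), "mean": float(np.mean(v)), "sem": sem, "n": len(v)})
    if not rows:
        raise ValueError("no track long enough for any requested Delta")
    return pd.DataFrame(rows)


def mean_squared_displacement(tracks, lag_grid_min):
    """Time-and-ensemble-averaged MSD per lag (µm²): for each track the
    squared displacement is averaged over all overlapping windows of the
    lag, then track averages are averaged across the cohort."""
    import pandas as pd

    if not tracks:
        raise ValueError("mean_squared_displacement: empty cohort")
    rows = []
    for lag in lag_grid_min:
        per_track = []
        for t in tracks:
            m = _check_on_grid(t, lag, "lag")
            pos = t.positions_um
            if m >= len(pos):
                continue
            disp = pos[m:] - pos[:-m]
            per_track.append(float(np.mean(np.sum(disp**2, axis=1))))
        if not per_track:
            raise ValueError(f"lag {lag} min exceeds every track duration")
        rows.append({"lag_min": float(lag), "msd_um2": float(np.mean(per_track)), "n": len(per_track)})
    return pd.DataFrame(rows)


def velocity_autocorrelation(tracks, lag_grid_min):
    """Normalized VACF per lag: the mean cosine similarity between step
    vectors separated by the lag, pooled over all windows and tracks
    (1 at lag 0 by construction; zero-magnitude steps are skipped)."""
    import pandas as pd

    if not tracks:
        raise ValueError("velocity_autocorrelation: empty cohort")
    rows = []
    for lag in lag_grid_min:
        vals = []
        any_valid = False
        for t in tracks:
            m = _check_on_grid(t, lag, "lag") if lag > 0 else 0
            steps = _steps(t)
            if m >= len(steps) and m > 0:
                continue
            any_valid = True
            if m == 0:
                v1 = v2 = steps
            else:
                v1, v2 = steps[:-m], steps[m:]
            n1 = np.linalg.norm(v1, axis=1)
            n2 = np.linalg.norm(v2, axis=1)
            ok = (n1 > 0) & (n2 > 0)
            if np.any(ok):
                vals.append(np.sum(v1[ok] * v2[ok], axis=1) / (n1[ok] * n2[ok]))
        if not any_valid:
            raise ValueError(f"lag {lag} min exceeds every track duration")
        pooled = np.concatenate(vals) if vals else np.array([np.nan])
        rows.append({"lag_min": float(lag), "vacf": float(np.mean(pooled)), "n_pairs": int(pooled.size)})
    return pd.DataFrame(rows)


@dataclass
class MigrationRecord:
    """Per-cell migration summary used by the group statistics."""

    cell_id: str
    condition: SubstrateCondition
    duration_min: float
    mean_speed_um_per_min: float
    v_x_um_per_min: float
    v_y_um_per_min: float
    speed_ratio_y_over_x: float
    directional_orientation_deg: float | None


def summarize_track(track: Trajectory, orientation_gate_min: float | None = MIN_ORIENTATION_MIN) -> MigrationRecord:
    sp = directional_speeds(track)
    try:
        orient = directional_orientation(track, orientation_gate_min)
    except ValueError:
        orient = None
    return MigrationRecord(
        cell_id=track.cell_id,
        condition=track.condition,
        duration_min=track.duration_min,
        mean_speed_um_per_min=average_speed(track),
        v_x_um_per_min=sp.v_x_um_per_min,
        v_y_um_per_min=sp.v_y_um_per_min,
        speed_ratio_y_over_x=sp.ratio_y_over_x,
        directional_orientation_deg=orient,
    )
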