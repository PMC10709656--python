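"""End-to-end pipeline: simulate -> morphology -> migration -> statistics
-> mechanics, with every intermediate written as CSV plus a run log and a
plain-text summary.  Re-running with the same configuration and seed
reproduces byte-identical CSV output."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cgio
from . import mechanics, migration, morphology, stats
from .conditions import CONTROL, build_condition_grid, format_condition_label
from .synthetic import SimulationParams, study_params, write_fixture_set

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (caught before any computation)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Defaults are the study conventions: elongation threshold 2 on the
    normalized aspect ratio, alignment threshold 2 deg, duration gates
    360/600 min, 2-deg alignment and 15-deg turning bins, turning-angle
    intervals {10, 50, 100, 200} min, ratio-curve intervals 10-600 min in
    10-min steps.
    """

    out_dir: str = "contactguide_run"
    seed: int = 0
    series: tuple[str, ...] = ("G2RN", "GNRN", "GNR2")
    depths_nm: tuple[float, ...] = (330.0, 725.0, 1000.0)
    n_cells: int = 30
    dt_min: float = 10.0
    duration_min: float = 600.0
    elongation_threshold: float = 2.0
    alignment_threshold_deg: float = 2.0
    min_track_min: float = 360.0
    min_orientation_min: float = 600.0
    alignment_bin_deg: float = 2.0
    turning_bin_deg: float = 15.0
    turning_deltas_min: tuple[float, ...] = (10.0, 50.0, 100.0, 200.0)
    ratio_delta_min: tuple[float, ...] = tuple(float(d) for d in range(10, 601, 10))
    filopodia_lengths_um: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    control_stat: str = "mean"

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be positive")
        if self.dt_min <= 0 or self.duration_min <= 0:
            raise ConfigError("dt_min and duration_min must be positive")
        for name in (
            "elongation_threshold",
            "alignment_threshold_deg",
            "min_track_min",
            "min_orientation_min",
            "alignment_bin_deg",
            "turning_bin_deg",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("turning_deltas_min", "ratio_delta_min"):
            for v in getattr(self, name):
                k = v / self.dt_min
                if v <= 0 or abs(k - round(k)) > 1e-9:
                    raise ConfigError(
                        f"{name} entry {v} min is not a positive multiple of dt={self.dt_min} min"
                    )
        unknown = [s for s in self.series if s.upper() not in ("G2RN", "GNRN", "GNR2")]
        if unknown:
            raise ConfigError(f"unknown series {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for key in ("series", "depths_nm", "turning_deltas_min", "ratio_delta_min", "filopodia_lengths_um"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    out_dir: Path
    conditions: list[str]
    files: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _conditions_for(config: RunConfig):
    seen = {CONTROL: None}
    for series in config.series:
        for c in build_condition_grid(series, config.depths_nm):
            seen.setdefault(c, None)
    return list(seen)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ConfigError, PipelineError):
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _simulate(config: RunConfig, conditions, fixtures_dir: Path):
    base = SimulationParams(
        n_cells=config.n_cells,
        duration_min=config.duration_min,
        dt_min=config.dt_min,
        seed=config.seed,
    )
    params_by_cond = {
        c: study_params(c, n_cells=config.n_cells, seed=config.seed + k, base=base)
        for k, c in enumerate(conditions)
    }
    manifest = write_fixture_set(conditions, params_by_cond, fixtures_dir)
    return manifest, params_by_cond


@_stage("morphology")
def _run_morphology(config: RunConfig, conditions, fixtures_dir: Path, out: Path, report: RunReport):
    per_cond_outlines = {}
    exclusions = {}
    for c in conditions:
        label = format_condition_label(c)
        outlines = cgio.read_outlines(
            fixtures_dir / f"outlines_{label}.csv", fixtures_dir / f"flags_{label}.csv"
        )
        kept, log = morphology.filter_static_cells(outlines)
        per_cond_outlines[c] = kept
        exclusions[label] = log
    records_by_cond = {c: morphology.measure_outlines(o) for c, o in per_cond_outlines.items()}
    control_records = records_by_cond[CONTROL]
    all_records = [r for recs in records_by_cond.values() for r in recs]
    morphology.normalize_aspect_ratios(all_records, control_records, stat=config.control_stat)

    cell_rows = [
        {
            "cell_id": r.cell_id,
            "condition": format_condition_label(r.condition),
            "area_um2": r.area_um2,
            "alpha": r.aspect_ratio,
            "alpha_bar": r.normalized_aspect,
            "theta_deg": r.alignment_deg,
            "included": r.included,
        }
        for r in all_records
    ]
    pd.DataFrame(cell_rows).to_csv(out / "morphology_cells.csv", index=False, float_format="%.6f")

    summary_rows = []
    for c, recs in records_by_cond.items():
        s = morphology.population_fractions(
            recs,
            group=format_condition_label(c),
            elong_threshold=config.elongation_threshold,
            align_threshold_deg=config.alignment_threshold_deg,
        )
        summary_rows.append(
            {
                "condition": s.group,
                "G_D_nm": c.groove_depth_nm,
                "R_w_um": c.ridge_width_um,
                "G_w_um": c.groove_width_um,
                "n_cells": s.n_cells,
                "P_elongated_pct": s.p_elongated_pct,
                "P_aligned_pct": s.p_aligned_pct,
                "alpha_mean": s.alpha_mean,
                "theta_mean_deg": s.theta_mean_deg,
            }
        )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "morphology_summary.csv", index=False, float_format="%.6f")

    hist_rows = []
    for depth, recs in _by_depth(records_by_cond).items():
        hist = morphology.alignment_histogram(recs, bin_deg=config.alignment_bin_deg)
        cdf = hist.cdf
        for i in range(len(hist.fractions)):
            hist_rows.append(
                {
                    "G_D_nm": depth,
                    "bin_lo_deg": hist.bin_edges_deg[i],
                    "bin_hi_deg": hist.bin_edges_deg[i + 1],
                    "fraction": hist.fractions[i],
                    "cdf": cdf[i],
                    "n_cells": hist.n_samples,
                }
            )
    pd.DataFrame(hist_rows).to_csv(out / "alignment_histograms.csv", index=False, float_format="%.6f")
    report.files["morphology_cells"] = "morphology_cells.csv"
    report.files["morphology_summary"] = "morphology_summary.csv"
    report.files["alignment_histograms"] = "alignment_histograms.csv"
    return records_by_cond, summary, exclusions


def _by_depth(by_cond: dict):
    grouped: dict[float, list] = {}
    for c, items in by_cond.items():
        grouped.setdefault(c.groove_depth_nm, []).extend(items)
    return dict(sorted(grouped.items()))


@_stage("migration")
def _run_migration(config: RunConfig, conditions, fixtures_dir: Path, out: Path, report: RunReport):
    tracks_by_cond = {}
    exclusions = {}
    for c in conditions:
        label = format_condition_label(c)
        tracks = cgio.read_trajectories(fixtures_dir / f"tracks_{label}.csv")
        kept, log = migration.filter_trajectories(tracks, min_duration_min=config.min_track_min)
        tracks_by_cond[c] = kept
        exclusions[label] = log

    cell_rows = []
    for c, tracks in tracks_by_cond.items():
        for t in tracks:
            rec = migration.summarize_track(t, orientation_gate_min=config.min_orientation_min)
            cell_rows.append(
                {
                    "cell_id": rec.cell_id,
                    "condition": format_condition_label(c),
                    "G_D_nm": c.groove_depth_nm,
                    "duration_min": rec.duration_min,
                    "mean_speed_um_per_min": rec.mean_speed_um_per_min,
                    "v_x_um_per_min": rec.v_x_um_per_min,
                    "v_y_um_per_min": rec.v_y_um_per_min,
                    "speed_ratio_y_over_x": rec.speed_ratio_y_over_x,
                    "directional_orientation_deg": rec.directional_orientation_deg,
                }
            )
    cells = pd.DataFrame(cell_rows)
    cells.to_csv(out / "migration_cells.csv", index=False, float_format="%.6f")

    by_depth = _by_depth(tracks_by_cond)
    occ_rows = []
    for depth, tracks in by_depth.items():
        for delta in config.turning_deltas_min:
            values = np.concatenate(
                [migration.angular_displacement(t, delta).values_deg for t in tracks]
            )
            hist = migration.turning_histogram(values, bin_deg=config.turning_bin_deg, delta_min=delta)
            for i in range(len(hist.fractions)):
                occ_rows.append(
                    {
                        "G_D_nm": depth,
                        "delta_min": delta,
                        "bin_lo_deg": hist.bin_edges_deg[i],
                        "bin_hi_deg": hist.bin_edges_deg[i + 1],
                        "fraction": hist.fractions[i],
                        "n_samples": hist.n_samples,
                    }
                )
    pd.DataFrame(occ_rows).to_csv(out / "turning_histograms.csv", index=False, float_format="%.6f")

    curve_frames = []
    msd_frames = []
    vacf_frames = []
    lags = [d for d in config.ratio_delta_min]
    abs_frames = []
    for depth, tracks in by_depth.items():
        curve = migration.cohort_ratio_curve(tracks, config.ratio_delta_min)
        curve.insert(0, "G_D_nm", depth)
        curve_frames.append(curve)
        curve_abs = migration.cohort_ratio_curve(tracks, config.ratio_delta_min, signed=False)
        curve_abs.insert(0, "G_D_nm", depth)
        abs_frames.append(curve_abs)
        msd = migration.mean_squared_displacement(tracks, lags)
        msd.insert(0, "G_D_nm", depth)
        msd_frames.append(msd)
        vacf = migration.velocity_autocorrelation(tracks, [0.0] + lags[:20])
        vacf.insert(0, "G_D_nm", depth)
        vacf_frames.append(vacf)
    pd.concat(curve_frames, ignore_index=True).to_csv(
        out / "ratio_curves.csv", index=False, float_format="%.6f"
    )
    pd.concat(abs_frames, ignore_index=True).to_csv(
        out / "ratio_curves_abs.csv", index=False, float_format="%.6f"
    )
    pd.concat(msd_frames, ignore_index=True).to_csv(out / "msd.csv", index=False, float_format="%.6f")
    pd.concat(vacf_frames, ignore_index=True).to_csv(out / "vacf.csv", index=False, float_format="%.6f")
    for key in ("migration_cells", "turning_histograms", "ratio_curves", "ratio_curves_abs", "msd", "vacf"):
        report.files[key] = f"{key}.csv"
    return tracks_by_cond, cells, exclusions


@_stage("statistics")
def _run_statistics(config: RunConfig, morph_summary: pd.DataFrame, morph_records, migr_cells: pd.DataFrame, out: Path, report: RunReport):
    depth_groups_alpha = {
        d: [r.aspect_ratio for r in recs] for d, recs in _by_depth(morph_records).items()
    }
    depth_groups_theta = {
        d: [r.alignment_deg for r in recs] for d, recs in _by_depth(morph_records).items()
    }
    speed_groups = {
        d: g["mean_speed_um_per_min"].to_list() for d, g in migr_cells.groupby("G_D_nm")
    }
    orient = migr_cells.dropna(subset=["directional_orientation_deg"])
    orient_groups = {
        d: g["directional_orientation_deg"].to_list() for d, g in orient.groupby("G_D_nm")
    }

    comp_rows = []
    pair_frames = []
    for metric, groups in (
        ("alpha", depth_groups_alpha),
        ("theta_deg", depth_groups_theta),
        ("mean_speed", speed_groups),
        ("directional_orientation", orient_groups),
    ):
        labels = [f"GD{int(d)}" for d in groups]
        res = stats.compare_groups(list(groups.values()), labels)
        comp_rows.append(
            {
                "metric": metric,
                "H": res.h_statistic,
                "p_value": res.p_value,
                "groups": ";".join(labels),
                "group_sizes": ";".join(str(s) for s in res.group_sizes),
            }
        )
        pw = res.pairwise.copy()
        pw.insert(0, "metric", metric)
        pair_frames.append(pw)
    pd.DataFrame(comp_rows).to_csv(out / "group_comparisons.csv", index=False, float_format="%.6g")
    pd.concat(pair_frames, ignore_index=True).to_csv(
        out / "pairwise_comparisons.csv", index=False, float_format="%.6g"
    )

    box_rows = []
    for metric, groups in (("alpha", depth_groups_alpha), ("theta_deg", depth_groups_theta)):
        for d, vals in groups.items():
            b = stats.box_summary(vals)
            box_rows.append(
                {
                    "metric": metric,
                    "G_D_nm": d,
                    "median": b.median,
                    "q1": b.q1,
                    "q3": b.q3,
                    "whisker_low": b.whisker_low,
                    "whisker_high": b.whisker_high,
                    "n_outliers": len(b.outliers),
                }
            )
    pd.DataFrame(box_rows).to_csv(out / "box_summaries.csv", index=False, float_format="%.6f")

    reg_rows = []
    for response in ("P_elongated_pct", "P_aligned_pct"):
        for case in (1, 2):
            try:
                res = stats.population_regression(morph_summary, case=case, response=response)
            except ValueError as exc:
                # too few conditions or collinear dimensions on a reduced grid
                logger.warning("regression of %s (case %d) skipped: %s", response, case, exc)
                continue
            for term in res.coefficients.index:
                reg_rows.append(
                    {
                        "response": response,
                        "case": case,
                        "term": term,
                        "coefficient": res.coefficients[term],
                        "p_value": res.p_values[term],
                        "r_squared": res.r_squared,
                        "n_obs": res.n_obs,
                    }
                )
    regress = pd.DataFrame(reg_rows)
    regress.to_csv(out / "population_regression.csv", index=False, float_format="%.6g")
    report.files["group_comparisons"] = "group_comparisons.csv"
    report.files["pairwise_comparisons"] = "pairwise_comparisons.csv"
    report.files["box_summaries"] = "box_summaries.csv"
    report.files["population_regression"] = "population_regression.csv"
    return regress


@_stage("mechanics")
def _run_mechanics(config: RunConfig, out: Path, report: RunReport):
    depths = [0.0] + list(config.depths_nm)
    table = mechanics.bending_angle_table(depths, config.filopodia_lengths_um)
    table.to_csv(out / "bending_angles.csv", index=False, float_format="%.6f")
    report.files["bending_angles"] = "bending_angles.csv"
    return table


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis chain and write all outputs under
    ``config.out_dir``.  Any stage failure aborts with the stage name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures_dir = out / "fixtures"
    conditions = _conditions_for(config)
    report = RunReport(out_dir=out, conditions=[format_condition_label(c) for c in conditions])

    manifest, params_by_cond = _simulate(config, conditions, fixtures_dir)
    morph_records, morph_summary, morph_excl = _run_morphology(
        config, conditions, fixtures_dir, out, report
    )
    tracks_by_cond, migr_cells, migr_excl = _run_migration(
        config, conditions, fixtures_dir, out, report
    )
    regress = _run_statistics(config, morph_summary, morph_records, migr_cells, out, report)
    _run_mechanics(config, out, report)

    by_depth_summary = (
        morph_summary.groupby("G_D_nm")
        .agg(
            n_cells=("n_cells", "sum"),
            P_elongated_pct=("P_elongated_pct", "mean"),
            P_aligned_pct=("P_aligned_pct", "mean"),
            alpha_mean=("alpha_mean", "mean"),
            theta_mean_deg=("theta_mean_deg", "mean"),
        )
        .reset_index()
    )
    speed_by_depth = (
        migr_cells.groupby("G_D_nm")["mean_speed_um_per_min"].mean().reset_index()
    )
    orient_by_depth = (
        migr_cells.dropna(subset=["directional_orientation_deg"])
        .groupby("G_D_nm")["directional_orientation_deg"]
        .mean()
        .reset_index()
    )
    report.summary = {
        "by_depth": by_depth_summary,
        "speed_by_depth": speed_by_depth,
        "orientation_by_depth": orient_by_depth,
        "regression": regress,
    }

    log_lines = [
        f"seed: {config.seed}",
        f"conditions: {len(conditions)}",
        f"cells_per_condition: {config.n_cells}",
        f"sampling_dt_min: {config.dt_min}",
        "conventions: groove axis = +y; angles in degrees; positions in um; times in min",
        f"thresholds: alpha_bar >= {config.elongation_threshold}; theta <= {config.alignment_threshold_deg} deg",
        f"duration_gates_min: dynamic > {config.min_track_min}; orientation >= {config.min_orientation_min}",
    ]
    for label, log in morph_excl.items():
        if log.n_input != log.n_included:
            log_lines.append(
                f"morphology_exclusions {label}: mitosis={len(log.mitosis)} "
                f"spans={len(log.spans_flat_and_pattern)}"
            )
    for label, log in migr_excl.items():
        if log.n_input != log.n_included:
            log_lines.append(
                f"migration_exclusions {label}: short={len(log.too_short)} "
                f"off_pattern={len(log.off_pattern)}"
            )
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")

    summary_lines = ["Contact-guidance analysis summary", "=" * 34, ""]
    summary_lines.append("Morphology by groove depth (pooled over lateral series):")
    summary_lines.append(by_depth_summary.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    summary_lines.append("")
    summary_lines.append("Mean migration speed by depth (um/min):")
    summary_lines.append(speed_by_depth.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    summary_lines.append("")
    summary_lines.append("Mean directional orientation by depth (deg):")
    summary_lines.append(orient_by_depth.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    summary_lines.append("")
    summary_lines.append("Population-fraction regression (R^2 by case):")
    if regress.empty:
        summary_lines.append("(skipped: condition grid too small for the regression model)")
    else:
        r2 = regress.drop_duplicates(subset=["response", "case"])[["response", "case", "r_squared", "n_obs"]]
        summary_lines.append(r2.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n", encoding="utf-8")
    report.files["run_log"] = "run_log.txt"
    report.files["summary"] = "summary.txt"
    return report
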