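"""CSV ingestion and serialization.

All files are comma-separated UTF-8 with '.' decimal and a mandatory
header; positions in µm, times in minutes, angles in degrees.

* trajectory CSV: ``cell_id,t_min,x_um,y_um,condition,on_pattern``
* outline CSV:    ``cell_id,vertex_index,x_um,y_um``
* flags CSV:      ``cell_id,condition,flag_mitosis,flag_spans_flat_and_pattern``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import format_condition_label, parse_condition_label
from .synthetic import CellOutline, Trajectory

_FLOAT_FMT = "%.6f"

TRAJECTORY_COLUMNS = ["cell_id", "t_min", "x_um", "y_um", "condition", "on_pattern"]
OUTLINE_COLUMNS = ["cell_id", "vertex_index", "x_um", "y_um"]
FLAGS_COLUMNS = ["cell_id", "condition", "flag_mitosis", "flag_spans_flat_and_pattern"]


def _require_columns(frame: pd.DataFrame, needed, path) -> None:
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _parse_bool(series: pd.Series, path) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].unique()[:5]
        raise ValueError(f"{path}: unparseable boolean values {list(bad)}")
    return out


def write_trajectories(tracks, path) -> None:
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "t_min": t.times_min,
                    "x_um": t.positions_um[:, 0],
                    "y_um": t.positions_um[:, 1],
                    "condition": format_condition_label(t.condition),
                    "on_pattern": t.on_pattern,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectories(path) -> list[Trajectory]:
    """Read, group and time-sort nucleus tracks; validates the regular
    sampling grid and rejects duplicated (cell, time) rows by name."""
    table = pd.read_csv(path)
    _require_columns(table, TRAJECTORY_COLUMNS, path)
    table["on_pattern"] = _parse_bool(table["on_pattern"], path)
    dup = table.duplicated(subset=["cell_id", "t_min"], keep=False)
    if dup.any():
        rows = table.loc[dup, ["cell_id", "t_min"]].drop_duplicates().head(5)
        raise ValueError(
            f"{path}: duplicated (cell_id, t_min) rows, e.g. "
            + "; ".join(f"{r.cell_id}@{r.t_min}" for r in rows.itertuples())
        )
    tracks = []
    for cell_id, grp in table.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_min")
        cond_labels = grp["condition"].unique()
        if len(cond_labels) > 1:
            raise ValueError(f"{path}: cell {cell_id} carries multiple condition labels")
        on_pattern = grp["on_pattern"].unique()
        if len(on_pattern) > 1:
            raise ValueError(f"{path}: cell {cell_id} carries conflicting on_pattern flags")
        tracks.append(
            Trajectory(
                cell_id=str(cell_id),
                times_min=grp["t_min"].to_numpy(dtype=float),
                positions_um=grp[["x_um", "y_um"]].to_numpy(dtype=float),
                condition=parse_condition_label(str(cond_labels[0])),
                on_pattern=bool(on_pattern[0]),
            )
        )
    return tracks


def write_outlines(outlines, path, flags_path) -> None:
    vert_frames = []
    flag_rows = []
    for o in outlines:
        vert_frames.append(
            pd.DataFrame(
                {
                    "cell_id": o.cell_id,
                    "vertex_index": np.arange(len(o.vertices_um)),
                    "x_um": o.vertices_um[:, 0],
                    "y_um": o.vertices_um[:, 1],
                }
            )
        )
        flag_rows.append(
            {
                "cell_id": o.cell_id,
                "condition": format_condition_label(o.condition),
                "flag_mitosis": o.flag_mitosis,
                "flag_spans_flat_and_pattern": o.flag_spans_flat_and_pattern,
            }
        )
    table = pd.concat(vert_frames, ignore_index=True) if vert_frames else pd.DataFrame(columns=OUTLINE_COLUMNS)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(flag_rows, columns=FLAGS_COLUMNS).to_csv(flags_path, index=False)


def read_outlines(path, flags_path, validate: bool = True) -> list[CellOutline]:
    """Read outline polygons and join per-cell flags; self-intersecting
    polygons and cells without a flags row are rejected by cell_id."""
    from .morphology import validate_outline

    verts = pd.read_csv(path)
    _require_columns(verts, OUTLINE_COLUMNS, path)
    flags = pd.read_csv(flags_path)
    _require_columns(flags, FLAGS_COLUMNS, flags_path)
    for col in ("flag_mitosis", "flag_spans_flat_and_pattern"):
        flags[col] = _parse_bool(flags[col], flags_path)
    flag_map = flags.set_index("cell_id")
    if flag_map.index.has_duplicates:
        dups = flag_map.index[flag_map.index.duplicated()].unique().tolist()
        raise ValueError(f"{flags_path}: duplicated flags rows for cells {dups}")
    missing = sorted(set(verts["cell_id"].astype(str)) - set(flag_map.index.astype(str)))
    if missing:
        raise ValueError(f"{flags_path}: missing flags rows for cells {missing}")
    outlines = []
    for cell_id, grp in verts.groupby("cell_id", sort=True):
        grp = grp.sort_values("vertex_index")
        row = flag_map.loc[cell_id]
        outline = CellOutline(
            cell_id=str(cell_id),
            vertices_um=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            condition=parse_condition_label(str(row["condition"])),
            flag_mitosis=bool(row["flag_mitosis"]),
            flag_spans_flat_and_pattern=bool(row["flag_spans_flat_and_pattern"]),
        )
        if validate:
            validate_outline(outline)
        outlines.append(outline)
    return outlines


def export_outline_masks(outlines, path, pixel_size_um: float = 1.0, margin_um: float = 5.0):
    """Optional TIFF label mask of the outlines (cell k gets label k+1) for
    interoperability with image tools.  Requires tifffile."""
    import shapely
    from shapely.geometry import Polygon

    try:
        import tifffile
    except ImportError as exc:  # pragma: no cover
        raise ImportError("TIFF export requires the tifffile package") from exc

    if not outlines:
        raise ValueError("no outlines to export")
    allverts = np.vstack([o.vertices_um for o in outlines])
    lo = allverts.min(axis=0) - margin_um
    hi = allverts.max(axis=0) + margin_um
    nx = int(np.ceil((hi[0] - lo[0]) / pixel_size_um))
    ny = int(np.ceil((hi[1] - lo[1]) / pixel_size_um))
    xs = lo[0] + (np.arange(nx) + 0.5) * pixel_size_um
    ys = lo[1] + (np.arange(ny) + 0.5) * pixel_size_um
    gx, gy = np.meshgrid(xs, ys)
    mask = np.zeros((ny, nx), dtype=np.uint16)
    for k, o in enumerate(outlines):
        inside = shapely.contains_xy(Polygon(o.vertices_um), gx.ravel(), gy.ravel())
        mask.ravel()[inside] = k + 1
    tifffile.imwrite(Path(path), mask)
    return mask
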