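"""Static morphometry of traced cell outlines.

Each cell is a simple polygon.  The pipeline measures spread area, fits a
moment-matched ellipse to obtain the aspect ratio ``alpha`` (major/minor)
and the alignment angle ``theta`` (acute angle between the major axis and
the groove direction, folded into [0, 90] deg), normalizes aspect ratios by
the control-substrate average (``alpha_bar = alpha / alpha_cont``), and
summarizes populations with the elongation (``alpha_bar >= 2``) and
alignment (``theta <= 2 deg``) fractions plus 2-degree alignment
histograms/CDFs.

The ellipse fit matches the filled region's area, centroid and second
central moments: orientation and aspect come from the principal axes of the
region covariance, and the axes are scaled so the ellipse area equals the
polygon area exactly — the behavior of the standard image-analysis fit of
filled shapes (not a least-squares fit to boundary vertices).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .conditions import SubstrateCondition
from .histogram import OccurrenceHistogram, occurrence_histogram
from .synthetic import CellOutline

logger = logging.getLogger(__name__)

_DEGENERATE_AREA_UM2 = 1e-9


@dataclass(frozen=True)
class EllipseFit:
    """Moment-matched ellipse of a polygonal cell region.

    ``major_um``/``minor_um`` are full axis lengths; ``orientation_deg`` is
    the major-axis direction in [0, 180) measured CCW from +x.
    """

    area_um2: float
    major_um: float
    minor_um: float
    aspect_ratio: float
    orientation_deg: float
    centroid_um: tuple[float, float]


@dataclass
class MorphologyRecord:
    cell_id: str
    condition: SubstrateCondition
    area_um2: float
    aspect_ratio: float
    alignment_deg: float
    normalized_aspect: float | None = None
    included: bool = True


@dataclass
class PopulationSummary:
    """Per-group morphology summary: cohort size, percentage of elongated
    (``alpha_bar >= threshold``) and aligned (``theta <= threshold``) cells,
    and the average aspect ratio / alignment angle."""

    group: str
    n_cells: int
    p_elongated_pct: float
    p_aligned_pct: float
    alpha_mean: float
    theta_mean_deg: float


def _closed(verts: np.ndarray) -> np.ndarray:
    if np.allclose(verts[0], verts[-1]):
        return verts
    return np.vstack([verts, verts[0]])


def _polygon_moments(verts: np.ndarray):
    """Signed area, centroid and second central moments of a polygon by
    exact boundary integrals (Green's theorem)."""
    v = _closed(np.asarray(verts, dtype=float))
    x0, y0 = v[:-1, 0], v[:-1, 1]
    x1, y1 = v[1:, 0], v[1:, 1]
    cross = x0 * y1 - x1 * y0
    a = 0.5 * np.sum(cross)
    if abs(a) < _DEGENERATE_AREA_UM2:
        raise ValueError("degenerate polygon: area below 1e-9 um^2")
    cx = np.sum((x0 + x1) * cross) / (6.0 * a)
    cy = np.sum((y0 + y1) * cross) / (6.0 * a)
    # second moments about the origin
    sxx = np.sum((x0 * x0 + x0 * x1 + x1 * x1) * cross) / 12.0
    syy = np.sum((y0 * y0 + y0 * y1 + y1 * y1) * cross) / 12.0
    sxy = np.sum((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross) / 24.0
    # per-unit-area central moments (region covariance)
    mxx = sxx / a - cx * cx
    myy = syy / a - cy * cy
    mxy = sxy / a - cx * cy
    return a, (cx, cy), (mxx, mxy, myy)


def polygon_area(outline: CellOutline | np.ndarray) -> float:
    """Shoelace area of the outline in µm², independent of vertex order."""
    verts = outline.vertices_um if isinstance(outline, CellOutline) else outline
    a, _, _ = _polygon_moments(verts)
    return abs(a)


def validate_outline(outline: CellOutline) -> None:
    """Reject self-intersecting or degenerate polygons."""
    from shapely.geometry import Polygon

    poly = Polygon(outline.vertices_um)
    if not poly.is_valid:
        raise ValueError(f"outline {outline.cell_id}: polygon is self-intersecting or invalid")
    if poly.area < _DEGENERATE_AREA_UM2:
        raise ValueError(f"outline {outline.cell_id}: degenerate polygon (zero area)")


_ISOTROPY_TOL = 1e-12


def fit_ellipse(outline: CellOutline) -> EllipseFit:
    """Fit the moment-matched ellipse of a simple polygon.

    Orientation is the principal axis of the region covariance; for an
    isotropic covariance (e.g. a square) the tie resolves to 0 deg.  The
    returned ellipse has exactly the polygon's area.
    """
    verts = outline.vertices_um
    a_signed, centroid, (mxx, mxy, myy) = _polygon_moments(verts)
    area = abs(a_signed)
    tr = mxx + myy
    diff = mxx - myy
    disc = math.hypot(diff, 2.0 * mxy)
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    if lam2 <= 0:
        raise ValueError(f"outline {outline.cell_id}: degenerate (collinear) polygon")
    if disc <= _ISOTROPY_TOL * tr:
        orientation = 0.0  # isotropic tie rule
        aspect = 1.0
    else:
        orientation = math.degrees(0.5 * math.atan2(2.0 * mxy, diff)) % 180.0
        aspect = math.sqrt(lam1 / lam2)
    minor = 2.0 * math.sqrt(area / (math.pi * aspect))
    major = aspect * minor
    return EllipseFit(
        area_um2=area,
        major_um=major,
        minor_um=minor,
        aspect_ratio=aspect,
        orientation_deg=orientation,
        centroid_um=centroid,
    )


def alignment_angle(fit: EllipseFit, condition: SubstrateCondition) -> float:
    """Acute angle between the ellipse major axis and the groove axis,
    folded into [0, 90] deg.  The control substrate uses the same +y
    reference axis for bookkeeping."""
    d = (fit.orientation_deg - condition.groove_axis_deg) % 180.0
    return min(d, 180.0 - d)


@dataclass
class ExclusionLog:
    """Counts and identities of excluded cells, by reason."""

    n_input: int = 0
    n_included: int = 0
    mitosis: list[str] = None
    spans_flat_and_pattern: list[str] = None

    def __post_init__(self):
        self.mitosis = self.mitosis or []
        self.spans_flat_and_pattern = self.spans_flat_and_pattern or []


def filter_static_cells(outlines) -> tuple[list[CellOutline], ExclusionLog]:
    """Drop cells that underwent mitosis or spread over both flat and
    patterned areas; both reasons are logged (a cell flagged for both is
    removed once and logged twice)."""
    log = ExclusionLog(n_input=len(outlines))
    missing = [
        o.cell_id
        for o in outlines
        if o.flag_mitosis is None or o.flag_spans_flat_and_pattern is None
    ]
    if missing:
        raise ValueError(f"missing exclusion flags for cells: {missing}")
    kept = []
    for o in outlines:
        if o.flag_mitosis:
            log.mitosis.append(o.cell_id)
        if o.flag_spans_flat_and_pattern:
            log.spans_flat_and_pattern.append(o.cell_id)
        if not (o.flag_mitosis or o.flag_spans_flat_and_pattern):
            kept.append(o)
    log.n_included = len(kept)
    if log.n_input != log.n_included:
        logger.info(
            "excluded %d/%d cells (mitosis: %d, spans flat+pattern: %d)",
            log.n_input - log.n_included,
            log.n_input,
            len(log.mitosis),
            len(log.spans_flat_and_pattern),
        )
    return kept, log


def measure_outlines(outlines) -> list[MorphologyRecord]:
    """Area, ellipse fit and alignment angle for every outline."""
    records = []
    for o in outlines:
        validate_outline(o)
        fit = fit_ellipse(o)
        records.append(
            MorphologyRecord(
                cell_id=o.cell_id,
                condition=o.condition,
                area_um2=fit.area_um2,
                aspect_ratio=fit.aspect_ratio,
                alignment_deg=alignment_angle(fit, o.condition),
            )
        )
    return records


def normalize_aspect_ratios(
    records, control_records, stat: str = "mean"
) -> list[MorphologyRecord]:
    """Attach ``alpha_bar = alpha / alpha_cont`` to every record, where
    ``alpha_cont`` is the mean (or median) aspect ratio of the included
    control cells.  Control records themselves are normalized too."""
    ctrl = [r.aspect_ratio for r in control_records if r.included]
    if not ctrl:
        raise ValueError("no included control cells to define alpha_cont")
    if stat == "mean":
        alpha_cont = float(np.mean(ctrl))
    elif stat == "median":
        alpha_cont = float(np.median(ctrl))
    else:
        raise ValueError(f"unknown control statistic {stat!r}")
    for r in records:
        r.normalized_aspect = r.aspect_ratio / alpha_cont
    return records


def population_fractions(
    records,
    group: str = "",
    elong_threshold: float = 2.0,
    align_threshold_deg: float = 2.0,
) -> PopulationSummary:
    """Percentage of elongated (``alpha_bar >= elong_threshold``) and
    aligned (``theta <= align_threshold_deg``) cells, with cohort averages.
    Comparisons are inclusive."""
    recs = [r for r in records if r.included]
    if not recs:
        raise ValueError("population_fractions: no included records")
    if any(r.normalized_aspect is None for r in recs):
        raise ValueError("records lack normalized aspect ratios; normalize first")
    ab = np.array([r.normalized_aspect for r in recs])
    th = np.array([r.alignment_deg for r in recs])
    return PopulationSummary(
        group=group,
        n_cells=len(recs),
        p_elongated_pct=100.0 * float(np.mean(ab >= elong_threshold)),
        p_aligned_pct=100.0 * float(np.mean(th <= align_threshold_deg)),
        alpha_mean=float(np.mean([r.aspect_ratio for r in recs])),
        theta_mean_deg=float(np.mean(th)),
    )


def alignment_histogram(records, bin_deg: float = 2.0) -> OccurrenceHistogram:
    """Normalized alignment-angle distribution over [0, 90] deg (45 bins at
    the default 2-degree width); ``.cdf`` gives the cumulative curve."""
    thetas = [r.alignment_deg for r in records if r.included]
    return occurrence_histogram(thetas, bin_deg, (0.0, 90.0))
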