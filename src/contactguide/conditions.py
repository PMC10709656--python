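"""Substrate conditions: the ridge/groove dimension grid and its label grammar.

A condition is one topographic configuration of the contact-guidance chip:
groove width ``G_w`` and ridge width ``R_w`` in micrometres, groove depth
``G_D`` in nanometres.  Labels follow the chip's naming grammar: ``G10R10``
is a 10 µm groove / 10 µm ridge pattern, an optional ``D`` suffix carries the
depth (``G2R8D725``), and the flat reference substrate is ``control`` with
all dimensions zero.  The groove long axis is +y by convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

GROOVE_AXIS_DEG = 90.0
"""Direction of the groove long axis, degrees counterclockwise from +x."""

DEFAULT_WIDTHS_UM = (2.0, 3.0, 4.0, 6.0, 8.0, 10.0)
DEFAULT_DEPTHS_NM = (330.0, 725.0, 1000.0)

_LABEL_RE = re.compile(
    r"^G(?P<gw>\d+(?:\.\d+)?)R(?P<rw>\d+(?:\.\d+)?)(?:D(?P<gd>\d+(?:\.\d+)?))?$"
)


class ConditionLabelError(ValueError):
    """Raised when a substrate-condition label does not match the grammar."""


@dataclass(frozen=True)
class SubstrateCondition:
    """One topographic condition of the guidance chip.

    Parameters
    ----------
    groove_width_um, ridge_width_um : float
        Lateral dimensions G_w and R_w in micrometres (0 for control).
    groove_depth_nm : float
        Vertical dimension G_D in nanometres (0 for control).
    groove_axis_deg : float
        Direction of the groove long axis, degrees CCW from +x.  The
        package convention is +y (90 deg); the control substrate keeps the
        same reference axis for bookkeeping.
    """

    groove_width_um: float
    ridge_width_um: float
    groove_depth_nm: float
    groove_axis_deg: float = GROOVE_AXIS_DEG

    def __post_init__(self) -> None:
        for name in ("groove_width_um", "ridge_width_um", "groove_depth_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")

    @property
    def is_control(self) -> bool:
        """True for the flat reference substrate (all dimensions zero)."""
        return (
            self.groove_width_um == 0
            and self.ridge_width_um == 0
            and self.groove_depth_nm == 0
        )

    @property
    def label(self) -> str:
        return format_condition_label(self)


CONTROL = SubstrateCondition(0.0, 0.0, 0.0)


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def format_condition_label(condition: SubstrateCondition) -> str:
    """Render a condition under the chip grammar; inverse of :func:`parse_condition_label`."""
    if condition.is_control:
        return "control"
    lab = f"G{_fmt_num(condition.groove_width_um)}R{_fmt_num(condition.ridge_width_um)}"
    if condition.groove_depth_nm > 0:
        lab += f"D{_fmt_num(condition.groove_depth_nm)}"
    return lab


def parse_condition_label(label: str) -> SubstrateCondition:
    """Parse a ``G<w>R<w>[D<depth>]`` or ``control`` label.

    Raises
    ------
    ConditionLabelError
        If the label does not match the grammar; the message names the
        offending token.
    """
    token = label.strip()
    if token.lower() in ("control", "cont", "cont."):
        return CONTROL
    m = _LABEL_RE.match(token)
    if m is None:
        raise ConditionLabelError(
            f"malformed condition label {token!r}: expected 'G<w>R<w>' with optional "
            "'D<depth>' suffix, or 'control'"
        )
    gd = m.group("gd")
    return SubstrateCondition(
        groove_width_um=float(m.group("gw")),
        ridge_width_um=float(m.group("rw")),
        groove_depth_nm=float(gd) if gd is not None else 0.0,
    )


#: Width sets of the three lateral series.  G2RN fixes G_w = 2 µm and sweeps
#: R_w; GNR2 fixes R_w = 2 µm and sweeps G_w; GNRN sweeps both together.
SERIES_WIDTHS = {
    "G2RN": tuple((2.0, rw) for rw in DEFAULT_WIDTHS_UM),
    "GNRN": tuple((w, w) for w in DEFAULT_WIDTHS_UM),
    "GNR2": tuple((gw, 2.0) for gw in (2.0, 3.0, 4.0, 6.0, 8.0)),
}


def build_condition_grid(series: str, depths_nm) -> list[SubstrateCondition]:
    """Cross one lateral series with a set of groove depths.

    Parameters
    ----------
    series : {"G2RN", "GNRN", "GNR2"}
        Which lateral sweep to build.
    depths_nm : iterable of float
        Groove depths; an empty iterable yields an empty list.
    """
    key = series.upper()
    if key not in SERIES_WIDTHS:
        raise ValueError(f"unknown series {series!r}: expected one of {sorted(SERIES_WIDTHS)}")
    return [
        SubstrateCondition(groove_width_um=gw, ridge_width_um=rw, groove_depth_nm=float(d))
        for d in depths_nm
        for gw, rw in SERIES_WIDTHS[key]
    ]


def study_grid(depths_nm=DEFAULT_DEPTHS_NM, include_control: bool = True) -> list[SubstrateCondition]:
    """The full study layout: control plus all three series at every depth,
    de-duplicated (G2R2 occurs in every series) with order preserved."""
    seen: dict[SubstrateCondition, None] = {}
    if include_control:
        seen[CONTROL] = None
    for series in ("G2RN", "GNRN", "GNR2"):
        for c in build_condition_grid(series, depths_nm):
            seen.setdefault(c, None)
    return list(seen)
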