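"""Filopodia bending-angle model.

A filopodium of length ``l_f`` anchored on a ridge edge and touching the
groove bottom at depth ``G_D`` makes an angle

    theta_f = arcsin(G_D / l_f)

with the groove bottom.  Deeper grooves force larger bending angles, which
raises the normal traction on the filopodial adhesion and destabilizes
lateral (cross-groove) protrusions — the geometric rationale for
depth-dependent guidance.  Depths are given in nm and filopodia lengths in
µm (the field's mixed convention); the angle is returned in degrees.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def filopodia_bending_angle(groove_depth_nm: float, filopodia_length_um: float) -> float:
    """theta_f = arcsin(G_D / l_f) in degrees, monotone increasing in G_D.

    Raises a domain error (reporting both values) when the depth exceeds
    the filopodium length.
    """
    if filopodia_length_um <= 0:
        raise ValueError(f"filopodia length must be positive, got {filopodia_length_um} um")
    if groove_depth_nm < 0:
        raise ValueError(f"groove depth must be nonnegative, got {groove_depth_nm} nm")
    ratio = (groove_depth_nm / 1000.0) / filopodia_length_um
    if ratio > 1.0:
        raise ValueError(
            f"bending angle undefined: groove depth {groove_depth_nm} nm exceeds "
            f"filopodia length {filopodia_length_um} um"
        )
    return math.degrees(math.asin(ratio))


def bending_angle_table(depths_nm, filopodia_lengths_um) -> pd.DataFrame:
    """theta_f for every (G_D, l_f) pair.

    Columns: G_D_nm, l_f_um, theta_f_deg (NaN where undefined), defined.
    """
    rows = []
    for d in depths_nm:
        for lf in filopodia_lengths_um:
            try:
                theta = filopodia_bending_angle(d, lf)
                defined = True
            except ValueError:
                theta, defined = np.nan, False
            rows.append(
                {"G_D_nm": float(d), "l_f_um": float(lf), "theta_f_deg": theta, "defined": defined}
            )
    return pd.DataFrame(rows, columns=["G_D_nm", "l_f_um", "theta_f_deg", "defined"])
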