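"""Initial nest-chamber geometry.

The first excavated chamber is modelled as a cylinder with a rounded top:
for base radius ``r`` and maximum height ``h``, the cylindrical portion has
height ``ch = h - r`` and the cap is approximated by an empirical 0.67
correction factor on the radius, giving

    V = pi * r^2 * (ch + 0.67 * r)   [cm^3].

At ``h = r`` the chamber is all cap and the formula is within 0.5% of a
hemisphere (0.67 vs 2/3).  The field protocol measures chamber width and
length (horizontal axes) rather than a radius; the default conversion uses
the mean horizontal semi-axis, r = (width + length) / 4, with alternative
rules selectable and recorded in output metadata.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["chamber_volume", "radius_from_dimensions", "add_chamber_volume", "RADIUS_RULES"]

CAP_FACTOR = 0.67  # empirical rounded-top correction; hemisphere would be 2/3


def chamber_volume(r, h):
    """Chamber volume V = pi r^2 ((h - r) + 0.67 r) in cm^3.

    Requires ``r >= 0`` and ``h >= r`` (the cylinder height ch = h - r may
    not be negative).  Vectorizes over arrays.
    """
    r_arr = np.asarray(r, dtype=float)
    h_arr = np.asarray(h, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("chamber radius must be non-negative")
    if np.any(h_arr < r_arr):
        raise ValueError("chamber height h must be >= radius r (ch = h - r >= 0)")
    out = math.pi * r_arr**2 * ((h_arr - r_arr) + CAP_FACTOR * r_arr)
    return out.item() if out.ndim == 0 else out


RADIUS_RULES = {
    "mean": lambda w, l: (w + l) / 4.0,
    "min": lambda w, l: np.minimum(w, l) / 2.0,
    "max": lambda w, l: np.maximum(w, l) / 2.0,
    "geometric": lambda w, l: np.sqrt(w * l) / 2.0,
}


def radius_from_dimensions(width, length, rule: str = "mean"):
    """Base radius (cm) from the measured horizontal width and length.

    The default "mean" rule halves the mean horizontal diameter,
    r = (width + length) / 4; "min", "max" and "geometric" semi-axis rules
    are available for sensitivity checks.
    """
    if rule not in RADIUS_RULES:
        raise ValueError(f"unknown radius rule {rule!r}; choose from {sorted(RADIUS_RULES)}")
    w = np.asarray(width, dtype=float)
    l = np.asarray(length, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("width and length must be positive")
    out = RADIUS_RULES[rule](w, l)
    return out.item() if out.ndim == 0 else out


def add_chamber_volume(nests: pd.DataFrame, rule: str = "mean") -> pd.DataFrame:
    """Append derived ``radius_cm`` and ``volume_cm3`` to a nest table.

    Expects columns width_cm, length_cm, height_cm.  The radius rule used
    is recorded in ``frame.attrs["radius_rule"]``.  Mean volumes reported
    downstream are means of per-nest volumes, never the volume of mean
    dimensions.
    """
    out = nests.copy()
    r = radius_from_dimensions(out["width_cm"], out["length_cm"], rule=rule)
    out["radius_cm"] = r
    out["volume_cm3"] = chamber_volume(r, out["height_cm"].to_numpy(float))
    out.attrs["radius_rule"] = rule
    return out
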