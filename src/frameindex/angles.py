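"""Angle bookkeeping helpers.

All public interfaces in this package speak degrees; trigonometry is done
in radians internally.  Signed circular differences live on (-180, 180],
absolute angles on [0, 360).
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_180", "wrap_360", "circular_difference", "deg2rad", "rad2deg"]

deg2rad = np.deg2rad
rad2deg = np.rad2deg


def wrap_360(angle_deg):
    """Map angles (degrees) to [0, 360)."""
    return np.asarray(angle_deg, dtype=float) % 360.0


def wrap_180(angle_deg):
    """Map angles (degrees) to the signed interval (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    w = (a + 180.0) % 360.0 - 180.0
    # the mod form yields [-180, 180); fold the single open endpoint
    w = np.where(w == -180.0, 180.0, w)
    if np.ndim(angle_deg) == 0:
        return float(w)
    return w


def circular_difference(a_deg, b_deg):
    """Signed difference a - b on (-180, 180] (degrees)."""
    return wrap_180(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))
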