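"""Angle helpers shared across modules.

Convention used throughout the package (single source of truth): angles are
in degrees, wrapped to the half-open interval (-180, 180]. 0 deg points
toward warmer temperatures along the gradient axis; +/-180 deg points toward
colder temperatures.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_angle", "ang_diff"]


def wrap_angle(angle_deg):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    # map -180 -> 180 to keep the interval half-open on the left
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle_deg) or getattr(angle_deg, "ndim", 1) == 0:
        return float(wrapped)
    return wrapped


def ang_diff(a_deg, b_deg):
    """Signed angular difference a - b, wrapped into (-180, 180]."""
    return wrap_angle(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))
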