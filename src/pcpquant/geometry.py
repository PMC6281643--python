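"""Shared coordinate and angle conventions.

Pixel coordinates are 0-based ``(x, y) = (column, row)`` and pixel-center
referenced; physical coordinates are in micrometres.  Angles follow the
display convention used throughout the package: 0 deg points "east"
(increasing column) and 90 deg points "up" as the image is displayed
(decreasing row), i.e. ``angle = atan2(-dy, dx)`` mapped onto [0, 360).
"""

from __future__ import annotations

import numpy as np

__all__ = ["vector_angle_deg", "unit_vector", "wrap_angle_deg"]


def wrap_angle_deg(angle_deg):
    """Map an angle (scalar or array, degrees) onto [0, 360)."""
    return np.asarray(angle_deg) % 360.0 if np.ndim(angle_deg) else float(angle_deg) % 360.0


def vector_angle_deg(dx, dy):
    """Angle of the vector (dx, dy) in image coordinates, degrees in [0, 360).

    ``dx`` is the column displacement (rightward positive) and ``dy`` the row
    displacement (downward positive); the angle is measured counter-clockwise
    on screen from the horizontal axis.
    """
    ang = np.degrees(np.arctan2(-np.asarray(dy, dtype=float), np.asarray(dx, dtype=float)))
    return wrap_angle_deg(ang)


def unit_vector(angle_deg):
    """(dx, dy) unit vector of an on-screen angle in degrees.

    Inverse of :func:`vector_angle_deg`: ``dy`` is negative for angles in
    (0, 180) because image rows grow downward.
    """
    rad = np.deg2rad(angle_deg)
    return np.cos(rad), -np.sin(rad)
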