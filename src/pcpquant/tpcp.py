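"""Translational planar cell polarity: centroid-to-patch displacement vectors.

The translational polarity of a cell is the vector drawn from the cell
centre (area centroid of its mask) to the basal body (single-cilium case)
or to the unweighted centroid of its basal-body patch (multiciliated case),
with magnitude in micrometres and on-screen angle in [0, 360) degrees.
Tissue-level coordination of the displacement directions is summarised with
the circular statistics of :mod:`pcpquant.rpcp`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import vector_angle_deg
from .rpcp import CircularSummary, circular_summary

__all__ = [
    "PolarityVector",
    "patch_centroid",
    "displacement",
    "displacement_coordination",
    "measure_field_tpcp",
]


@dataclass(frozen=True)
class PolarityVector:
    """Origin -> tip displacement with physical magnitude and angle.

    Zero-magnitude vectors carry ``angle_deg = 0`` and ``degenerate=True``
    and are excluded from angular summaries.
    """

    origin_px: tuple
    tip_px: tuple
    magnitude_um: float
    angle_deg: float
    degenerate: bool = False


def patch_centroid(points_px) -> tuple:
    """Unweighted mean of basal-body positions ((x, y) pixel pairs)."""
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    if pts.size == 0:
        raise ValueError("patch_centroid needs at least one basal body")
    return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


def displacement(origin_px, target_px, pixel_size_um: float) -> PolarityVector:
    """Displacement vector from a cell centre to a target point.

    ``origin_px`` is typically ``CellRegion.centroid_px``; ``target_px`` the
    BB-patch centroid.  Magnitude is the Euclidean pixel distance scaled by
    ``pixel_size_um``.
    """
    ox, oy = float(origin_px[0]), float(origin_px[1])
    tx, ty = float(target_px[0]), float(target_px[1])
    if not (np.isfinite(tx) and np.isfinite(ty)):
        raise ValueError("target must be finite")
    dx, dy = tx - ox, ty - oy
    mag = float(np.hypot(dx, dy) * pixel_size_um)
    if mag == 0.0:
        return PolarityVector((ox, oy), (tx, ty), 0.0, 0.0, degenerate=True)
    return PolarityVector((ox, oy), (tx, ty), mag, float(vector_angle_deg(dx, dy)))


def displacement_coordination(
    vectors, noise_floor_um: float = 0.2, csd_method: str = "circular"
) -> CircularSummary:
    """Circular summary of displacement directions across cells of a field.

    Vectors below ``noise_floor_um`` (including degenerate zero vectors)
    carry no reliable direction and are excluded; fewer than two surviving
    vectors is an error.
    """
    angles = [v.angle_deg for v in vectors if not v.degenerate and v.magnitude_um >= noise_floor_um]
    if len(angles) < 2:
        raise ValueError(
            "displacement coordination needs at least 2 vectors above the "
            f"noise floor ({noise_floor_um} um); got {len(angles)}"
        )
    return circular_summary(angles, csd_method=csd_method)


def measure_field_tpcp(
    regions,
    bb_spots,
    pixel_size_um: float,
    field_id: str = "",
) -> pd.DataFrame:
    """Per-cell displacement table for one field.

    ``regions`` are segmented :class:`~pcpquant.segmentation.CellRegion`
    objects and ``bb_spots`` cell-assigned basal-body spots.  Cells without
    any assigned basal body are excluded (reported via the ``n_bb`` of
    present rows only).
    """
    by_cell = {}
    for s in bb_spots:
        if s.cell_id is not None:
            by_cell.setdefault(s.cell_id, []).append((s.x_px, s.y_px))
    rows = []
    for region in regions:
        pts = by_cell.get(region.cell_id)
        if not pts:
            continue
        vec = displacement(region.centroid_px, patch_centroid(pts), pixel_size_um)
        rows.append(
            {
                "field_id": field_id,
                "cell_id": region.cell_id,
                "n_bb": len(pts),
                "magnitude_um": vec.magnitude_um,
                "angle_deg": vec.angle_deg,
                "degenerate": vec.degenerate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["field_id", "cell_id", "n_bb", "magnitude_um", "angle_deg", "degenerate"],
    )
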