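"""Punctate-signal detection, FOP/gamma-tubulin pairing, cell assignment.

Spots (basal bodies, FOP dots, membrane puncta) are detected as multiscale
Laplacian-of-Gaussian maxima with sub-pixel localisation by a quadratic fit
around the response peak.  FOP and gamma-tubulin dots are paired into
basal-body polarity units by mutual-nearest-neighbour matching under a
physical distance cap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "Spot",
    "BBPair",
    "SpotDetectionParams",
    "detect_spots",
    "pair_spots",
    "assign_spots_to_cells",
    "spots_to_table",
]


@dataclass(frozen=True)
class Spot:
    """A detected punctum with sub-pixel position (x=col, y=row)."""

    x_px: float
    y_px: float
    intensity: float
    response: float
    sigma_px: float
    channel: str = ""
    cell_id: int | None = None


@dataclass(frozen=True)
class BBPair:
    """A matched FOP / gamma-tubulin dot pair (one basal body)."""

    fop: Spot
    gtub: Spot
    separation_um: float
    cell_id: int | None = None


@dataclass(frozen=True)
class SpotDetectionParams:
    """LoG detection parameters.

    The detection threshold is the larger of ``threshold_rel`` times the
    maximum scale-normalised LoG response and ``threshold_snr`` times the
    robust (MAD-based) noise level of the response, so blank noise-only
    fields yield (essentially) no detections while bright fields keep a
    relative cut.
    """

    min_sigma_px: float = 1.0
    max_sigma_px: float = 2.0
    n_sigma: int = 3
    threshold_rel: float = 0.15
    threshold_snr: float = 6.0

    def __post_init__(self):
        if not (0 < self.min_sigma_px <= self.max_sigma_px):
            raise ValueError("need 0 < min_sigma_px <= max_sigma_px")
        if self.n_sigma < 1:
            raise ValueError("n_sigma must be >= 1")


def _quadratic_offset(fm1: float, f0: float, fp1: float) -> float:
    """1D sub-pixel offset of a parabola through three samples, clamped."""
    denom = fm1 - 2 * f0 + fp1
    if denom >= 0:  # not a maximum; keep the integer position
        return 0.0
    return float(np.clip(0.5 * (fm1 - fp1) / denom, -0.5, 0.5))


def detect_spots(
    channel: np.ndarray,
    params: SpotDetectionParams | None = None,
    mask: np.ndarray | None = None,
    channel_name: str = "",
) -> list:
    """Detect spots in a 2D plane; optionally restrict to a binary mask.

    Returns spots sorted by decreasing peak intensity.  An empty mask yields
    an empty list.
    """
    params = params or SpotDetectionParams()
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a 2D plane")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("mask shape must match the image")
        if not mask.any():
            return []

    sigmas = np.linspace(params.min_sigma_px, params.max_sigma_px, params.n_sigma)
    cube = np.stack([-(s**2) * ndi.gaussian_laplace(img, s) for s in sigmas])

    resp0 = cube[0]
    noise = 1.4826 * np.median(np.abs(resp0 - np.median(resp0)))
    thresh = max(params.threshold_rel * float(cube.max()), params.threshold_snr * noise)

    footprint = np.ones((3, 3, 3) if params.n_sigma > 1 else (1, 3, 3), dtype=bool)
    local_max = (cube == ndi.maximum_filter(cube, footprint=footprint)) & (cube > thresh)
    s_idx, rows, cols = np.nonzero(local_max)

    # greedy non-maximum suppression within 2 px across scales
    order = np.argsort(cube[s_idx, rows, cols])[::-1]
    kept = []
    if len(order):
        pts = np.column_stack([cols[order], rows[order]]).astype(float)
        tree_pts = []
        for i, (c, r) in enumerate(pts):
            if any((c - pc) ** 2 + (r - pr) ** 2 < 4.0 for pc, pr in tree_pts):
                continue
            tree_pts.append((c, r))
            kept.append(order[i])

    smoothed = ndi.gaussian_filter(img, params.min_sigma_px)
    n_rows, n_cols = img.shape
    spots = []
    for i in kept:
        si, r, c = int(s_idx[i]), int(rows[i]), int(cols[i])
        plane = cube[si]
        dx = dy = 0.0
        if 0 < c < n_cols - 1:
            dx = _quadratic_offset(plane[r, c - 1], plane[r, c], plane[r, c + 1])
        if 0 < r < n_rows - 1:
            dy = _quadratic_offset(plane[r - 1, c], plane[r, c], plane[r + 1, c])
        x, y = c + dx, r + dy
        if mask is not None and not mask[int(round(y)), int(round(x))]:
            continue
        spots.append(
            Spot(
                x_px=float(x),
                y_px=float(y),
                intensity=float(smoothed[r, c]),
                response=float(plane[r, c]),
                sigma_px=float(sigmas[si]),
                channel=channel_name,
            )
        )
    spots.sort(key=lambda s: (-s.intensity, s.x_px, s.y_px))
    return spots


def pair_spots(
    fop: list,
    gtub: list,
    max_pair_dist_um: float = 0.8,
    pixel_size_um: float = 1.0,
):
    """Mutual-nearest-neighbour pairing of FOP and gamma-tubulin spots.

    Returns ``(pairs, unmatched_fop, unmatched_gtub)``.  A FOP and a
    gamma-tubulin spot are paired iff each is the other's nearest neighbour
    and their separation is at most ``max_pair_dist_um``; the result is
    independent of input order and no spot appears in two pairs.
    """
    if not fop or not gtub:
        return [], list(fop), list(gtub)
    fop = sorted(fop, key=lambda s: (s.x_px, s.y_px))
    gtub = sorted(gtub, key=lambda s: (s.x_px, s.y_px))
    f_xy = np.array([[s.x_px, s.y_px] for s in fop])
    g_xy = np.array([[s.x_px, s.y_px] for s in gtub])
    max_px = max_pair_dist_um / pixel_size_um

    f_tree, g_tree = cKDTree(f_xy), cKDTree(g_xy)
    d_fg, nn_of_f = g_tree.query(f_xy)  # nearest gtub for each fop
    _, nn_of_g = f_tree.query(g_xy)  # nearest fop for each gtub

    pairs = []
    matched_g = set()
    for i_f, i_g in enumerate(nn_of_f):
        if nn_of_g[i_g] == i_f and d_fg[i_f] <= max_px:
            sep_um = float(d_fg[i_f] * pixel_size_um)
            cell = gtub[i_g].cell_id if gtub[i_g].cell_id is not None else fop[i_f].cell_id
            pairs.append(BBPair(fop=fop[i_f], gtub=gtub[i_g], separation_um=sep_um, cell_id=cell))
            matched_g.add(i_g)
    matched_f = {nn_of_g[i_g] for i_g in matched_g}
    unmatched_fop = [s for i, s in enumerate(fop) if i not in matched_f]
    unmatched_gtub = [s for i, s in enumerate(gtub) if i not in matched_g]
    return pairs, unmatched_fop, unmatched_gtub


def assign_spots_to_cells(
    spots: list,
    label_image: np.ndarray,
    pixel_size_um: float,
    max_dist_um: float = 1.0,
) -> list:
    """Attach cell ids to spots from a segmentation label image.

    A spot takes the label under its rounded position; spots on label 0
    (membrane / background) take the nearest cell within ``max_dist_um``,
    else ``None``.
    """
    labels = np.asarray(label_image)
    if labels.ndim != 2:
        raise ValueError("label image must be 2D")
    if not spots:
        return []
    # nearest labelled pixel for every background pixel, once
    dist, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    out = []
    for s in spots:
        r, c = int(round(s.y_px)), int(round(s.x_px))
        if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
            out.append(replace(s, cell_id=None))
            continue
        lab = int(labels[r, c])
        if lab == 0:
            if dist[r, c] * pixel_size_um <= max_dist_um:
                lab = int(labels[ir[r, c], ic[r, c]])
            else:
                lab = 0
        out.append(replace(s, cell_id=lab if lab > 0 else None))
    return out


def spots_to_table(spots: list, pixel_size_um: float, field_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "field_id": field_id,
                "channel": s.channel,
                "x_px": s.x_px,
                "y_px": s.y_px,
                "x_um": s.x_px * pixel_size_um,
                "y_um": s.y_px * pixel_size_um,
                "intensity": s.intensity,
                "cell_id": s.cell_id,
            }
            for s in spots
        ],
        columns=["field_id", "channel", "x_px", "y_px", "x_um", "y_um", "intensity", "cell_id"],
    )


def pairs_to_table(pairs: list, pixel_size_um: float, field_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "field_id": field_id,
                "cell_id": p.cell_id,
                "fop_x_px": p.fop.x_px,
                "fop_y_px": p.fop.y_px,
                "gtub_x_px": p.gtub.x_px,
                "gtub_y_px": p.gtub.y_px,
                "separation_um": p.separation_um,
            }
            for p in pairs
        ],
        columns=[
            "field_id", "cell_id", "fop_x_px", "fop_y_px",
            "gtub_x_px", "gtub_y_px", "separation_um",
        ],
    )
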