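"""Synthetic multiciliated-epithelium image generator with known ground truth.

The forward model emulates en-face confocal fields of the lateral-ventricle
ependyma: a sheet of convex-ish polygonal cells (Voronoi tessellation of
Lloyd-relaxed Poisson seeds), each carrying a patch of basal bodies (BBs)
displaced from the cell centroid (translational polarity), per-BB rotational
angles drawn around a cell-mean direction (rotational polarity), a junctional
membrane channel, membrane-enriched vs uniform marker channels, and punctate
membrane dots.  A Gaussian point-spread function and Poisson+Gaussian noise
are applied last; the ground-truth tables record every sampled quantity
before noise and are the oracle for all downstream stages.

Channels rendered (roles in parentheses):

- ``membrane``  junctional marker outlining cell contours (beta-catenin role)
- ``gtub``      basal-body dots (gamma-tubulin role)
- ``fop``       basal-foot-opposite dots paired with each BB (FOP role)
- ``enriched``  membrane-enriched diffuse marker (Vangl2/Fzd3 role)
- ``uniform``   spatially uniform marker, the non-enriched control
- ``puncta``    punctate dots on the membrane (p-MLC role)

Intensities live on a 16-bit scale: background 100, spot/membrane peak
amplitude 1000; the diffuse enriched marker uses a cytoplasm level of 250
with the membrane level multiplied by ``membrane_to_cytoplasm_ratio``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.ops
from scipy import ndimage as ndi
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon

from .geometry import unit_vector, vector_angle_deg, wrap_angle_deg
from .io import ImageStack, config_hash, write_csv, write_field

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "GroundTruth",
    "generate_sheet",
    "generate_two_genotype_experiment",
]

BACKGROUND = 100.0
AMPLITUDE = 1000.0
CYTOPLASM_LEVEL = 250.0
INTENSITY_MAX = 65535


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: Gaussian read noise plus optional Poisson shot noise."""

    gaussian_sd: float = 100.0
    poisson: bool = True

    def __post_init__(self):
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated field.

    Physical quantities are in micrometres.  ``field_size_um`` divided by
    ``pixel_size_um`` must give integer pixel dimensions.
    """

    field_size_um: tuple = (50.0, 50.0)
    pixel_size_um: float = 0.1
    n_cells: int = 25
    bb_per_cell: tuple = (12, 22)
    # translational polarity
    displacement_um: float = 2.0
    displacement_angle_deg: float = 0.0
    displacement_coordination_kappa: float = 10.0
    # rotational polarity
    rotation_angle_deg: float = 0.0
    rotation_coordination_kappa: float = 5.0
    rotation_kappa: float = 8.0
    fop_offset_um: float = 0.3
    # BB patch geometry; spacing > 2 * fop_offset_um keeps each FOP dot
    # unambiguously closest to its own basal body
    bb_patch_radius_um: float = 2.0
    bb_min_spacing_um: float = 0.65
    # diffuse and punctate markers
    membrane_to_cytoplasm_ratio: float = 4.0
    dot_density_per_um: float = 0.5
    # optics / detector
    psf_sigma_um: float = 0.1
    psf_sigma_z_um: float = 0.4
    membrane_width_um: float = 0.3
    noise: NoiseModel = field(default_factory=NoiseModel)
    # axial structure (z-stacks for docking analyses)
    z_planes: int = 1
    z_step_um: float = 0.75
    docked_fraction: float = 1.0
    apical_z_um: float = 1.5
    bb_z_jitter_um: float = 0.15
    scatter_depth_um: float = 4.0
    seed: int = 0

    def __post_init__(self):
        w, h = self.field_size_um
        for name, val in [
            ("field width", w),
            ("field height", h),
            ("pixel_size_um", self.pixel_size_um),
            ("fop_offset_um", self.fop_offset_um),
            ("bb_patch_radius_um", self.bb_patch_radius_um),
            ("psf_sigma_um", self.psf_sigma_um),
            ("membrane_width_um", self.membrane_width_um),
            ("z_step_um", self.z_step_um),
            ("membrane_to_cytoplasm_ratio", self.membrane_to_cytoplasm_ratio),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be > 0, got {val}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        lo, hi = self.bb_per_cell
        if not (1 <= lo <= hi):
            raise ValueError("bb_per_cell must be an increasing range of ints >= 1")
        for name, val in [
            ("displacement_coordination_kappa", self.displacement_coordination_kappa),
            ("rotation_coordination_kappa", self.rotation_coordination_kappa),
            ("rotation_kappa", self.rotation_kappa),
        ]:
            if val < 0:
                raise ValueError(f"{name} (von Mises concentration) must be >= 0")
        if self.displacement_um < 0:
            raise ValueError("displacement_um must be >= 0")
        if not 0.0 <= self.docked_fraction <= 1.0:
            raise ValueError("docked_fraction must be in [0, 1]")
        for dim, val in [("width", w), ("height", h)]:
            n = val / self.pixel_size_um
            if abs(n - round(n)) > 1e-6:
                raise ValueError(
                    f"field {dim} {val} um is not an integer number of "
                    f"{self.pixel_size_um} um pixels"
                )

    @property
    def shape_px(self) -> tuple:
        """(n_rows, n_cols) of the rendered image."""
        w, h = self.field_size_um
        return (int(round(h / self.pixel_size_um)), int(round(w / self.pixel_size_um)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """True per-cell and per-BB geometry of a simulated field (pre-noise).

    ``cells`` has one row per cell (centroid, polygon WKT, true displacement
    vector, true mean rotational angle, docked flag, apical z); ``bbs`` one
    row per basal body (gamma-tubulin and FOP dot positions, true angle, z);
    ``puncta`` one row per membrane punctum.
    """

    cells: pd.DataFrame
    bbs: pd.DataFrame
    puncta: pd.DataFrame
    pixel_size_um: float
    z_step_um: float | None = None

    def polygons(self) -> list:
        """Shapely cell polygons in pixel coordinates, ordered as ``cells``."""
        return [shapely.from_wkt(w) for w in self.cells["polygon_wkt"]]

    def write(self, directory, stem: str, provenance: dict | None = None) -> dict:
        directory = Path(directory)
        paths = {
            "cells": write_csv(self.cells, directory / f"{stem}_cells.csv", provenance),
            "bbs": write_csv(self.bbs, directory / f"{stem}_bbs.csv", provenance),
            "puncta": write_csv(self.puncta, directory / f"{stem}_puncta.csv", provenance),
        }
        return paths

    @classmethod
    def read(cls, directory, stem: str, pixel_size_um: float, z_step_um=None):
        from .io import read_csv

        directory = Path(directory)
        return cls(
            cells=read_csv(directory / f"{stem}_cells.csv"),
            bbs=read_csv(directory / f"{stem}_bbs.csv"),
            puncta=read_csv(directory / f"{stem}_puncta.csv"),
            pixel_size_um=pixel_size_um,
            z_step_um=z_step_um,
        )


# ---------------------------------------------------------------------------
# geometry sampling


def _bounded_voronoi(points: np.ndarray, width: float, height: float) -> list:
    """Voronoi polygons of ``points`` clipped to the field rectangle.

    Seeds are mirrored across the four box edges so every region of an
    interior seed is bounded; regions are then intersected with the box.
    """
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, width), (1, 0.0), (1, height)):
        m = points.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    box = Polygon([(0, 0), (width, 0), (width, height), (0, height)])
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(box)
        polys.append(poly)
    return polys


def _tessellate(rng, cfg: SimulationConfig) -> list:
    """Lloyd-relaxed Voronoi tessellation of the field, in um coordinates."""
    w, h = cfg.field_size_um
    pts = np.column_stack([rng.uniform(0, w, cfg.n_cells), rng.uniform(0, h, cfg.n_cells)])
    for _ in range(2):  # two Lloyd iterations: convex-ish, fairly uniform cells
        polys = _bounded_voronoi(pts, w, h)
        pts = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    return _bounded_voronoi(pts, w, h)


def _sample_disc_points(rng, center, radius, n, min_spacing, region: Polygon):
    """Place up to ``n`` points in a disc inside ``region``, min spacing apart.

    Points sit on a randomly rotated and offset hexagonal lattice with
    per-point jitter; the lattice pitch guarantees the spacing even after
    jitter, mimicking the quasi-regular packing of basal bodies in an
    apical patch.  Nodes nearest the patch centre are used first, so the
    point-cloud centroid stays close to ``center``.
    """
    cx, cy = center
    allowed = Point(cx, cy).buffer(radius).intersection(region)
    if allowed.is_empty or allowed.area <= 0:
        return []
    jitter = 0.14  # fraction of pitch; spacing >= pitch * (1 - 2*jitter)
    pitch_area = np.sqrt(2 * allowed.area / (np.sqrt(3) * max(n, 1)))
    pitch = max(min_spacing / (1 - 2 * jitter), 0.95 * pitch_area)
    theta = rng.uniform(0, np.pi / 3)
    ct, st = np.cos(theta), np.sin(theta)
    off = rng.uniform(0, pitch, size=2)
    half_extent = radius + 2 * pitch
    n_steps = int(np.ceil(half_extent / (pitch * np.sqrt(3) / 2))) + 1
    nodes = []
    for i in range(-n_steps, n_steps + 1):
        y0 = i * pitch * np.sqrt(3) / 2 + off[1]
        row_shift = (i % 2) * pitch / 2 + off[0]
        for j in range(-n_steps, n_steps + 1):
            x0 = j * pitch + row_shift
            x = cx + ct * x0 - st * y0
            y = cy + st * x0 + ct * y0
            nodes.append((x, y))
    nodes = [p for p in nodes if allowed.contains(Point(p))]
    nodes.sort(key=lambda p: (p[0] - cx) ** 2 + (p[1] - cy) ** 2)
    chosen = nodes[:n]
    if not chosen:
        # tiny allowed region between lattice nodes: one BB at its pole
        pole = allowed.representative_point()
        return [(pole.x, pole.y)]
    max_j = jitter * pitch
    out = []
    for x, y in chosen:
        r = max_j * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        out.append((x + r * np.cos(phi), y + r * np.sin(phi)))
    # recentre the patch on its target so the patch centroid tracks the
    # intended displacement; back off when the shift would leave the region
    arr = np.asarray(out)
    shift = np.array([cx, cy]) - arr.mean(axis=0)
    for scale in (1.0, 0.5, 0.25, 0.0):
        moved = arr + scale * shift
        if all(region.buffer(1e-9).contains(Point(p)) for p in moved):
            arr = moved
            break
    return [tuple(p) for p in arr]


def _shrink_to_fit(poly: Polygon, radius: float) -> tuple:
    """Largest fraction of ``radius`` whose inward buffer of poly is nonempty."""
    for f in (1.0, 0.85, 0.7, 0.55, 0.4, 0.25):
        safe = poly.buffer(-(radius * f + 0.1))
        if not safe.is_empty and safe.area > 0:
            return safe, radius * f
    raise ValueError(
        "simulated cells are smaller than the basal-body patch; decrease "
        "bb_patch_radius_um or n_cells (mean cell area "
        f"{poly.area:.1f} um^2 vs patch radius {radius} um)"
    )


def _on_border(a, b, width: float, height: float, tol: float = 1e-4) -> bool:
    """True when the segment a-b lies on the field boundary (clipped edge)."""
    for coord, bound in ((0, 0.0), (0, width), (1, 0.0), (1, height)):
        if abs(a[coord] - bound) < tol and abs(b[coord] - bound) < tol:
            return True
    return False


def _unique_edges(polys: list, field_size_um) -> list:
    """Deduplicated junctional segments across the tessellation.

    Segments lying on the field boundary are clipping artefacts, not cell
    junctions, and carry no membrane signal.
    """
    w, h = field_size_um
    seen = {}
    for poly in polys:
        xs, ys = poly.exterior.coords.xy
        for i in range(len(xs) - 1):
            a = (round(xs[i], 4), round(ys[i], 4))
            b = (round(xs[i + 1], 4), round(ys[i + 1], 4))
            if _on_border(a, b, w, h):
                continue
            key = (a, b) if a <= b else (b, a)
            seen.setdefault(key, (a, b))
    return list(seen.values())


def _apical_z_map(cfg: SimulationConfig, shape_px):
    """Apical-surface depth (um) per pixel; a flat plane by default."""
    return np.full(shape_px, cfg.apical_z_um)


def sample_geometry(cfg: SimulationConfig, rng=None):
    """Sample all ground-truth geometry for one field (no rendering).

    Returns a :class:`GroundTruth`; positions are stored in pixels and the
    cell polygons as WKT in pixel coordinates.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    w, h = cfg.field_size_um
    mean_area = w * h / cfg.n_cells
    patch_area = np.pi * cfg.bb_patch_radius_um**2
    if mean_area < 1.5 * patch_area:
        raise ValueError(
            f"configuration implies mean cell area {mean_area:.1f} um^2, too "
            f"small for a basal-body patch of radius {cfg.bb_patch_radius_um} um "
            f"({patch_area:.1f} um^2); reduce n_cells or the patch radius"
        )
    polys = _tessellate(rng, cfg)
    px = cfg.pixel_size_um

    cell_rows, bb_rows = [], []
    for cid, poly in enumerate(polys, start=1):
        c = poly.centroid
        safe, r_eff = _shrink_to_fit(poly, cfg.bb_patch_radius_um)
        # translational polarity: displaced BB-patch centre
        phi = np.degrees(
            rng.vonmises(np.deg2rad(cfg.displacement_angle_deg), cfg.displacement_coordination_kappa)
        )
        mag = max(0.0, rng.normal(cfg.displacement_um, 0.15 * cfg.displacement_um))
        ux, uy = unit_vector(phi)
        target = Point(c.x + mag * ux, c.y + mag * uy)
        if not safe.contains(target):
            target = shapely.ops.nearest_points(safe, target)[0]

        n_bb = int(rng.integers(cfg.bb_per_cell[0], cfg.bb_per_cell[1] + 1))
        # BBs may sit anywhere in the cell interior (small membrane margin);
        # the patch-centre constraint above already keeps the disc inside
        bb_region = poly.buffer(-0.15)
        if bb_region.is_empty:
            bb_region = safe
        bb_pts = _sample_disc_points(
            rng, (target.x, target.y), r_eff, n_bb, cfg.bb_min_spacing_um, bb_region
        )
        if not bb_pts:
            raise ValueError(
                f"no basal bodies could be placed in cell {cid}; the "
                "configuration implies cells smaller than the BB patch"
            )
        # the true displacement is measured to the realised patch centroid,
        # i.e. the quantity the pipeline estimates, recorded before noise
        patch = np.mean(bb_pts, axis=0)
        true_dx, true_dy = patch[0] - c.x, patch[1] - c.y
        true_mag = float(np.hypot(true_dx, true_dy))
        true_ang = vector_angle_deg(true_dx, true_dy) if true_mag > 0 else 0.0
        # rotational polarity: per-BB beat angles about the cell mean
        mu_c = np.degrees(
            rng.vonmises(np.deg2rad(cfg.rotation_angle_deg), cfg.rotation_coordination_kappa)
        )
        docked = bool(rng.uniform() < cfg.docked_fraction)
        apical_z = cfg.apical_z_um
        max_z = (cfg.z_planes - 1) * cfg.z_step_um if cfg.z_planes > 1 else 0.0
        for bid, (bx, by) in enumerate(bb_pts):
            theta = wrap_angle_deg(
                np.degrees(rng.vonmises(np.deg2rad(mu_c), cfg.rotation_kappa))
            )
            tx, ty = unit_vector(theta)
            fx, fy = bx - cfg.fop_offset_um * tx, by - cfg.fop_offset_um * ty
            if cfg.z_planes > 1:
                if docked:
                    z = apical_z + rng.normal(0.0, cfg.bb_z_jitter_um)
                else:
                    z = apical_z + rng.uniform(0.8, cfg.scatter_depth_um)
                z = float(np.clip(z, 0.0, max_z))
            else:
                z = 0.0
            bb_rows.append(
                {
                    "cell_id": cid,
                    "bb_id": bid,
                    "gtub_x_px": bx / px,
                    "gtub_y_px": by / px,
                    "fop_x_px": fx / px,
                    "fop_y_px": fy / px,
                    "angle_deg": float(theta),
                    "z_um": z,
                }
            )
        poly_px = shapely.transform(poly, lambda a: a / px)
        cell_rows.append(
            {
                "cell_id": cid,
                "centroid_x_px": c.x / px,
                "centroid_y_px": c.y / px,
                "disp_magnitude_um": true_mag,
                "disp_angle_deg": float(true_ang),
                "mean_rotation_deg": float(wrap_angle_deg(mu_c)),
                "n_bb": len(bb_pts),
                "docked": docked,
                "apical_z_um": apical_z,
                "polygon_wkt": shapely.to_wkt(poly_px, rounding_precision=3),
            }
        )

    # membrane puncta on deduplicated tessellation edges (shared walls once)
    punct_rows = []
    for (x0, y0), (x1, y1) in _unique_edges(polys, cfg.field_size_um):
        length = float(np.hypot(x1 - x0, y1 - y0))
        for t in rng.uniform(size=rng.poisson(cfg.dot_density_per_um * length)):
            punct_rows.append(
                {"x_px": (x0 + t * (x1 - x0)) / px, "y_px": (y0 + t * (y1 - y0)) / px}
            )

    return GroundTruth(
        cells=pd.DataFrame(cell_rows),
        bbs=pd.DataFrame(
            bb_rows,
            columns=[
                "cell_id", "bb_id", "gtub_x_px", "gtub_y_px",
                "fop_x_px", "fop_y_px", "angle_deg", "z_um",
            ],
        ),
        puncta=pd.DataFrame(punct_rows, columns=["x_px", "y_px"]),
        pixel_size_um=px,
        z_step_um=cfg.z_step_um if cfg.z_planes > 1 else None,
    )


# ---------------------------------------------------------------------------
# rendering


def _add_gaussian_spots(img, xs, ys, amplitudes, sigma_px):
    """Accumulate sub-pixel Gaussian spots into ``img`` (in place)."""
    half = max(3, int(np.ceil(5 * sigma_px)))
    n_rows, n_cols = img.shape
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), np.shape(xs))
    for x, y, amp in zip(np.atleast_1d(xs), np.atleast_1d(ys), amplitudes):
        c0, r0 = int(round(x)), int(round(y))
        cs = slice(max(0, c0 - half), min(n_cols, c0 + half + 1))
        rs = slice(max(0, r0 - half), min(n_rows, r0 + half + 1))
        if cs.start >= cs.stop or rs.start >= rs.stop:
            continue
        cc = np.arange(cs.start, cs.stop)
        rr = np.arange(rs.start, rs.stop)
        g = np.exp(-((cc - x) ** 2)[None, :] / (2 * sigma_px**2)) * np.exp(
            -((rr - y) ** 2)[:, None] / (2 * sigma_px**2)
        )
        img[rs, cs] += amp * g


def _membrane_ribbon(gt: GroundTruth, shape_px, width_px: int) -> np.ndarray:
    """Binary membrane ribbon: rasterised polygon edges dilated to width."""
    from skimage.draw import line

    skel = np.zeros(shape_px, dtype=bool)
    field_px = (float(shape_px[1]), float(shape_px[0]))
    for (x0, y0), (x1, y1) in _unique_edges(gt.polygons(), field_px):
        rr, cc = line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        ok = (rr >= 0) & (rr < shape_px[0]) & (cc >= 0) & (cc < shape_px[1])
        skel[rr[ok], cc[ok]] = True
    n_dil = max(0, (width_px - 1) // 2)
    if n_dil:
        skel = ndi.binary_dilation(skel, structure=np.ones((3, 3)), iterations=n_dil)
    return skel


def render_plane_images(cfg: SimulationConfig, gt: GroundTruth) -> dict:
    """Noise-free 2D channel images (float) for a single-plane field."""
    shape = cfg.shape_px
    px = cfg.pixel_size_um
    sigma_px = cfg.psf_sigma_um / px
    width_px = max(1, int(round(cfg.membrane_width_um / px)))
    ribbon = _membrane_ribbon(gt, shape, width_px)

    membrane = ndi.gaussian_filter(np.where(ribbon, AMPLITUDE, 0.0), sigma_px)
    gtub = np.zeros(shape)
    _add_gaussian_spots(gtub, gt.bbs["gtub_x_px"].to_numpy(), gt.bbs["gtub_y_px"].to_numpy(), AMPLITUDE, sigma_px)
    fop = np.zeros(shape)
    _add_gaussian_spots(fop, gt.bbs["fop_x_px"].to_numpy(), gt.bbs["fop_y_px"].to_numpy(), AMPLITUDE, sigma_px)
    enriched = np.where(ribbon, CYTOPLASM_LEVEL * cfg.membrane_to_cytoplasm_ratio, CYTOPLASM_LEVEL)
    enriched = ndi.gaussian_filter(enriched, sigma_px)
    uniform = np.full(shape, CYTOPLASM_LEVEL)
    puncta = np.zeros(shape)
    if len(gt.puncta):
        _add_gaussian_spots(puncta, gt.puncta["x_px"].to_numpy(), gt.puncta["y_px"].to_numpy(), AMPLITUDE, sigma_px)

    return {
        "membrane": membrane,
        "gtub": gtub,
        "fop": fop,
        "enriched": enriched,
        "uniform": uniform,
        "puncta": puncta,
    }


def _apply_noise(img: np.ndarray, noise: NoiseModel, rng) -> np.ndarray:
    out = img + BACKGROUND
    if noise.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(np.round(out), 0, INTENSITY_MAX).astype(np.uint16)


def generate_sheet(cfg: SimulationConfig):
    """Simulate one field: returns ``(ImageStack, GroundTruth)``.

    A fixed ``cfg`` (including its seed) yields byte-identical images and
    ground-truth tables on every call.
    """
    rng = np.random.default_rng(cfg.seed)
    gt = sample_geometry(cfg, rng)
    channels = ("membrane", "gtub", "fop", "enriched", "uniform", "puncta")
    planes = render_plane_images(cfg, gt)

    noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    if cfg.z_planes == 1:
        data = np.stack([_apply_noise(planes[ch], cfg.noise, noise_rng) for ch in channels])
        stack = ImageStack(data, channels, cfg.pixel_size_um)
        return stack, gt

    # z-stack: modulate each channel by a Gaussian axial profile
    sigma_z = cfg.psf_sigma_z_um
    z_of_plane = np.arange(cfg.z_planes) * cfg.z_step_um
    apical = _apical_z_map(cfg, cfg.shape_px)
    vols = {ch: np.zeros((cfg.z_planes,) + cfg.shape_px) for ch in channels}
    surface_channels = ("membrane", "enriched", "uniform", "puncta")
    for k, zk in enumerate(z_of_plane):
        w_surface = np.exp(-((zk - apical) ** 2) / (2 * sigma_z**2))
        for ch in surface_channels:
            vols[ch][k] = planes[ch] * w_surface
    sigma_px = cfg.psf_sigma_um / cfg.pixel_size_um
    for k, zk in enumerate(z_of_plane):
        wz = np.exp(-((zk - gt.bbs["z_um"].to_numpy()) ** 2) / (2 * sigma_z**2))
        keep = wz > 1e-3
        if keep.any():
            _add_gaussian_spots(
                vols["gtub"][k],
                gt.bbs["gtub_x_px"].to_numpy()[keep],
                gt.bbs["gtub_y_px"].to_numpy()[keep],
                AMPLITUDE * wz[keep],
                sigma_px,
            )
            _add_gaussian_spots(
                vols["fop"][k],
                gt.bbs["fop_x_px"].to_numpy()[keep],
                gt.bbs["fop_y_px"].to_numpy()[keep],
                AMPLITUDE * wz[keep],
                sigma_px,
            )
    data = np.stack([_apply_noise(vols[ch], cfg.noise, noise_rng) for ch in channels])
    stack = ImageStack(data, channels, cfg.pixel_size_um, z_step_um=cfg.z_step_um)
    return stack, gt


# ---------------------------------------------------------------------------
# two-genotype experiments


def generate_two_genotype_experiment(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
    n_fields: int,
    seed: int,
    out_dir,
    labels=("WT", "KO"),
) -> pd.DataFrame:
    """Write paired fields for two genotypes plus ground truth and a manifest.

    Per-field seeds are derived deterministically from ``seed``.  Returns the
    manifest DataFrame (one row per field) which is also written as
    ``manifest.csv`` in ``out_dir``.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if (
        config_a.field_size_um != config_b.field_size_um
        or config_a.pixel_size_um != config_b.pixel_size_um
    ):
        raise ValueError("both genotypes must share field and pixel geometry")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    field_seeds = rng.integers(0, 2**31 - 1, size=2 * n_fields)

    rows = []
    i_seed = 0
    for label, cfg in zip(labels, (config_a, config_b)):
        for i in range(n_fields):
            fcfg = dataclasses.replace(cfg, seed=int(field_seeds[i_seed]))
            i_seed += 1
            stack, gt = generate_sheet(fcfg)
            stem = f"{label}_f{i:02d}"
            prov = {"config_hash": config_hash(fcfg.to_dict()), "seed": fcfg.seed}
            tiff_path = write_field(out_dir / f"{stem}.tif", stack)
            gt.write(out_dir, stem, prov)
            rows.append(
                {
                    "field_id": stem,
                    "genotype": label,
                    "image": tiff_path.name,
                    "seed": fcfg.seed,
                    "pixel_size_um": fcfg.pixel_size_um,
                    "z_planes": fcfg.z_planes,
                    "n_cells_true": len(gt.cells),
                }
            )
    manifest = pd.DataFrame(rows)
    write_csv(manifest, out_dir / "manifest.csv", {"seed": seed})
    return manifest
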