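"""Shared fixtures: simulated fields reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from pcpquant.segmentation import MembraneMaskParams, segment_cells

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")
from pcpquant.simulate import SimulationConfig, generate_sheet

PIXEL = 0.1  # um/px used by every fixture


def make_config(**overrides) -> SimulationConfig:
    defaults = dict(seed=1)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_field():
    """One default 50x50 um field (WT-like polarity), seed 1."""
    return generate_sheet(make_config())


@pytest.fixture(scope="session")
def segmented_default(default_field):
    """Label image, regions, skeleton and selection of the default field."""
    stack, _ = default_field
    return segment_cells(stack.plane("membrane"), MembraneMaskParams(), PIXEL)


@pytest.fixture(scope="session")
def big_cell_field():
    """Few large cells with 40 basal bodies each (spot-detection scenario)."""
    cfg = make_config(
        field_size_um=(30.0, 30.0),
        n_cells=4,
        bb_per_cell=(40, 40),
        bb_patch_radius_um=4.0,
        displacement_um=0.5,
        seed=7,
    )
    return generate_sheet(cfg)


def interior_polygons(gt, shape_px):
    """Ground-truth polygons fully inside the field (not clipped)."""
    import shapely

    box = shapely.box(0.01, 0.01, shape_px[1] - 0.01, shape_px[0] - 0.01)
    return [p for p in gt.polygons() if p.buffer(-1e-6).within(box)]


def match_regions_to_truth(regions, gt):
    """Map each segmented region to the ground-truth cell containing its centroid."""
    from shapely.geometry import Point

    polys = gt.polygons()
    mapping = {}
    for r in regions:
        pt = Point(r.centroid_px)
        for i, poly in enumerate(polys):
            if poly.contains(pt):
                mapping[r.cell_id] = int(gt.cells["cell_id"].iloc[i])
                break
    return mapping


def circ_diff_deg(a, b):
    """Signed smallest angular difference a-b in degrees."""
    return (np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0
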