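"""Tests of spot detection, FOP/gamma-tubulin pairing and cell assignment."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from pcpquant.spots import (
    Spot,
    SpotDetectionParams,
    assign_spots_to_cells,
    detect_spots,
    pair_spots,
)

from conftest import PIXEL, make_config, match_regions_to_truth


def gaussian_dot_image(x, y, size=64, amp=1000.0, sigma=1.2, background=100.0):
    cc, rr = np.meshgrid(np.arange(size), np.arange(size))
    return background + amp * np.exp(-((cc - x) ** 2 + (rr - y) ** 2) / (2 * sigma**2))


def one_to_one_matches(det_xy, true_xy, radius=2.0):
    """Number of optimal one-to-one matches within ``radius`` pixels."""
    if len(det_xy) == 0 or len(true_xy) == 0:
        return 0
    d = cdist(true_xy, det_xy)
    ri, ci = linear_sum_assignment(np.minimum(d, 2 * radius))
    return int((d[ri, ci] <= radius).sum())


class TestDetectSpots:
    def test_single_dot_subpixel_position(self):
        img = gaussian_dot_image(30.3, 24.7)
        spots = detect_spots(img)
        assert len(spots) == 1
        assert spots[0].x_px == pytest.approx(30.3, abs=0.25)
        assert spots[0].y_px == pytest.approx(24.7, abs=0.25)

    def test_blank_noise_false_positive_rate(self):
        """On pure-noise fields, false positives stay below 0.1 per field."""
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            img = 100.0 + rng.normal(0, 100.0, size=(500, 500))
            total += len(detect_spots(img))
        assert total / 20 <= 0.1

    def test_recall_precision_on_crowded_cells(self, big_cell_field):
        """Recall and precision >= 0.95 against true basal bodies at SNR 10."""
        stack, gt = big_cell_field
        spots = detect_spots(stack.plane("gtub"))
        det = np.array([[s.x_px, s.y_px] for s in spots])
        true = gt.bbs[["gtub_x_px", "gtub_y_px"]].to_numpy()
        n_match = one_to_one_matches(det, true)
        assert n_match / len(true) >= 0.95  # recall
        assert n_match / len(det) >= 0.95  # precision

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        img = 100.0 + rng.normal(0, 30.0, size=(80, 80))
        for x, y in [(20.2, 30.5), (51.7, 44.1)]:
            img += gaussian_dot_image(x, y, size=80, background=0.0)
        shifted = np.roll(img, (5, 7), axis=(0, 1))
        a = sorted((s.x_px, s.y_px) for s in detect_spots(img))
        b = sorted((s.x_px - 7, s.y_px - 5) for s in detect_spots(shifted))
        assert len(a) == len(b) == 2
        for (ax, ay), (bx, by) in zip(a, b):
            assert ax == pytest.approx(bx, abs=1e-9)
            assert ay == pytest.approx(by, abs=1e-9)

    def test_empty_mask_returns_empty(self):
        img = gaussian_dot_image(30, 30)
        assert detect_spots(img, mask=np.zeros_like(img, dtype=bool)) == []

    def test_mask_restricts_detections(self):
        img = gaussian_dot_image(16, 16) + gaussian_dot_image(48, 48) - 100.0
        mask = np.zeros(img.shape, dtype=bool)
        mask[:32, :32] = True
        spots = detect_spots(img, mask=mask)
        assert len(spots) == 1
        assert spots[0].x_px == pytest.approx(16, abs=0.5)


def _spot(x, y, cell_id=None):
    return Spot(x_px=x, y_px=y, intensity=1.0, response=1.0, sigma_px=1.0, cell_id=cell_id)


class TestPairSpots:
    def test_singleton_within_range(self):
        pairs, uf, ug = pair_spots([_spot(0, 0)], [_spot(3, 0)], 0.8, PIXEL)
        assert len(pairs) == 1 and not uf and not ug
        assert pairs[0].separation_um == pytest.approx(0.3)

    def test_distance_filter(self):
        pairs, uf, ug = pair_spots([_spot(0, 0)], [_spot(12, 0)], 0.8, PIXEL)
        assert pairs == [] and len(uf) == 1 and len(ug) == 1

    def test_symmetric_in_input_order(self):
        rng = np.random.default_rng(0)
        f = [_spot(x, y) for x, y in rng.uniform(0, 100, size=(30, 2))]
        g = [_spot(x + 2, y) for x, y in rng.uniform(0, 100, size=(30, 2))]
        p1, _, _ = pair_spots(f, g, 0.8, PIXEL)
        p2, _, _ = pair_spots(list(reversed(f)), list(reversed(g)), 0.8, PIXEL)
        key = lambda p: (p.fop.x_px, p.fop.y_px)
        assert sorted(map(key, p1)) == sorted(map(key, p2))

    def test_agrees_with_hungarian_assignment(self, default_field):
        """Mutual-NN pairing matches min-cost assignment on >= 98% of pairs."""
        stack, gt = default_field
        fop = detect_spots(stack.plane("fop"))
        gtub = detect_spots(stack.plane("gtub"))
        pairs, _, _ = pair_spots(fop, gtub, 0.8, PIXEL)
        assert len(pairs) >= 200
        f_xy = np.array([[s.x_px, s.y_px] for s in sorted(fop, key=lambda s: (s.x_px, s.y_px))])
        g_xy = np.array([[s.x_px, s.y_px] for s in sorted(gtub, key=lambda s: (s.x_px, s.y_px))])
        cap = 0.8 / PIXEL
        d = cdist(f_xy, g_xy)
        ri, ci = linear_sum_assignment(np.minimum(d, 2 * cap))
        hungarian = {
            (tuple(f_xy[i]), tuple(g_xy[j])) for i, j in zip(ri, ci) if d[i, j] <= cap
        }
        ours = {((p.fop.x_px, p.fop.y_px), (p.gtub.x_px, p.gtub.y_px)) for p in pairs}
        agreement = len(ours & hungarian) / max(len(hungarian), 1)
        assert agreement >= 0.98


class TestAssignSpotsToCells:
    def test_interior_and_near_membrane_rules(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[5:18, 5:18] = 1
        labels[22:36, 22:36] = 2
        spots = [_spot(10, 10), _spot(18.6, 10), _spot(1, 39)]
        out = assign_spots_to_cells(spots, labels, pixel_size_um=0.5, max_dist_um=1.0)
        assert out[0].cell_id == 1  # interior pixel
        assert out[1].cell_id == 1  # 2 px (1 um) from cell 1
        assert out[2].cell_id is None  # too far from any cell

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_spots_to_cells([_spot(0, 0)], np.zeros((4, 4, 4), dtype=int), 0.1)

    def test_bb_spots_assigned_to_true_cells(self, default_field, segmented_default):
        """>= 99% of basal-body spots land in their ground-truth cell."""
        stack, gt = default_field
        labels, regions, _, _ = segmented_default
        spots = assign_spots_to_cells(detect_spots(stack.plane("gtub")), labels, PIXEL)
        region_to_true = match_regions_to_truth(regions, gt)
        true_xy = gt.bbs[["gtub_x_px", "gtub_y_px"]].to_numpy()
        tree = cKDTree(true_xy)
        checked = correct = 0
        for s in spots:
            if s.cell_id is None or s.cell_id not in region_to_true:
                continue
            d, i = tree.query([s.x_px, s.y_px])
            if d > 2:
                continue
            checked += 1
            correct += int(gt.bbs["cell_id"].iloc[i] == region_to_true[s.cell_id])
        assert checked > 100
        assert correct / checked >= 0.99
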