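"""Tests of the synthetic epithelium generator and its ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point

from pcpquant.geometry import vector_angle_deg
from pcpquant.io import read_field, write_field
from pcpquant.rpcp import circular_summary, vonmises_csd_deg
from pcpquant.simulate import (
    GroundTruth,
    NoiseModel,
    SimulationConfig,
    generate_sheet,
    generate_two_genotype_experiment,
    sample_geometry,
)

from conftest import circ_diff_deg, make_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pixel_size_um": -0.1},
            {"n_cells": 0},
            {"rotation_kappa": -1.0},
            {"docked_fraction": 1.5},
            {"bb_per_cell": (10, 5)},
            {"field_size_um": (50.05, 50.0)},  # non-integer pixel grid
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_cells_smaller_than_patch_rejected(self):
        cfg = make_config(field_size_um=(20.0, 20.0), n_cells=40)
        with pytest.raises(ValueError, match="patch"):
            sample_geometry(cfg)


class TestGroundTruthGeometry:
    def test_every_bb_inside_its_cell_polygon(self, default_field):
        _, gt = default_field
        polys = {cid: poly for cid, poly in zip(gt.cells["cell_id"], gt.polygons())}
        for row in gt.bbs.itertuples():
            assert polys[row.cell_id].contains(Point(row.gtub_x_px, row.gtub_y_px))

    def test_angles_in_range(self, default_field):
        _, gt = default_field
        for col, frame in [("angle_deg", gt.bbs), ("disp_angle_deg", gt.cells),
                           ("mean_rotation_deg", gt.cells)]:
            vals = frame[col].to_numpy()
            assert np.all((vals >= 0) & (vals < 360))

    def test_fop_to_gtub_direction_matches_recorded_angle(self, default_field):
        _, gt = default_field
        ang = vector_angle_deg(
            gt.bbs["gtub_x_px"] - gt.bbs["fop_x_px"],
            gt.bbs["gtub_y_px"] - gt.bbs["fop_y_px"],
        )
        assert np.max(np.abs(circ_diff_deg(ang, gt.bbs["angle_deg"]))) < 1e-6

    def test_fop_offset_distance(self, default_field):
        _, gt = default_field
        d_px = np.hypot(
            gt.bbs["gtub_x_px"] - gt.bbs["fop_x_px"],
            gt.bbs["gtub_y_px"] - gt.bbs["fop_y_px"],
        )
        assert np.allclose(d_px * gt.pixel_size_um, 0.3, atol=1e-9)


class TestDegenerateLimits:
    def test_zero_displacement_concentrated_rotation(self):
        """kappa -> infinity and zero displacement collapse both polarities."""
        cfg = make_config(displacement_um=0.0, rotation_kappa=1e6, seed=11)
        gt = sample_geometry(cfg)
        # every FOP->gtub angle within 0.5 deg of its cell mean
        merged = gt.bbs.merge(gt.cells[["cell_id", "mean_rotation_deg"]], on="cell_id")
        spread = circ_diff_deg(merged["angle_deg"], merged["mean_rotation_deg"])
        assert np.max(np.abs(spread)) < 0.5
        # BB-patch centroid within 1 px of the cell centroid
        for cid, grp in gt.bbs.groupby("cell_id"):
            cell = gt.cells.set_index("cell_id").loc[cid]
            dx = grp["gtub_x_px"].mean() - cell["centroid_x_px"]
            dy = grp["gtub_y_px"].mean() - cell["centroid_y_px"]
            assert np.hypot(dx, dy) < 1.0

    def test_determinism_bit_exact(self):
        cfg = make_config(seed=5)
        s1, g1 = generate_sheet(cfg)
        s2, g2 = generate_sheet(cfg)
        assert np.array_equal(s1.data, s2.data)
        pd.testing.assert_frame_equal(g1.cells, g2.cells)
        pd.testing.assert_frame_equal(g1.bbs, g2.bbs)
        pd.testing.assert_frame_equal(g1.puncta, g2.puncta)


class TestAngleStatistics:
    def test_csd_of_generated_angles_matches_bessel_oracle(self):
        """Sampled per-cell angle spread matches the analytic von Mises CSD.

        The oracle is sqrt(-2 ln(I1(k)/I0(k))) via Bessel evaluation; the
        sample is the pooled deviation of per-BB angles from their cell
        means across many cells (~1,500 angles at kappa = 8).
        """
        kappa = 8.0
        pooled = []
        for seed in (21, 22, 23):
            cfg = make_config(rotation_kappa=kappa, bb_per_cell=(20, 22), seed=seed)
            gt = sample_geometry(cfg)
            merged = gt.bbs.merge(gt.cells[["cell_id", "mean_rotation_deg"]], on="cell_id")
            pooled.extend(circ_diff_deg(merged["angle_deg"], merged["mean_rotation_deg"]))
        csd = circular_summary(np.asarray(pooled) % 360.0).csd_deg
        assert csd == pytest.approx(vonmises_csd_deg(kappa), rel=0.05)

    def test_vonmises_moments_converge(self):
        """At n = 1e4 the sample resultant length is within 2% of I1/I0."""
        from scipy.special import i0e, i1e

        rng = np.random.default_rng(0)
        for kappa in (0.5, 2.0, 8.0):
            angles = np.degrees(rng.vonmises(0.0, kappa, size=10_000)) % 360.0
            r_bar = circular_summary(angles).resultant_length
            assert r_bar == pytest.approx(i1e(kappa) / i0e(kappa), rel=0.02)


class TestRoundTrip:
    def test_field_and_ground_truth_survive_disk_round_trip(self, tmp_path, default_field):
        stack, gt = default_field
        path = write_field(tmp_path / "f.tif", stack)
        back = read_field(path)
        assert np.array_equal(back.data, stack.data)
        assert back.channels == stack.channels
        assert back.pixel_size_um == stack.pixel_size_um
        gt.write(tmp_path, "f")
        gt2 = GroundTruth.read(tmp_path, "f", gt.pixel_size_um)
        for a, b in [(gt.cells, gt2.cells), (gt.bbs, gt2.bbs), (gt.puncta, gt2.puncta)]:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, check_exact=False)


class TestTwoGenotypeExperiment:
    def test_counts_and_manifest(self, tmp_path):
        cfg = make_config(field_size_um=(30.0, 30.0), n_cells=9)
        manifest = generate_two_genotype_experiment(cfg, cfg, n_fields=3, seed=0, out_dir=tmp_path)
        assert len(manifest) == 6
        assert sorted(manifest["genotype"].unique()) == ["KO", "WT"]
        assert len(list(tmp_path.glob("*.tif"))) == 6
        assert (tmp_path / "manifest.csv").exists()

    def test_n_fields_validation(self, tmp_path):
        cfg = make_config()
        with pytest.raises(ValueError):
            generate_two_genotype_experiment(cfg, cfg, n_fields=0, seed=0, out_dir=tmp_path)

    def test_mismatched_geometry_rejected(self, tmp_path):
        a = make_config()
        b = make_config(pixel_size_um=0.2)
        with pytest.raises(ValueError):
            generate_two_genotype_experiment(a, b, n_fields=1, seed=0, out_dir=tmp_path)

    def test_csd_monotone_in_kappa(self, tmp_path):
        """Mean true per-cell CSD is strictly larger in the low-kappa arm."""
        wt = make_config(rotation_kappa=8.0, field_size_um=(30.0, 30.0), n_cells=9)
        ko = dataclasses.replace(wt, rotation_kappa=0.5)
        csds = {"WT": [], "KO": []}
        for label, cfg in (("WT", wt), ("KO", ko)):
            for seed in (31, 32):
                gt = sample_geometry(dataclasses.replace(cfg, seed=seed))
                for _, grp in gt.bbs.groupby("cell_id"):
                    csds[label].append(circular_summary(grp["angle_deg"].to_numpy()).csd_deg)
        assert np.mean(csds["KO"]) > np.mean(csds["WT"])

    def test_displacement_distributions_separable(self):
        """Ground-truth displacements of 2.0 vs 0.3 um arms separate at p < 0.01."""
        from scipy.stats import mannwhitneyu

        mags = {}
        for label, disp in (("WT", 2.0), ("KO", 0.3)):
            vals = []
            for seed in (41, 42):
                gt = sample_geometry(make_config(displacement_um=disp, seed=seed))
                vals.extend(gt.cells["disp_magnitude_um"])
            mags[label] = vals
        assert len(mags["WT"]) >= 15 and len(mags["KO"]) >= 15
        assert mannwhitneyu(mags["WT"], mags["KO"]).pvalue < 0.01
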