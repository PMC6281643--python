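"""Tests of circular statistics and Watson's two-sample U2.

The brute-force oracles here are deliberately naive re-implementations
(explicit loops over unit vectors and empirical CDFs) kept independent of
the library code paths they check.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcpquant.rpcp import (
    UndefinedCircularSpread,
    circular_summary,
    per_cell_rpcp,
    pooled_cell_mean_summary,
    rose_histogram,
    rotation_angle,
    vonmises_csd_deg,
    watson_u2,
    watson_u2_statistic,
)
from pcpquant.spots import BBPair, Spot

from conftest import circ_diff_deg, make_config


def brute_force_circular(angles_deg):
    """Direct unit-vector-summation oracle for mean angle, R-bar and CSD."""
    sx = sy = 0.0
    for a in angles_deg:
        sx += math.cos(math.radians(a))
        sy += math.sin(math.radians(a))
    n = len(angles_deg)
    r = math.hypot(sx, sy) / n
    mean = math.degrees(math.atan2(sy, sx)) % 360.0
    csd = math.degrees(math.sqrt(-2.0 * math.log(r))) if r > 0 else float("nan")
    return mean, r, csd


def brute_force_u2(a, b):
    """O((n+m)^2) direct-definition Watson U2 (empirical CDF differences)."""
    a = [x % 360.0 for x in a]
    b = [x % 360.0 for x in b]
    pooled = sorted(set(a + b))
    n, m = len(a), len(b)
    d, t = [], []
    for x in pooled:
        fa = sum(1 for v in a if v <= x) / n
        fb = sum(1 for v in b if v <= x) / m
        d.append(fa - fb)
        t.append(sum(1 for v in a + b if v == x))
    total = n + m
    sum_td = sum(ti * di for ti, di in zip(t, d))
    sum_td2 = sum(ti * di * di for ti, di in zip(t, d))
    return n * m / total**2 * (sum_td2 - sum_td**2 / total)


def _pair(fx, fy, gx, gy):
    f = Spot(x_px=fx, y_px=fy, intensity=1, response=1, sigma_px=1)
    g = Spot(x_px=gx, y_px=gy, intensity=1, response=1, sigma_px=1)
    sep = math.hypot(gx - fx, gy - fy)
    return BBPair(fop=f, gtub=g, separation_um=sep)


class TestRotationAngle:
    def test_horizontal_reference(self):
        assert rotation_angle(_pair(0, 0, 1, 0)) == pytest.approx(0.0)

    def test_up_is_90(self):
        assert rotation_angle(_pair(0, 0, 0, -1)) == pytest.approx(90.0)

    def test_coincident_dots_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            rotation_angle(_pair(1, 1, 1, 1))


class TestCircularSummary:
    def test_constant_angles(self):
        s = circular_summary([90, 90, 90])
        assert s.mean_angle_deg == pytest.approx(90.0)
        assert s.resultant_length == pytest.approx(1.0)
        assert s.csd_deg == pytest.approx(0.0, abs=1e-9)

    def test_wraparound_mean(self):
        s = circular_summary([350, 10])
        assert s.mean_angle_deg == pytest.approx(0.0, abs=1e-9) or s.mean_angle_deg == pytest.approx(360.0)

    def test_symmetric_triple_matches_brute_force(self):
        s = circular_summary([10, 20, 30])
        mean, r, csd = brute_force_circular([10, 20, 30])
        assert s.mean_angle_deg == pytest.approx(20.0, abs=1e-9)
        assert s.csd_deg == pytest.approx(csd, abs=1e-9)
        assert s.resultant_length == pytest.approx(r, abs=1e-12)

    def test_antipodal_undefined(self):
        with pytest.raises(UndefinedCircularSpread):
            circular_summary([0.0, 180.0])

    def test_angular_deviation_variant(self):
        angles = [10, 40, 80]
        s = circular_summary(angles, csd_method="angular")
        _, r, _ = brute_force_circular(angles)
        assert s.csd_deg == pytest.approx(math.degrees(math.sqrt(2 * (1 - r))))

    @given(
        st.lists(st.floats(0, 360, exclude_max=True), min_size=3, max_size=20),
        st.integers(-3, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_permutation_and_wrapping(self, angles, k):
        try:
            s0 = circular_summary(angles)
        except UndefinedCircularSpread:
            return
        shuffled = list(reversed(angles))
        s1 = circular_summary([a + 360.0 * k for a in shuffled])
        assert s1.mean_angle_deg == pytest.approx(s0.mean_angle_deg, abs=1e-6)
        assert s1.csd_deg == pytest.approx(s0.csd_deg, abs=1e-6)

    def test_agrees_with_pingouin(self):
        """Independent library cross-check of mean direction and R-bar."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        angles = np.degrees(rng.vonmises(1.0, 2.0, size=200)) % 360.0
        s = circular_summary(angles)
        assert s.mean_angle_deg == pytest.approx(
            np.degrees(pg.circ_mean(np.deg2rad(angles))) % 360.0, abs=1e-6
        )
        assert s.resultant_length == pytest.approx(
            float(pg.circ_r(np.deg2rad(angles))), abs=1e-9
        )

    def test_csd_monotone_in_kappa(self):
        """Sample CSD decreases with von Mises concentration (n = 1e4)."""
        rng = np.random.default_rng(2)
        csds = []
        for kappa in (0.5, 2.0, 8.0):
            angles = np.degrees(rng.vonmises(0.0, kappa, size=10_000)) % 360.0
            csds.append(circular_summary(angles).csd_deg)
        assert csds[0] > csds[1] > csds[2]


class TestWatsonU2:
    def test_identical_samples_null(self):
        a = [10.0, 50.0, 90.0, 200.0, 355.0]
        for seed in (0, 1, 2):
            res = watson_u2(a, a, n_permutations=199, seed=seed)
            assert res.p_value >= 0.5
        assert watson_u2_statistic(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_statistic_matches_brute_force_oracle(self):
        a = [12.0, 97.0, 184.5, 201.0, 330.0]
        b = [45.0, 110.0, 151.5, 280.0, 333.3]
        assert watson_u2_statistic(a, b) == pytest.approx(brute_force_u2(a, b), abs=1e-12)

    @given(
        st.lists(st.floats(0, 360, exclude_max=True), min_size=4, max_size=15),
        st.lists(st.floats(0, 360, exclude_max=True), min_size=4, max_size=15),
    )
    @settings(max_examples=50, deadline=None)
    def test_statistic_equals_oracle_on_random_samples(self, a, b):
        assert watson_u2_statistic(a, b) == pytest.approx(brute_force_u2(a, b), abs=1e-10)

    def test_invariant_to_common_rotation(self):
        rng = np.random.default_rng(3)
        a = np.degrees(rng.vonmises(0, 2, 20)) % 360
        b = np.degrees(rng.vonmises(1, 2, 25)) % 360
        u0 = watson_u2_statistic(a, b)
        for rot in (37.0, 123.4, 300.0):
            assert watson_u2_statistic((a + rot) % 360, (b + rot) % 360) == pytest.approx(
                u0, abs=1e-9
            )

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            watson_u2([1, 2, 3], [4, 5, 6, 7])

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(4)
        a = np.degrees(rng.vonmises(0.0, 4.0, 50)) % 360
        b = np.degrees(rng.vonmises(np.pi / 2, 4.0, 50)) % 360
        res = watson_u2(a, b, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.u2 > 0.268  # above the 1% asymptotic critical value


class TestPerCellRpcp:
    def test_uniform_cell_has_zero_csd(self):
        import pandas as pd

        df = pd.DataFrame({"cell_id": [1] * 6, "angle_deg": [33.0] * 6})
        table, excluded = per_cell_rpcp(df, min_bb=5)
        assert excluded == []
        assert table["csd_deg"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_min_bb_exclusion(self):
        import pandas as pd

        df = pd.DataFrame(
            {"cell_id": [1] * 6 + [2] * 3, "angle_deg": list(range(6)) + [1, 2, 3]}
        )
        table, excluded = per_cell_rpcp(df, min_bb=5)
        assert list(table["cell_id"]) == [1]
        assert excluded == [2]

    def test_pooled_mean_recovers_common_direction(self):
        """Per-cell means from a common-direction kappa=8 sheet pool to mu.

        All cells share the tissue direction (coordination kappa -> inf);
        the pooled circular mean of per-cell mean angles must land within
        5 degrees of the configured direction.
        """
        from pcpquant.simulate import sample_geometry

        mu = 40.0
        cfg = make_config(
            rotation_angle_deg=mu, rotation_coordination_kappa=1e6, rotation_kappa=8.0, seed=9
        )
        gt = sample_geometry(cfg)
        rows = []
        for _, grp in gt.bbs.groupby("cell_id"):
            rows.append(circular_summary(grp["angle_deg"].to_numpy()).mean_angle_deg)
        import pandas as pd

        pooled = pooled_cell_mean_summary(pd.DataFrame({"mean_angle_deg": rows}))
        assert abs(circ_diff_deg(pooled.mean_angle_deg, mu)) < 5.0


class TestRoseHistogram:
    def test_counts_conserved_and_binned(self):
        table = rose_histogram([0, 15, 25, 355], bin_width_deg=20)
        assert table["count"].sum() == 4
        assert table.loc[0, "count"] == 2  # [0, 20): 0 and 15
        assert table.loc[17, "count"] == 1  # [340, 360): 355

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            rose_histogram([1.0], bin_width_deg=25)


def test_vonmises_csd_oracle_values():
    """Spot-check the Bessel-based population CSD at kappa = 2."""
    from scipy.special import i0, i1

    expected = math.degrees(math.sqrt(-2 * math.log(i1(2.0) / i0(2.0))))
    assert vonmises_csd_deg(2.0) == pytest.approx(expected, abs=1e-9)
    with pytest.raises(UndefinedCircularSpread):
        vonmises_csd_deg(0.0)
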