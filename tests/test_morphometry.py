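"""Arc length, tortuosity, resampling, pairing and termination order."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ciliamorph import morphometry
from ciliamorph.core import Polyline3D

from conftest import straight_polyline


def random_polyline(rng, n=50, scale=100.0):
    steps = rng.standard_normal((n - 1, 3)) * scale
    steps[np.all(steps == 0, axis=1)] = 1.0
    pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return Polyline3D(pts)


class TestArcLength:
    def test_3_4_5_triangle(self):
        p = Polyline3D(np.array([[0.0, 0.0, 0.0], [0.0, 3.0, 4.0]]))
        assert morphometry.arc_length(p) == pytest.approx(5.0)

    def test_collinear_unit_steps(self):
        assert morphometry.arc_length(straight_polyline(11, 1.0)) == pytest.approx(10.0)

    def test_matches_bruteforce_summation(self):
        rng = np.random.default_rng(42)
        poly = random_polyline(rng)
        # independent segment-by-segment oracle
        expected = 0.0
        for a, b in zip(poly.points[:-1], poly.points[1:]):
            expected += float(np.sqrt(sum((bi - ai) ** 2 for ai, bi in zip(a, b))))
        assert morphometry.arc_length(poly) == pytest.approx(expected, rel=1e-9)

    def test_single_point_is_zero_with_warning(self):
        p = Polyline3D(np.zeros((1, 3)))
        with pytest.warns(UserWarning):
            assert morphometry.arc_length(p) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        poly = random_polyline(rng, n=20)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-1e4, 1e4, 3)
        moved = Polyline3D(poly.points @ rot.T + shift)
        assert morphometry.arc_length(moved) == pytest.approx(
            morphometry.arc_length(poly), rel=1e-6
        )


class TestTortuosity:
    def test_collinear_is_one(self):
        assert morphometry.tortuosity(straight_polyline()) == pytest.approx(1.0)

    def test_semicircle_closed_form(self):
        theta = np.deg2rad(np.arange(0.0, 180.0 + 1.0, 1.0))
        pts = np.column_stack([np.zeros_like(theta), np.sin(theta), np.cos(theta)]) * 500.0
        assert morphometry.tortuosity(Polyline3D(pts)) == pytest.approx(
            np.pi / 2.0, abs=1e-4
        )

    def test_coincident_endpoints_inf_sentinel(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [0, 0, 0]], dtype=float)
        with pytest.warns(UserWarning):
            assert morphometry.tortuosity(Polyline3D(pts)) == np.inf

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_at_least_one_by_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        poly = random_polyline(rng, n=15)
        assert morphometry.tortuosity(poly) >= 1.0 - 1e-9


class TestResample:
    def test_straight_line_point_count(self):
        res = morphometry.resample_polyline(straight_polyline(2, 100.0), 10.0)
        assert res.n_points == 11
        assert np.allclose(res.points[-1], [100.0, 0.0, 0.0])

    def test_step_beyond_length_gives_endpoints(self):
        res = morphometry.resample_polyline(straight_polyline(5, 10.0), 1000.0)
        assert res.n_points == 2
        assert np.allclose(res.points, [[0, 0, 0], [40, 0, 0]])

    def test_length_preserved_for_smooth_curve(self):
        theta = np.linspace(0, np.pi, 200)
        pts = np.column_stack([theta * 10, np.sin(theta) * 300, np.cos(theta) * 300])
        poly = Polyline3D(pts)
        res = morphometry.resample_polyline(poly, 5.0)
        assert morphometry.arc_length(res) == pytest.approx(
            morphometry.arc_length(poly), rel=0.01
        )

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            morphometry.resample_polyline(straight_polyline(), 0.0)


class TestPairing:
    def _parallel(self, offset, n=30, step=20.0):
        a = straight_polyline(n, step, source_id=0, tubule_class="A")
        pts = a.points.copy()
        pts[:, 2] += offset
        b = Polyline3D(pts, tubule_class="B", source_id=1)
        return a, b

    def test_parallel_25nm_paired(self):
        a, b = self._parallel(25.0)
        pairs = morphometry.pair_doublets([a, b])
        assert pairs[0] == pairs[1]

    def test_isolated_tubule_unpaired(self):
        assert morphometry.pair_doublets([straight_polyline()]) == {}

    def test_distant_curves_unpaired(self):
        a, b = self._parallel(200.0)
        assert morphometry.pair_doublets([a, b]) == {}


class TestTermination:
    def _pair(self, pid, la, lb):
        a = Polyline3D(
            np.array([[0, 0, 0], [la, 0, 0]], float), "A", pair_id=pid, source_id=2 * pid
        )
        b = Polyline3D(
            np.array([[0, 0, 25], [lb, 0, 25]], float), "B", pair_id=pid, source_id=2 * pid + 1
        )
        return [a, b]

    def test_fraction_b_first(self):
        polys = self._pair(0, 100, 60) + self._pair(1, 100, 90) + self._pair(2, 100, 130)
        frac, table = morphometry.termination_stats(polys)
        assert frac == pytest.approx(2.0 / 3.0)
        assert table.loc[table.pair_id == 2, "inverted"].item()

    def test_equal_lengths_zero_fraction_zero_delta(self):
        polys = self._pair(0, 100, 100) + self._pair(1, 80, 80)
        frac, table = morphometry.termination_stats(polys)
        assert frac == 0.0
        assert np.allclose(table["delta_length_nm"], 0.0)


class TestSummaries:
    def test_mean_and_sample_sd(self):
        df = pd.DataFrame({"tubule_class": ["A"] * 3, "length_nm": [3.0, 4.0, 5.0]})
        (summary,) = morphometry.summarize_lengths(df)
        assert summary.mean == pytest.approx(4.0)
        assert summary.sd == pytest.approx(1.0)
        assert summary.n == 3

    def test_single_value_sd_zero_with_flag(self):
        df = pd.DataFrame({"tubule_class": ["B"], "length_nm": [7.0]})
        with pytest.warns(UserWarning):
            (summary,) = morphometry.summarize_lengths(df)
        assert summary.sd == 0.0
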