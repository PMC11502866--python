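"""Distance fields, profile sampling, smoothing and transition detection."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ciliamorph import profiles
from ciliamorph.core import DistanceProfile, LabelVolume, Polyline3D


def cylinder_volume(radius_nm=100.0, spacing=4.0, n_lat=64, n_z=32, thickness=3):
    """Straight z-aligned tube: membrane shell of `thickness` voxels at
    `radius_nm`, lumen inside."""
    c = n_lat * spacing / 2.0
    yc = (np.arange(n_lat) + 0.5) * spacing - c
    rad = np.sqrt(yc[:, None] ** 2 + yc[None, :] ** 2)
    arr = np.zeros((n_z, n_lat, n_lat), dtype=np.uint8)
    shell = (rad >= radius_nm) & (rad < radius_nm + thickness * spacing)
    arr[:, shell] = 2
    arr[:, rad < radius_nm] = 3
    vol = LabelVolume(
        arr, (spacing,) * 3, {2: "cilium_membrane", 3: "cilium_lumen"}
    )
    return vol, c


class TestDistanceField:
    def test_on_axis_value_matches_cylinder_radius(self):
        vol, c = cylinder_volume()
        field = profiles.membrane_distance_field(vol)
        axis = field.values[16, 32, 32]
        assert axis == pytest.approx(100.0, abs=4.0)

    def test_membrane_voxels_are_zero(self):
        vol, _ = cylinder_volume()
        field = profiles.membrane_distance_field(vol)
        assert np.all(field.values[vol.array == 2] == 0.0)

    def test_matches_exhaustive_search_on_small_volume(self):
        rng = np.random.default_rng(0)
        arr = np.zeros((16, 16, 16), dtype=np.uint8)
        arr[rng.random(arr.shape) > 0.98] = 2
        arr[3, 3, 3] = 2
        spacing = (8.0, 6.0, 4.0)  # anisotropic
        vol = LabelVolume(arr, spacing, {2: "cilium_membrane"})
        field = profiles.membrane_distance_field(vol)
        mem = np.argwhere(arr == 2) * spacing
        every = np.indices(arr.shape).reshape(3, -1).T * spacing
        oracle = cdist(every, mem).min(axis=1).reshape(arr.shape)
        assert np.allclose(field.values, oracle, atol=1e-9)

    def test_axis_permutation_invariance_isotropic(self):
        rng = np.random.default_rng(2)
        arr = np.zeros((12, 12, 12), dtype=np.uint8)
        arr[rng.random(arr.shape) > 0.95] = 2
        vol = LabelVolume(arr, (4.0, 4.0, 4.0), {2: "cilium_membrane"})
        base = profiles.membrane_distance_field(vol).values
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            pvol = LabelVolume(
                np.transpose(arr, perm).copy(), (4.0, 4.0, 4.0), {2: "cilium_membrane"}
            )
            pfield = profiles.membrane_distance_field(pvol).values
            assert np.allclose(pfield, np.transpose(base, perm))

    def test_missing_membrane_label_is_hard_error(self):
        vol = LabelVolume(np.ones((4, 4, 4), dtype=np.uint8), (4, 4, 4), {1: "axon"})
        with pytest.raises(ValueError, match="cilium_membrane"):
            profiles.membrane_distance_field(vol)


class TestSampleProfile:
    def test_axis_profile_constant_at_radius(self):
        vol, c = cylinder_volume(n_z=64)
        field = profiles.membrane_distance_field(vol)
        axis = Polyline3D(np.array([[20.0, c, c], [230.0, c, c]]))
        prof = profiles.sample_profile(axis, field)
        assert prof.raw.size == 54  # ~210 nm at 4 nm steps
        assert np.all(np.abs(prof.raw - 100.0) <= 5.0)

    def test_point_near_membrane_is_near_zero(self):
        vol, c = cylinder_volume()
        field = profiles.membrane_distance_field(vol)
        probe = Polyline3D(np.array([[60.0, c, c + 102.0], [70.0, c, c + 102.0]]))
        prof = profiles.sample_profile(probe, field, step=2.0)
        assert prof.raw.min() <= 4.0


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        prof = DistanceProfile(0, np.full(50, 40.0))
        sm = profiles.smooth_profile(prof, sigma=3.0)
        assert np.allclose(sm.smoothed, 40.0)

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(20, 120, 40)
        sm = profiles.smooth_profile(DistanceProfile(0, raw), sigma=0.0)
        assert np.array_equal(sm.smoothed, raw)

    def test_impulse_peak_matches_discrete_kernel(self):
        n, sigma = 61, 3.0
        raw = np.zeros(n)
        raw[30] = 1.0
        sm = profiles.smooth_profile(DistanceProfile(0, raw), sigma=sigma)
        # closed-form discrete Gaussian kernel, normalized (scipy truncates
        # at 4 sigma by default)
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        assert sm.smoothed[30] == pytest.approx(kernel[radius], rel=1e-9)
        assert sm.smoothed.sum() == pytest.approx(1.0, abs=1e-6)

    def test_mean_preserved_with_reflect_boundary(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(10, 150, 37)
        sm = profiles.smooth_profile(DistanceProfile(0, raw), sigma=3.0)
        assert sm.smoothed.mean() == pytest.approx(raw.mean(), rel=1e-6)


class TestTransitions:
    def _smoothed(self, values):
        arr = np.asarray(values, float)
        return DistanceProfile(0, arr, smoothed=arr, sigma=3.0)

    def test_ramp_and_hold_gives_one_event_at_peak(self):
        ramp = np.concatenate([np.full(50, 40.0), np.linspace(40, 100, 60), np.full(80, 100.0)])
        events = profiles.detect_major_transitions(self._smoothed(ramp))
        assert len(events) == 1
        ev = events[0]
        assert ev.classification == "major"
        assert ev.peak_nm == pytest.approx(100.0)
        assert ev.onset_index == 50 + 30  # first ramp index above 70 nm

    def test_flat_low_profile_no_events(self):
        assert profiles.detect_major_transitions(self._smoothed(np.full(100, 40.0))) == []

    def test_two_separated_excursions_two_events(self):
        prof = np.full(120, 40.0)
        prof[10:30] = 90.0
        prof[70:95] = 85.0
        events = profiles.detect_major_transitions(self._smoothed(prof))
        assert [(e.onset_index, e.end_index) for e in events] == [(10, 29), (70, 94)]

    def test_short_run_below_min_run_ignored(self):
        prof = np.full(100, 40.0)
        prof[50:55] = 120.0  # 5 < min_run=10
        assert profiles.detect_major_transitions(self._smoothed(prof)) == []

    def test_profile_shorter_than_min_run_flagged_none(self):
        (ev,) = profiles.detect_major_transitions(self._smoothed(np.full(5, 90.0)))
        assert ev.classification == "none"


class TestExport:
    def test_row_counts_and_flags(self):
        raw = np.concatenate([np.full(30, 40.0), np.full(30, 100.0)])
        prof = DistanceProfile(7, raw, smoothed=raw, sigma=3.0)
        table = profiles.export_profile_table([prof])
        assert len(table) == 60
        assert set(table.source_id) == {7}
        flagged = table.loc[table.is_major_transition, "point_index"]
        ev = profiles.detect_major_transitions(prof)[0]
        assert flagged.min() == ev.onset_index and flagged.max() == ev.end_index

    def test_empty_input_header_only(self):
        table = profiles.export_profile_table([])
        assert table.empty
        assert list(table.columns) == [
            "source_id", "point_index", "raw_nm", "smoothed_nm", "is_major_transition",
        ]
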