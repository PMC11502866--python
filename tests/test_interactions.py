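"""Pocket length, contact detection/census and contact-fraction statistics."""

import numpy as np
import pandas as pd
import pytest

from ciliamorph import interactions, synthetic
from ciliamorph.core import Polyline3D
from ciliamorph.interactions import ContactRecord


def _short_scene(pocket_length, cilium_length=800.0, neighbor_gaps=(), **kw):
    spec = synthetic.SceneSpec(
        pocket_length=pocket_length, neighbor_gaps=tuple(neighbor_gaps), **kw
    )
    axo = synthetic.AxonemeSpec(
        n_doublets=3,
        triplet_length=0.0,
        a_lengths=(cilium_length - 150.0,) * 3,
        b_lengths=(400.0,) * 3,
        wiggle_amplitude=0.0,
    )
    skeletons, truth = synthetic.generate_axoneme(axo, seed=0)
    return synthetic.voxelize_scene(skeletons, spec, truth=truth, cilium_length=cilium_length)


class TestPocket:
    def test_recovers_constructed_pocket_length(self, mouse_scene):
        m = interactions.measure_pocket(
            mouse_scene.volume, mouse_scene.axis, membrane_radius=125.0, step=50.0
        )
        assert m.pocket_length_nm == pytest.approx(
            mouse_scene.pocket_length_true, abs=100.0
        )

    def test_zero_pocket_detected_as_zero(self):
        scene = _short_scene(pocket_length=0.0)
        m = interactions.measure_pocket(scene.volume, scene.axis, step=50.0)
        assert m.pocket_length_nm == 0.0

    def test_fully_wrapped_cilium_pocket_spans_full_length(self):
        scene = _short_scene(pocket_length=800.0, cilium_length=800.0)
        m = interactions.measure_pocket(scene.volume, scene.axis, step=50.0)
        assert m.pocket_length_nm == pytest.approx(800.0, abs=100.0)

    def test_enclosure_profile_in_unit_interval(self, mouse_scene):
        m = interactions.measure_pocket(
            mouse_scene.volume, mouse_scene.axis, membrane_radius=125.0, step=100.0
        )
        assert np.all((m.enclosure_profile >= 0) & (m.enclosure_profile <= 1))

    def test_translation_invariance(self):
        scene = _short_scene(pocket_length=400.0)
        arr = scene.volume.array
        pad = 6
        shifted = np.zeros(
            (arr.shape[0], arr.shape[1] + pad, arr.shape[2]), dtype=arr.dtype
        )
        shifted[:, pad:, :] = arr
        vol2 = synthetic.LabelVolume(
            shifted, scene.volume.spacing, scene.volume.label_table
        )
        axis2 = Polyline3D(
            scene.axis.points + [0.0, pad * scene.volume.spacing[1], 0.0]
        )
        m1 = interactions.measure_pocket(scene.volume, scene.axis, step=50.0)
        m2 = interactions.measure_pocket(vol2, axis2, step=50.0)
        assert m1.pocket_length_nm == m2.pocket_length_nm


class TestContacts:
    def test_gap_within_threshold_detected_beyond_not(self, small_scene):
        records = interactions.detect_contacts(small_scene.volume)
        found = {r.neighbor_class for r in records}
        assert found == {"neighbor:beta", "neighbor:endothelial"}  # 10 nm gaps
        # the 50 nm acinar neighbour is beyond the default 20 nm threshold
        assert "neighbor:acinar" not in found

    def test_two_disjoint_neighbors_two_records(self, small_scene):
        records = interactions.detect_contacts(small_scene.volume)
        assert len(records) == 2
        assert all(r.min_gap_nm <= 20.0 for r in records)
        assert all(r.voxel_count >= 10 for r in records)

    def test_shrinking_gap_max_never_adds_neighbors(self, small_scene):
        # each constructed neighbour is one contact; shrinking the gap
        # threshold can only lose neighbours, never add them
        detected = [
            {
                r.neighbor_label
                for r in interactions.detect_contacts(small_scene.volume, gap_max=g)
            }
            for g in (60.0, 40.0, 20.0, 12.0, 5.0)
        ]
        for larger, smaller in zip(detected, detected[1:]):
            assert smaller <= larger

    def test_contact_area_scales_with_voxel_count(self, small_scene):
        records = interactions.detect_contacts(small_scene.volume)
        for r in records:
            assert r.contact_area_nm2 == pytest.approx(r.voxel_count * 16.0)


class TestCensus:
    def _rec(self, cls, cid=0):
        return ContactRecord(cid, 9, cls, 20, 320.0, 10.0)

    def test_empty_records_all_zero_row(self):
        census = interactions.contact_census([])
        assert len(census) == 1
        assert census.drop(columns="cilium_id").sum().sum() == 0

    def test_counts_by_class(self):
        recs = [
            self._rec("neighbor:beta"),
            self._rec("neighbor:beta"),
            self._rec("axon"),
        ]
        census = interactions.contact_census(recs)
        assert census.loc[0, "beta"] == 2
        assert census.loc[0, "axon"] == 1

    def test_unrecognized_class_goes_to_unknown(self):
        census = interactions.contact_census([self._rec("neighbor:martian")])
        assert census.loc[0, "unknown"] == 1

    def test_totals_conserved(self):
        recs = [self._rec("neighbor:beta", cid) for cid in (0, 0, 1)]
        census = interactions.contact_census(recs)
        assert census.drop(columns="cilium_id").to_numpy().sum() == 3


class TestFractions:
    def _census(self, contacting, total, group):
        return pd.DataFrame(
            {
                "cilium_id": range(total),
                "axon": [1] * contacting + [0] * (total - contacting),
                "_g": group,
            }
        )

    def test_per_group_percent_and_mean(self):
        df = pd.concat(
            [self._census(10, 80, "m1"), self._census(15, 100, "m2")], ignore_index=True
        )
        mean, sd, per = interactions.fraction_with_axon_contact(df, df["_g"])
        assert sorted(per) == [12.5, 15.0]
        assert mean == pytest.approx(13.75)

    def test_single_group_sd_zero_with_warning(self):
        df = self._census(5, 50, "m1")
        with pytest.warns(UserWarning):
            mean, sd, _ = interactions.fraction_with_axon_contact(df, df["_g"])
        assert (mean, sd) == (10.0, 0.0)

    def test_all_contacting_is_100_pm_0(self):
        df = pd.concat(
            [self._census(4, 4, "m1"), self._census(6, 6, "m2")], ignore_index=True
        )
        mean, sd, _ = interactions.fraction_with_axon_contact(df, df["_g"])
        assert (mean, sd) == (100.0, 0.0)


class TestMarkerPositivity:
    def test_single_group_half_positive(self):
        df = pd.DataFrame({"group": ["m1"] * 4, "positive": [True, True, False, False]})
        with pytest.warns(UserWarning):
            mean, sd, _ = interactions.marker_positivity(df)
        assert mean == 50.0

    def test_two_groups_mean_and_sd(self):
        df = pd.DataFrame(
            {
                "group": ["m1"] * 10 + ["m2"] * 25,
                "positive": [True] * 7 + [False] * 3 + [True] * 18 + [False] * 7,
            }
        )
        mean, sd, _ = interactions.marker_positivity(df)
        assert mean == pytest.approx((70.0 + 72.0) / 2)
        assert sd == pytest.approx(np.std([70.0, 72.0], ddof=1))
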