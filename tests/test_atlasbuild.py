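"""Re-inflation, probability maps, and atlas characterization metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from arteryatlas.atlasbuild import (
    Atlas,
    ProbabilityMap,
    arterial_volume_ratio,
    build_atlas,
    build_probability_map,
    concatenated_volume,
    dominating_volume,
    max_probability,
    reinflate,
    volume_conserving_binarize,
    whole_atlas_avr,
    metrics_table,
)
from arteryatlas.volumes import BinaryVolume, LabelVolume, ScalarVolume, default_affine


def _label_volume(labels, names=None, vox=1.0):
    labels = np.asarray(labels, dtype=np.int32)
    names = names or {int(k): f"a{int(k)}" for k in np.unique(labels) if k != 0}
    return LabelVolume(labels, names, np.full(3, vox), default_affine(vox))


def _binary(mask, vox=1.0):
    return BinaryVolume(np.asarray(mask, dtype=bool), np.full(3, vox), default_affine(vox))


def _pmap(values, n_included=2, vox=1.0, name="a"):
    return ProbabilityMap(name, np.asarray(values, dtype=float), n_included,
                          np.full(3, vox), default_affine(vox))


class TestReinflate:
    def test_single_seed_fills_cube_mask(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        out = reinflate(_label_volume(labels, {1: "a"}), _binary(mask))
        np.testing.assert_array_equal(out.labels == 1, mask)

    def test_two_labels_meet_at_midpoint_tie_to_lower_id(self):
        n = 27
        labels = np.zeros((n, 3, 3), dtype=np.int32)
        labels[10, 1, 1] = 1
        labels[16, 1, 1] = 2
        mask = np.zeros((n, 3, 3), dtype=bool)
        mask[5:22, 1, 1] = True
        out = reinflate(_label_volume(labels, {1: "a", 2: "b"}), _binary(mask))
        # brute-force nearest-label oracle per mask voxel, limited to the
        # 7-voxel cubic kernel's reach of 3
        for x in range(5, 22):
            d1, d2 = abs(x - 10), abs(x - 16)
            expected = 0
            if min(d1, d2) <= 3:
                expected = 1 if d1 <= d2 else 2  # equidistant -> lower id
            assert out.labels[x, 1, 1] == expected
        assert out.labels[13, 1, 1] == 1  # exact midpoint, tie broken low

    def test_voxels_beyond_kernel_reach_stay_background(self):
        labels = np.zeros((20, 3, 3), dtype=np.int32)
        labels[2, 1, 1] = 1
        mask = np.zeros((20, 3, 3), dtype=bool)
        mask[2:15, 1, 1] = True
        out = reinflate(_label_volume(labels, {1: "a"}), _binary(mask))
        assert (out.labels[2:6, 1, 1] == 1).all()
        assert (out.labels[6:, 1, 1] == 0).all()

    def test_never_labels_outside_mask(self):
        rng = np.random.default_rng(0)
        mask = rng.random((12, 12, 12)) > 0.6
        labels = np.where(mask & (rng.random((12, 12, 12)) > 0.8), 1, 0)
        if not labels.any():
            labels[tuple(np.argwhere(mask)[0])] = 1
        out = reinflate(_label_volume(labels, {1: "a"}), _binary(mask))
        assert not (out.labels[~mask] > 0).any()

    def test_even_kernel_rejected(self):
        lv = _label_volume(np.zeros((3, 3, 3)), {1: "a"})
        with pytest.raises(ValueError):
            reinflate(lv, _binary(np.ones((3, 3, 3))), kernel_vox=4)

    def test_labels_outside_mask_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = 1
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[2, 2, 2] = True
        with pytest.raises(ValueError, match="inside the mask"):
            reinflate(_label_volume(labels, {1: "a"}), _binary(mask))


class TestProbabilityMap:
    def _volumes(self, occupancy):
        """One-voxel arteries: occupancy[i] True -> subject i's artery at (1,1,1)."""
        vols = []
        for occ in occupancy:
            labels = np.zeros((3, 3, 3), dtype=np.int32)
            if occ:
                labels[1, 1, 1] = 1
            vols.append(_label_volume(labels, {1: "a"}))
        return vols

    def test_voxel_fraction_over_included_subjects(self):
        vols = self._volumes([True, True, True])
        vols[2].labels[1, 1, 1] = 0
        vols[2].labels[0, 0, 0] = 1  # present elsewhere
        pmap = build_probability_map("a", vols, label_id=1)
        assert pmap.n_included == 3
        assert pmap.values[1, 1, 1] == pytest.approx(2 / 3)

    def test_denominator_counts_included_arteries_not_cohort(self):
        # 3 subjects, artery present in 2, the voxel occupied in 1 -> 1/2
        vols = self._volumes([True, False, False])
        vols[1].labels[0, 0, 0] = 1
        pmap = build_probability_map("a", vols, label_id=1)
        assert pmap.n_included == 2
        assert pmap.values[1, 1, 1] == pytest.approx(1 / 2)

    def test_identical_volumes_give_binary_map(self):
        pmap = build_probability_map("a", self._volumes([True] * 4), label_id=1)
        assert set(np.unique(pmap.values)) <= {0.0, 1.0}

    def test_absent_artery_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            build_probability_map("a", self._volumes([False, False]), label_id=1)

    def test_probability_mass_conservation(self, rng):
        vols = []
        for _ in range(5):
            labels = (rng.random((8, 8, 8)) > 0.7).astype(np.int32)
            vols.append(_label_volume(labels, {1: "a"}))
        pmap = build_probability_map("a", vols, label_id=1)
        total = sum(int((v.labels == 1).sum()) for v in vols)
        assert pmap.values.sum() * pmap.n_included == pytest.approx(total)


class TestMetrics:
    def test_concatenated_volume_unit_conversion(self):
        values = np.zeros((10, 10, 10))
        values.ravel()[:1000] = 0.5
        assert concatenated_volume(_pmap(values)) == pytest.approx(1.0)

    def test_concatenated_volume_of_empty_map_is_zero(self):
        assert concatenated_volume(_pmap(np.zeros((4, 4, 4)))) == 0.0

    def test_concatenated_volume_at_study_voxel_size(self):
        values = np.zeros((20, 20, 20))
        values.ravel()[:5832] = 1.0
        assert concatenated_volume(_pmap(values, vox=0.7)) == pytest.approx(
            5832 * 0.343 / 1000.0
        )

    def test_avr_identical_subject_volumes_is_one(self):
        values = np.zeros((5, 5, 5))
        values[1:3, 1:3, 1:3] = 1.0
        vol = concatenated_volume(_pmap(values))
        assert arterial_volume_ratio(_pmap(values), [vol, vol, vol]) == 1.0

    def test_avr_two_disjoint_equal_arteries_is_two(self):
        values = np.zeros((6, 3, 3))
        values[0:2, 0, 0] = 0.5
        values[4:6, 0, 0] = 0.5
        pmap = _pmap(values)
        per_subject = concatenated_volume(pmap) / 2
        assert arterial_volume_ratio(pmap, [per_subject, per_subject]) == pytest.approx(2.0)

    def test_avr_empty_subject_list_rejected(self):
        with pytest.raises(ValueError):
            arterial_volume_ratio(_pmap(np.ones((2, 2, 2))), [])

    def test_dominating_volume_single_map_atlas(self):
        pmap = _pmap(np.full((3, 3, 3), 0.5))
        assert dominating_volume(pmap, Atlas({"a": pmap})) == 100.0

    def test_dominating_volume_strict_split(self):
        a = _pmap(np.array([[[0.5, 0.2]]]), name="a")
        b = _pmap(np.array([[[0.3, 0.4]]]), name="b")
        atlas = Atlas({"a": a, "b": b})
        assert dominating_volume(a, atlas) == 50.0
        assert dominating_volume(b, atlas) == 50.0

    def test_exact_ties_do_not_dominate(self):
        a = _pmap(np.full((2, 2, 2), 0.5), name="a")
        b = _pmap(np.full((2, 2, 2), 0.5), name="b")
        atlas = Atlas({"a": a, "b": b})
        assert dominating_volume(a, atlas) == 0.0

    def test_max_probability(self):
        assert max_probability(_pmap(np.array([[[0.5, 1.0]]]))) == 1.0
        assert max_probability(_pmap(np.array([[[0.5, 0.0]]]))) == 0.5
        with pytest.raises(ValueError):
            max_probability(_pmap(np.zeros((2, 2, 2))))

    def test_whole_atlas_avr_single_row_equals_row_avr(self):
        values = np.zeros((5, 5, 5))
        values[1:3, 1:3, 1:3] = 1.0
        _, rows = build_atlas([_label_volume(values.astype(int), {1: "a"})])
        assert whole_atlas_avr(rows) == pytest.approx(rows[0].avr)
        assert whole_atlas_avr(metrics_table(rows)) == pytest.approx(rows[0].avr)


class TestVolumeConservingBinarize:
    def test_top_k_kept(self):
        vals = np.array([0.9, 0.6, 0.4, 0.1]).reshape(1, 1, 4)
        out = volume_conserving_binarize(
            ScalarVolume.from_array(vals), target_volume_vox=2
        )
        np.testing.assert_array_equal(out.mask.ravel(), [True, True, False, False])

    def test_binary_input_at_own_volume_is_identity(self):
        mask = np.zeros((4, 4, 4))
        mask[1:3, 1:3, 1:3] = 1.0
        out = volume_conserving_binarize(ScalarVolume.from_array(mask), int(mask.sum()))
        np.testing.assert_array_equal(out.mask, mask.astype(bool))

    @given(st.integers(1, 60))
    def test_count_matches_sorted_oracle(self, target):
        rng = np.random.default_rng(99)
        vals = rng.random((4, 4, 4))
        out = volume_conserving_binarize(ScalarVolume.from_array(vals), target)
        thr = np.sort(vals.ravel())[::-1][target - 1]
        assert int(out.mask.sum()) == int((vals >= thr).sum()) >= target

    def test_shortfall_returns_all_positive_with_warning(self):
        vals = np.zeros((3, 3, 3))
        vals[0, 0, 0] = 1.0
        with pytest.warns(RuntimeWarning):
            out = volume_conserving_binarize(ScalarVolume.from_array(vals), 5)
        assert int(out.mask.sum()) == 1


class TestBuildAtlas:
    def test_single_subject_atlas_maps_equal_subject_binaries(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[1:3, 1, 1] = 1
        labels[4:6, 4, 4] = 2
        lv = _label_volume(labels, {1: "a", 2: "b"})
        atlas, rows = build_atlas([lv])
        np.testing.assert_array_equal(atlas.maps["a"].values, (labels == 1).astype(float))
        np.testing.assert_array_equal(atlas.maps["b"].values, (labels == 2).astype(float))
        assert all(r.avr == 1.0 and r.max_probability == 1.0 for r in rows)

    def test_zero_deformation_cohort_all_identities(self, zero_cohort):
        from arteryatlas.pipeline import build_cohort_atlas

        _, rows = build_cohort_atlas(zero_cohort, mode="nonlinear")
        assert all(r.avr == 1.0 for r in rows)
        assert all(r.max_probability == 1.0 for r in rows)
        assert all(r.dominating_volume_pct == 100.0 for r in rows)


class TestAvrMonotonicity:
    def test_avr_does_not_decrease_with_deformation_amplitude(self):
        """Under rigid-only normalization the residual non-linear anatomy
        spreads the maps, so whole-atlas AVR grows with warp amplitude."""
        from arteryatlas.phantom import CohortConfig, default_artery_specs, generate_cohort
        from arteryatlas.pipeline import build_cohort_atlas, process_subject

        avrs = []
        for amplitude in (0.0, 1.0, 2.0):
            config = CohortConfig(n_subjects=5, deform_amplitude_mm=amplitude,
                                  noise_sd=0.0, seed=13)
            cohort = generate_cohort(default_artery_specs(config), config)
            processed = [process_subject(s) for s in cohort]
            _, rows = build_cohort_atlas(processed, mode="rigid")
            avrs.append(whole_atlas_avr(rows))
        assert avrs[0] <= avrs[1] <= avrs[2]
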