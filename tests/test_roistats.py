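"""SUVR and ROI summary tests: normalisation, composites, percent change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fdglong as fl
from fdglong.phantom import RegionEffect


def _constant_image(atlas, value):
    return fl.VolumeImage(np.full(atlas.labels.shape, float(value)), atlas.voxel_size_mm)


class TestRoiMeans:
    def test_constant_field(self, small_atlas):
        means = fl.roi_means(_constant_image(small_atlas, 2.0), small_atlas)
        assert set(means) == set(small_atlas.names.values())
        assert all(v == pytest.approx(2.0) for v in means.values())

    def test_hand_arithmetic(self):
        labels = np.zeros((3, 1, 1), dtype=np.int32)
        labels[:, 0, 0] = 1
        atlas = fl.LabelAtlas(labels, {1: "cerebellum"}, (1.0, 1.0, 1.0))
        img = fl.VolumeImage(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1), (1.0, 1.0, 1.0))
        assert fl.roi_means(img, atlas)["cerebellum"] == pytest.approx(2.0)

    def test_matches_voxel_loop_oracle(self, small_atlas, rng):
        img = fl.VolumeImage(
            rng.normal(1, 0.2, small_atlas.labels.shape), small_atlas.voxel_size_mm
        )
        means = fl.roi_means(img, small_atlas)
        for lab, name in small_atlas.names.items():
            acc, n = 0.0, 0
            for idx in zip(*np.nonzero(small_atlas.labels == lab)):
                acc += img.values[idx]
                n += 1
            assert means[name] == pytest.approx(acc / n, abs=1e-12)

    def test_grid_mismatch_rejected(self, small_atlas):
        img = fl.VolumeImage(np.ones((4, 4, 4)), small_atlas.voxel_size_mm)
        with pytest.raises(ValueError):
            fl.roi_means(img, small_atlas)


class TestComputeSuvr:
    def test_uniform_image_normalises_to_one(self, small_atlas):
        suvr_img, suvrs = fl.compute_suvr(_constant_image(small_atlas, 7.3), small_atlas)
        np.testing.assert_allclose(suvr_img.values, 1.0, rtol=1e-12)
        assert all(v == pytest.approx(1.0) for v in suvrs.values())

    def test_ratio_arithmetic(self):
        labels = np.zeros((2, 1, 1), dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[1, 0, 0] = 2
        atlas = fl.LabelAtlas(labels, {1: "cerebellum", 2: "parietal"}, (1.0, 1.0, 1.0))
        img = fl.VolumeImage(np.array([1.5, 1.8]).reshape(2, 1, 1), (1.0, 1.0, 1.0))
        _, suvrs = fl.compute_suvr(img, atlas)
        assert suvrs["parietal"] == pytest.approx(1.2)
        assert suvrs["cerebellum"] == pytest.approx(1.0)

    def test_phantom_forward_pass_exact(self, small_atlas):
        names = tuple(small_atlas.names[k] for k in sorted(small_atlas.names))
        effects = {n: RegionEffect(1.0, 0.0, 0.0) for n in names}
        effects["parietal"] = RegionEffect(1.03, 0.0, 0.0)
        _, truth = fl.simulate_cohort(
            2, (0, 6), effects, seed=0, region_names=names, subject_intercept_sd=0.0
        )
        img = fl.render_visit_image(
            truth, "sub000", 0, small_atlas, psf_fwhm_mm=0.0, noise_sd=0.0
        )
        _, suvrs = fl.compute_suvr(img, small_atlas)
        assert suvrs["parietal"] == pytest.approx(1.03, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(scale=st.floats(0.1, 50.0))
    def test_invariant_to_global_rescaling(self, small_atlas, scale):
        rng = np.random.default_rng(7)
        base = fl.VolumeImage(
            rng.uniform(0.5, 2.0, small_atlas.labels.shape), small_atlas.voxel_size_mm
        )
        _, suvrs1 = fl.compute_suvr(base, small_atlas)
        _, suvrs2 = fl.compute_suvr(base.with_values(scale * base.values), small_atlas)
        for region in suvrs1:
            assert suvrs2[region] == pytest.approx(suvrs1[region], rel=1e-10)

    def test_reference_always_one(self, small_atlas, rng):
        img = fl.VolumeImage(
            rng.uniform(0.5, 2.0, small_atlas.labels.shape), small_atlas.voxel_size_mm
        )
        _, suvrs = fl.compute_suvr(img, small_atlas)
        assert suvrs["cerebellum"] == pytest.approx(1.0, abs=1e-14)

    def test_nonpositive_reference_rejected(self, small_atlas):
        with pytest.raises(ValueError):
            fl.compute_suvr(_constant_image(small_atlas, 0.0), small_atlas)


class TestGlobalCortex:
    def _atlas_two(self, n1, n2):
        labels = np.zeros((n1 + n2, 1, 1), dtype=np.int32)
        labels[:n1, 0, 0] = 1
        labels[n1:, 0, 0] = 2
        return fl.LabelAtlas(labels, {1: "parietal", 2: "occipital"}, (1.0, 1.0, 1.0))

    def test_equal_sizes_average(self):
        atlas = self._atlas_two(5, 5)
        out = fl.global_cortex(
            {"parietal": 1.0, "occipital": 1.2}, atlas, members=("parietal", "occipital")
        )
        assert out == pytest.approx(1.1)

    def test_voxel_weighted_mean(self):
        atlas = self._atlas_two(100, 300)
        out = fl.global_cortex(
            {"parietal": 1.0, "occipital": 1.2}, atlas, members=("parietal", "occipital")
        )
        assert out == pytest.approx(1.15)

    def test_equals_merged_mask_roi_mean(self, small_atlas, rng):
        img = fl.VolumeImage(
            rng.uniform(0.5, 2.0, small_atlas.labels.shape), small_atlas.voxel_size_mm
        )
        members = ("parietal", "superior_frontal", "lateral_temporal")
        _, suvrs = fl.compute_suvr(img, small_atlas)
        composite = fl.global_cortex(suvrs, small_atlas, members=members)
        merged = np.zeros_like(small_atlas.labels, dtype=bool)
        for m in members:
            merged |= small_atlas.mask(m)
        ref = fl.roi_means(img, small_atlas)["cerebellum"]
        assert composite == pytest.approx(img.values[merged].mean() / ref, abs=1e-12)

    def test_missing_member_rejected(self, small_atlas):
        with pytest.raises(KeyError):
            fl.global_cortex({"parietal": 1.0}, small_atlas, members=("parietal", "occipital"))


def _table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "month", "region", "suvr", "pvc", "carrier"])


class TestMeanPercentChange:
    def test_two_interval_hand_arithmetic(self):
        table = _table([
            ("a", 0, "parietal", 1.00, True, True),
            ("a", 6, "parietal", 0.99, True, True),
            ("a", 12, "parietal", 0.98, True, True),
        ])
        out = fl.mean_percent_change(table, "parietal", "carrier")
        expected = 100.0 * ((0.99 - 1.00) / 1.00 + (0.98 - 0.99) / 0.99) / 2.0
        assert out == pytest.approx(expected, abs=1e-12)
        assert out == pytest.approx(-1.005, abs=5e-4)

    def test_constant_trajectories_give_zero(self):
        table = _table([
            ("a", m, "parietal", 1.1, True, False) for m in (0, 6, 12, 18)
        ])
        assert fl.mean_percent_change(table, "parietal", "non-carrier") == 0.0

    def test_single_visit_subject_contributes_nothing(self):
        table = _table([
            ("a", 0, "parietal", 1.0, True, True),
            ("a", 6, "parietal", 0.9, True, True),
            ("b", 0, "parietal", 5.0, True, True),
        ])
        assert fl.mean_percent_change(table, "parietal", "carrier") == pytest.approx(-10.0)

    def test_matches_per_subject_loop_oracle(self):
        rng = np.random.default_rng(5)
        months = (0, 6, 12, 24, 36)
        rows, oracle_changes = [], []
        for i in range(6):
            s = rng.uniform(0.9, 1.3, len(months))
            for m, v in zip(months, s):
                rows.append((f"s{i}", m, "parietal", v, True, True))
            oracle_changes.extend(100.0 * (s[1:] - s[:-1]) / s[:-1])
        out = fl.mean_percent_change(_table(rows), "parietal", "carrier")
        assert out == pytest.approx(float(np.mean(oracle_changes)), abs=1e-12)

    def test_study_scale_parietal_decline_reproduced(self):
        """The default carrier parietal decline comes back near -1.5%/interval."""
        subjects, truth = fl.simulate_cohort(24, seed=17)
        table = fl.suvr_table_from_truth(truth, subjects, noise_sd=0.005, seed=18)
        carrier = fl.mean_percent_change(table, "parietal", "carrier")
        noncarrier = fl.mean_percent_change(table, "parietal", "non-carrier")
        assert carrier == pytest.approx(-1.5, abs=0.3)
        assert noncarrier == pytest.approx(-0.31, abs=0.3)

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError):
            fl.mean_percent_change(_table([]), "parietal", "carriers")
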