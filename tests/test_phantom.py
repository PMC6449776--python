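"""Phantom generator tests: atlas geometry, cohort simulation, rendering."""

import numpy as np
import pytest

import fdglong as fl
from fdglong.phantom import GridSizeError, RegionEffect


class TestMakeAtlas:
    def test_construction_contract(self):
        atlas = fl.make_atlas((40, 48, 40), 10, voxel_size_mm=(1.5, 1.5, 1.5), seed=7)
        counts = atlas.voxel_counts()
        assert len(counts) == 10
        assert all(c > 0 for c in counts.values())
        assert "cerebellum" in counts

    def test_minimal_two_region_case(self):
        atlas = fl.make_atlas((8, 8, 8), 2, seed=1)
        counts = atlas.voxel_counts()
        assert set(counts) == {"cerebellum", "parietal"}
        assert all(c > 0 for c in counts.values())
        assert (atlas.labels == 0).any()  # background remains

    def test_deterministic_for_fixed_seed(self):
        a = fl.make_atlas((24, 28, 24), 8, seed=3)
        b = fl.make_atlas((24, 28, 24), 8, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.names == b.names

    def test_small_regions_capped(self, small_atlas):
        counts = small_atlas.voxel_counts()
        for name in fl.SMALL_REGIONS & set(counts):
            assert counts[name] <= 400, f"{name} too large for a partial-volume testbed"

    def test_grid_too_small_rejected(self):
        with pytest.raises(GridSizeError):
            fl.make_atlas((4, 4, 4), 10, seed=0)

    def test_reference_required(self):
        with pytest.raises(ValueError):
            fl.make_atlas((20, 20, 20), 2, seed=0, region_names=("parietal", "caudate"))


class TestSubjectRecord:
    def _kwargs(self, **over):
        base = dict(
            subject_id="s0", carrier=True, sex="F", education_years=16.0,
            baseline_age=70.0, scan_months=(0, 6, 12), converted=False,
            event_or_censor_month=12.0,
        )
        base.update(over)
        return base

    def test_valid_record_accepted(self):
        rec = fl.SubjectRecord(**self._kwargs())
        assert rec.scan_months == (0, 6, 12)

    @pytest.mark.parametrize("over", [
        {"scan_months": (6, 12)},
        {"scan_months": (0, 12, 6)},
        {"education_years": -1.0},
        {"sex": "X"},
        {"event_or_censor_month": 24.0},
    ])
    def test_invalid_records_rejected(self, over):
        with pytest.raises(ValueError):
            fl.SubjectRecord(**self._kwargs(**over))


class TestSimulateCohort:
    def test_zero_slopes_give_constant_truth(self):
        effects = {
            "cerebellum": RegionEffect(1.0, 0.0, 0.0),
            "parietal": RegionEffect(1.1, 0.0, 0.0),
        }
        subjects, truth = fl.simulate_cohort(3, (0, 6, 12), effects, seed=2)
        for s in subjects:
            vals = [truth.value(s.subject_id, m, "parietal") for m in s.scan_months]
            assert np.ptp(vals) == 0.0

    def test_reference_region_constant_one(self):
        subjects, truth = fl.simulate_cohort(3, seed=4)
        for s in subjects:
            for m in s.scan_months:
                assert truth.value(s.subject_id, m, "cerebellum") == 1.0

    def test_deterministic_for_fixed_seed(self):
        s1, t1 = fl.simulate_cohort(3, seed=9)
        s2, t2 = fl.simulate_cohort(3, seed=9)
        assert s1 == s2
        assert t1.regional_truth == t2.regional_truth

    def test_extreme_negative_slope_rejected(self):
        effects = {
            "cerebellum": RegionEffect(1.0, 0.0, 0.0),
            "parietal": RegionEffect(1.0, -0.05, -0.05),
        }
        with pytest.raises(ValueError, match="non-positive"):
            fl.simulate_cohort(3, effect_params=effects, seed=0)

    def test_reference_effect_must_be_pinned(self):
        effects = {
            "cerebellum": RegionEffect(1.2, 0.0, 0.0),
            "parietal": RegionEffect(1.0, 0.0, 0.0),
        }
        with pytest.raises(ValueError, match="reference"):
            fl.simulate_cohort(3, effect_params=effects, seed=0)

    def test_conversion_hazard_ordering_enforced(self):
        with pytest.raises(ValueError, match="hazard"):
            fl.simulate_cohort(3, seed=0, conversion_hazards=(0.001, 0.01))

    def test_carriers_convert_more_often_on_average(self):
        n_c = n_n = 0
        for seed in range(8):
            subjects, _ = fl.simulate_cohort(24, seed=seed)
            n_c += sum(s.converted for s in subjects if s.carrier)
            n_n += sum(s.converted for s in subjects if not s.carrier)
        assert n_c > n_n


class TestSlopeCalibration:
    @pytest.mark.parametrize("pct", [-1.5, -0.31, 0.291, 1.152])
    def test_calibrated_slope_reproduces_target_percent_change(self, pct):
        months = np.asarray(fl.DEFAULT_SCAN_MONTHS, dtype=float)
        s = fl.slope_for_percent_change(1.044, pct, fl.DEFAULT_SCAN_MONTHS)
        v = 1.044 + s * months
        observed = float(np.mean(100.0 * (v[1:] - v[:-1]) / v[:-1]))
        assert observed == pytest.approx(pct, abs=1e-9)


class TestRenderVisitImage:
    def test_identity_rendering_without_blur_or_noise(self, small_atlas):
        names = tuple(small_atlas.names[k] for k in sorted(small_atlas.names))
        subjects, truth = fl.simulate_cohort(2, (0, 6), seed=5, region_names=names)
        img = fl.render_visit_image(
            truth, "sub000", 0, small_atlas, psf_fwhm_mm=0.0, noise_sd=0.0
        )
        means = fl.roi_means(img, small_atlas)
        for region, mean in means.items():
            assert mean == pytest.approx(truth.value("sub000", 0, region), abs=1e-12)

    def test_deterministic_for_fixed_seed(self, small_atlas):
        names = tuple(small_atlas.names[k] for k in sorted(small_atlas.names))
        _, truth = fl.simulate_cohort(2, (0, 6), seed=5, region_names=names)
        a = fl.render_visit_image(truth, "sub000", 0, small_atlas, seed=42)
        b = fl.render_visit_image(truth, "sub000", 0, small_atlas, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_visit_rejected(self, small_atlas):
        names = tuple(small_atlas.names[k] for k in sorted(small_atlas.names))
        _, truth = fl.simulate_cohort(2, (0, 6), seed=5, region_names=names)
        with pytest.raises(KeyError):
            fl.render_visit_image(truth, "sub000", 99, small_atlas)

    def test_blurred_small_region_mean_between_truth_and_surround(self, small_atlas):
        # hot small region in a cooler surround: partial-volume spill
        # pulls the ROI mean strictly toward the surround
        names = tuple(small_atlas.names[k] for k in sorted(small_atlas.names))
        effects = {n: RegionEffect(1.0, 0.0, 0.0) for n in names}
        effects["amygdala"] = RegionEffect(1.2, 0.0, 0.0)
        _, truth = fl.simulate_cohort(2, (0, 6), effects, seed=5, region_names=names)
        img = fl.render_visit_image(
            truth, "sub000", 0, small_atlas, psf_fwhm_mm=8.0, noise_sd=0.0
        )
        mean = fl.roi_means(img, small_atlas)["amygdala"]
        assert 1.0 < mean < 1.2

    def test_atrophy_erodes_region_and_fills_with_csf(self, small_atlas):
        names = tuple(small_atlas.names[k] for k in sorted(small_atlas.names))
        _, truth = fl.simulate_cohort(
            2, (0, 60), seed=5, region_names=names, atrophy_rates={"amygdala": 0.005}
        )
        img0 = fl.render_visit_image(
            truth, "sub000", 0, small_atlas, psf_fwhm_mm=0.0, noise_sd=0.0
        )
        img1 = fl.render_visit_image(
            truth, "sub000", 60, small_atlas, psf_fwhm_mm=0.0, noise_sd=0.0
        )
        mask = small_atlas.mask("amygdala")
        truth_val = truth.value("sub000", 60, "amygdala")
        # 30% of the region volume is eroded to CSF uptake at month 60
        n_csf = int((img1.values[mask] < truth_val - 1e-9).sum())
        assert n_csf == pytest.approx(0.30 * mask.sum(), rel=0.05)
        assert (img0.values[mask] > 0.5).all()

    def test_smoothed_noise_is_spatially_correlated(self, small_atlas):
        names = tuple(small_atlas.names[k] for k in sorted(small_atlas.names))
        _, truth = fl.simulate_cohort(2, (0, 6), seed=5, region_names=names)
        white = fl.render_visit_image(
            truth, "sub000", 0, small_atlas, psf_fwhm_mm=0.0, noise_sd=0.05, seed=1
        )
        smooth = fl.render_visit_image(
            truth, "sub000", 0, small_atlas, psf_fwhm_mm=0.0, noise_sd=0.05, seed=1,
            noise_fwhm_mm=8.0,
        )
        def lag1(v):
            d = v - v.mean()
            return float((d[:-1] * d[1:]).mean() / (d * d).mean())
        noise_w = (white.values - fl.render_visit_image(
            truth, "sub000", 0, small_atlas, psf_fwhm_mm=0.0, noise_sd=0.0).values).ravel()
        noise_s = (smooth.values - fl.render_visit_image(
            truth, "sub000", 0, small_atlas, psf_fwhm_mm=0.0, noise_sd=0.0).values).ravel()
        assert abs(lag1(noise_w)) < 0.1
        assert lag1(noise_s) > 0.5


class TestSlopeRecoveryMonotonicity:
    def test_larger_injected_difference_gives_larger_estimate(self):
        """Mean |interaction| over replicates grows with the injected |slope difference|."""
        deltas = (0.0, 0.0008, 0.0016)
        mean_abs = []
        for delta in deltas:
            effects = {
                "cerebellum": RegionEffect(1.0, 0.0, 0.0),
                "parietal": RegionEffect(1.05, -0.0005 - delta, -0.0005),
            }
            estimates = []
            for rep in range(4):
                subjects, truth = fl.simulate_cohort(
                    12, (0, 12, 24, 36, 48), effects, seed=100 + rep
                )
                table = fl.suvr_table_from_truth(
                    truth, subjects, noise_sd=0.01, seed=200 + rep
                )
                res = fl.fit_roi_lmm(table, "parietal", subjects)
                estimates.append(res.interaction_estimate)
            mean_abs.append(float(np.mean(np.abs(estimates))))
        assert mean_abs[0] < mean_abs[1] < mean_abs[2]
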