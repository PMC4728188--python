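"""Ordered reliability checks, category maps, masking and reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dceqc import (CheckThresholds, ErrorCategory, OUTSIDE, build_error_map,
                   categorize_voxel, category_report, histogram_values,
                   mask_from_categories)
from dceqc.tofts import PKParams

THR = CheckThresholds()


def fake_fit(ktrans=0.2, ve=0.3, vp=0.02, converged=True):
    class _Fit:
        params = PKParams(ktrans, ve, vp)
        kep = ktrans / ve if ve > 0 else 0.0
    _Fit.converged = converged
    return _Fit()


def trace(values):
    v = np.asarray(values, dtype=float)
    return v, np.ones_like(v, dtype=bool)


class TestCategorizeVoxel:
    def test_high_sd_wins_regardless_of_later_checks(self):
        # sd ~ 7.5 mM > 5 mM, and mean is also tiny -> earliest check wins
        c, v = trace(np.resize([15.0, -14.9], 100))
        assert categorize_voxel(c, v, fake_fit(), THR) == ErrorCategory.GD_SD_TOO_BIG

    def test_nonreal_frame_detected_after_sd(self):
        c, v = trace(np.full(100, 0.5))
        v[40] = False
        assert categorize_voxel(c, v, fake_fit(), THR) == ErrorCategory.GD_NOT_REAL

    def test_low_mean_is_gd_too_small(self):
        c, v = trace(np.full(100, 0.005))
        assert categorize_voxel(c, v, None, THR,
                                prefit_only=False) == ErrorCategory.GD_TOO_SMALL

    def test_nonconvergence(self):
        c, v = trace(np.full(100, 0.5))
        assert categorize_voxel(c, v, fake_fit(converged=False),
                                THR) == ErrorCategory.NON_CONVERGENCE

    @pytest.mark.parametrize("fit,expected", [
        (fake_fit(), ErrorCategory.GOOD),
        (fake_fit(ve=1.2), ErrorCategory.VE_GE_ONE),
        (fake_fit(ve=1.0), ErrorCategory.VE_GE_ONE),      # boundary fails
        (fake_fit(vp=1.3), ErrorCategory.VP_GE_ONE),
        (fake_fit(ktrans=12.0, ve=0.9), ErrorCategory.PARAM_TOO_LARGE),
        (fake_fit(ktrans=8.0, ve=0.5), ErrorCategory.PARAM_TOO_LARGE),  # kep=16
    ])
    def test_post_fit_rules(self, fit, expected):
        c, v = trace(np.full(100, 0.5))
        assert categorize_voxel(c, v, fit, THR) == expected

    def test_ve_before_vp_before_param(self):
        c, v = trace(np.full(100, 0.5))
        fit = fake_fit(ktrans=20.0, ve=1.5, vp=1.5)
        assert categorize_voxel(c, v, fit, THR) == ErrorCategory.VE_GE_ONE

    def test_missing_fit_after_passing_prefit_is_contract_violation(self):
        c, v = trace(np.full(100, 0.5))
        with pytest.raises(RuntimeError):
            categorize_voxel(c, v, None, THR)

    def test_prefit_only_returns_none_on_pass(self):
        c, v = trace(np.full(100, 0.5))
        assert categorize_voxel(c, v, None, THR, prefit_only=True) is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(sd=st.floats(5.0, 30.0), mean=st.floats(0.0, 0.009))
    def test_multi_failure_always_earliest(self, sd, mean):
        # fails both the sd check (1) and the mean check (3): category is (1)
        c = np.resize([mean + sd, mean - sd], 120)
        v = np.ones_like(c, dtype=bool)
        assert categorize_voxel(c, v, None, THR,
                                prefit_only=True) == ErrorCategory.GD_SD_TOO_BIG

    def test_optional_variance_ratio_check(self):
        thr = CheckThresholds(post_pre_var_ratio_max=4.0)
        rng = np.random.default_rng(0)
        c = np.concatenate([rng.normal(0.2, 0.01, 10), rng.normal(0.5, 0.5, 90)])
        v = np.ones_like(c, dtype=bool)
        assert categorize_voxel(c, v, None, thr,
                                prefit_only=True) == ErrorCategory.GD_SD_TOO_BIG
        # off by default
        assert categorize_voxel(c, v, None, THR, prefit_only=True) is None


class TestThresholdDefaults:
    def test_defaults_match_published_settings(self):
        t = CheckThresholds()
        assert t.gd_sd_max == 5.0
        assert t.gd_mean_min == 0.01
        assert t.ktrans_max == 10.0
        assert t.kep_max == 15.0
        assert t.ve_limit == 1.0 and t.vp_limit == 1.0
        assert t.rel_tol == 1e-6
        assert t.max_iter == 100

    def test_each_threshold_flips_its_category(self):
        c_ok, v = trace(np.full(100, 0.5))
        # gd_sd_max: tighten until the clean trace fails
        tight = CheckThresholds(gd_sd_max=1e-9)
        assert categorize_voxel(c_ok + np.resize([0.001, -0.001], 100), v,
                                None, tight,
                                prefit_only=True) == ErrorCategory.GD_SD_TOO_BIG
        # gd_mean_min: raise above the trace mean
        high_mean = CheckThresholds(gd_mean_min=0.6)
        assert categorize_voxel(c_ok, v, None, high_mean,
                                prefit_only=True) == ErrorCategory.GD_TOO_SMALL
        # ktrans_max / kep_max / ve_limit / vp_limit
        assert categorize_voxel(c_ok, v, fake_fit(ktrans=0.2),
                                CheckThresholds(ktrans_max=0.1)) == \
            ErrorCategory.PARAM_TOO_LARGE
        assert categorize_voxel(c_ok, v, fake_fit(ktrans=0.2, ve=0.3),
                                CheckThresholds(kep_max=0.5)) == \
            ErrorCategory.PARAM_TOO_LARGE
        assert categorize_voxel(c_ok, v, fake_fit(ve=0.3),
                                CheckThresholds(ve_limit=0.25)) == \
            ErrorCategory.VE_GE_ONE
        assert categorize_voxel(c_ok, v, fake_fit(vp=0.02),
                                CheckThresholds(vp_limit=0.01)) == \
            ErrorCategory.VP_GE_ONE

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CheckThresholds(gd_sd_max=0.0)
        with pytest.raises(ValueError):
            CheckThresholds(max_iter=0)


def _toy_map(codes, mask=None):
    codes = np.asarray(codes, dtype=np.int16)
    mask = np.ones_like(codes, dtype=bool) if mask is None else mask
    return build_error_map(codes, mask)


class TestErrorCategoryMap:
    def test_tally_conserves_masked_count(self):
        codes = np.zeros((4, 4, 2), dtype=int)
        codes[0, 0, 0] = int(ErrorCategory.VE_GE_ONE)
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[:2] = True
        emap = _toy_map(codes, mask)
        assert sum(emap.tally.values()) == int(mask.sum())
        assert np.all(emap.categories[~mask] == OUTSIDE)

    def test_all_good_renders_black(self):
        emap = _toy_map(np.zeros((3, 3, 1), dtype=int))
        rgb = emap.render_slice(0)
        assert np.all(rgb == 0)

    def test_zero_uptake_core_renders_contiguous_red(self):
        codes = np.zeros((6, 6, 1), dtype=int)
        codes[2:4, 2:4, 0] = int(ErrorCategory.GD_TOO_SMALL)
        rgb = _toy_map(codes).render_slice(0)
        red = (rgb == [255, 0, 0]).all(axis=-1)
        assert red[2:4, 2:4].all() and red.sum() == 4

    def test_ve_and_vp_share_green(self):
        codes = np.array([[[int(ErrorCategory.VE_GE_ONE)],
                           [int(ErrorCategory.VP_GE_ONE)]]])
        rgb = _toy_map(codes).render_slice(0)
        assert (rgb[0, 0] == [0, 255, 0]).all() and (rgb[0, 1] == [0, 255, 0]).all()

    def test_uncategorized_masked_voxel_rejected(self):
        codes = np.full((2, 2, 1), 99, dtype=int)
        with pytest.raises(ValueError):
            _toy_map(codes)

    def test_png_round_trip(self, tmp_path):
        from PIL import Image

        codes = np.zeros((4, 4, 2), dtype=int)
        codes[1, 1, 0] = int(ErrorCategory.NON_CONVERGENCE)
        paths = _toy_map(codes).save_slices_png(tmp_path, scale=1)
        assert len(paths) == 2
        img = np.asarray(Image.open(paths[0]))
        assert tuple(img[1, 1]) == (255, 0, 255)


class TestMaskingAndHistogram:
    def _core_map(self):
        codes = np.zeros((6, 6, 1), dtype=int)
        codes[2:4, 2:4, 0] = int(ErrorCategory.GD_TOO_SMALL)
        codes[0, 5, 0] = int(ErrorCategory.VE_GE_ONE)
        return _toy_map(codes)

    def test_accept_all_codes_recovers_roi(self):
        emap = self._core_map()
        mask = mask_from_categories(emap, accepted=set(ErrorCategory))
        assert mask.sum() == emap.mask.sum()

    def test_accept_good_excludes_exactly_the_core(self):
        emap = self._core_map()
        mask = mask_from_categories(emap, accepted={ErrorCategory.GOOD})
        assert not mask[2:4, 2:4, 0].any()
        assert mask.sum() == emap.mask.sum() - 5

    def test_default_histogram_assigns_zero_to_no_uptake(self):
        emap = self._core_map()
        ktrans = np.full((6, 6, 1), 0.7)
        vals = histogram_values(ktrans, emap)
        assert (vals == 0.0).sum() == 4          # the GD_TOO_SMALL core
        assert (vals == 0.7).sum() == 36 - 5     # GOOD voxels keep their value

    def test_empty_accept_set_rejected(self):
        with pytest.raises(ValueError):
            mask_from_categories(self._core_map(), accepted=set())


class TestCategoryReport:
    def test_identical_maps_have_zero_difference(self):
        emap = _toy_map(np.zeros((3, 3, 1), dtype=int))
        df = category_report({"b1": emap, "b2": emap})
        assert df.loc["diff_b2", "GOOD"] == 0

    def test_row_sums_equal_masked_count(self):
        codes = np.zeros((4, 4, 1), dtype=int)
        codes[0] = int(ErrorCategory.VE_GE_ONE)
        df = category_report({"a": _toy_map(codes), "b": _toy_map(codes)})
        names = [c.name for c in ErrorCategory]
        assert (df.loc[["a", "b"], names].sum(axis=1) == 16).all()

    def test_grid_mismatch_rejected(self):
        a = _toy_map(np.zeros((3, 3, 1), dtype=int))
        b = _toy_map(np.zeros((4, 4, 1), dtype=int))
        with pytest.raises(ValueError):
            category_report({"a": a, "b": b})

    def test_small_aif_produces_more_ve_failures(self, noisy_phantom, noisy_result):
        # mirrors the AIF-comparison: same data refit with AIF/3
        from dceqc.config import PipelineConfig
        from dceqc.pipeline import run_pipeline

        data = noisy_phantom
        res_small = run_pipeline(
            data.dynamic, data.times, data.spec.acq, data.mfa, data.mfa_angles,
            data.tumour_mask, artery_mask=data.artery_mask,
            config=PipelineConfig(), aif_override=data.truth.aif.scaled(1 / 3))
        df = category_report({"true_aif": noisy_result.error_map,
                              "third_aif": res_small.error_map})
        assert df.loc["third_aif", "VE_GE_ONE"] >= df.loc["true_aif", "VE_GE_ONE"]
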