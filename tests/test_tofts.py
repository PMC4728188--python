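"""Extended Tofts model: forward evaluation, fitting, volume assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dceqc import (ArterialInputFunction, ExtendedToftsModel, PKParams,
                   SolverControls, etm_forward, fit_etm, fit_volume)
from dceqc.errormap import ErrorCategory
from dceqc.signal import ConcentrationSeries

from conftest import quadrature_oracle


class TestForwardModel:
    def test_ktrans_zero_is_pure_vascular(self, default_aif, frame_times):
        p = PKParams(ktrans=0.0, ve=0.0, vp=0.05)
        ct = etm_forward(p, default_aif, frame_times)
        np.testing.assert_allclose(ct, 0.05 * default_aif.cp, rtol=1e-12)

    @pytest.mark.parametrize("ktrans", [0.05, 0.2, 1.0])
    @pytest.mark.parametrize("ve", [0.1, 0.3, 0.6])
    @pytest.mark.parametrize("vp", [0.0, 0.02, 0.1])
    def test_matches_quadrature_oracle(self, default_aif, frame_times, ktrans, ve, vp):
        p = PKParams(ktrans, ve, vp)
        ct = etm_forward(p, default_aif, frame_times)
        oracle = quadrature_oracle(p, default_aif, frame_times)
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(ct - oracle)) / scale < 1e-3

    def test_constant_input_closed_form(self, frame_times):
        c = 1.2
        aif = ArterialInputFunction(frame_times, np.full_like(frame_times, c), "model")
        p = PKParams(ktrans=0.2, ve=0.4, vp=0.0)
        ct = etm_forward(p, aif, frame_times)
        analytic = p.ve * c * (1 - np.exp(-(p.ktrans / p.ve) * frame_times / 60.0))
        assert np.max(np.abs(ct - analytic)) < 1e-6

    def test_nonuniform_grid_agrees_with_uniform_path(self, default_aif):
        # same samples, one grid perturbed infinitesimally -> loop branch
        t_uni = np.arange(0.0, 300.0, 3.0)
        t_non = t_uni.copy()
        t_non[1:] += np.linspace(0, 0.5, t_non.size - 1)  # irregular spacing
        p = PKParams(0.25, 0.35, 0.02)
        ct_non = etm_forward(p, default_aif, t_non)
        oracle = quadrature_oracle(p, default_aif, t_non)
        assert np.max(np.abs(ct_non - oracle)) / np.max(np.abs(oracle)) < 1e-3

    def test_monotone_in_vp(self, default_aif, frame_times):
        base = PKParams(0.15, 0.3, 0.01)
        more = PKParams(0.15, 0.3, 0.08)
        diff = etm_forward(more, default_aif, frame_times) - etm_forward(
            base, default_aif, frame_times)
        assert np.all(diff >= -1e-15)

    def test_invalid_ve_rejected(self, default_aif, frame_times):
        with pytest.raises(ValueError):
            etm_forward(PKParams(0.2, 0.0, 0.01), default_aif, frame_times)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(ktrans=st.floats(0.01, 2.0), ve=st.floats(0.05, 0.9),
           vp=st.floats(0.0, 0.2), beta=st.floats(1.5, 4.0))
    def test_aif_scaling_covariance_exact(self, default_aif, frame_times,
                                          ktrans, ve, vp, beta):
        # Cp/beta with beta-scaled params leaves the curve identical
        ct = etm_forward(PKParams(ktrans, ve, vp), default_aif, frame_times)
        ct_b = etm_forward(PKParams(beta * ktrans, beta * ve, beta * vp),
                           default_aif.scaled(1 / beta), frame_times)
        np.testing.assert_allclose(ct_b, ct, rtol=1e-9, atol=1e-12)


class TestFitEtm:
    def test_noiseless_self_consistency(self, default_aif, frame_times):
        truth = PKParams(0.15, 0.25, 0.03)
        ct = etm_forward(truth, default_aif, frame_times)
        res = fit_etm(ct, default_aif, frame_times)
        assert res.converged
        for got, want in zip(res.params.as_array(), truth.as_array()):
            assert got == pytest.approx(want, rel=1e-3)

    def test_null_signal_drives_params_to_zero(self, default_aif, frame_times):
        res = fit_etm(np.zeros_like(frame_times), default_aif, frame_times)
        assert res.converged
        assert res.params.ktrans < 1e-4
        assert res.params.vp < 1e-4

    def test_beta_scaling_of_fitted_parameters(self, default_aif, frame_times):
        truth = PKParams(0.15, 0.25, 0.03)
        ct = etm_forward(truth, default_aif, frame_times)
        beta = 2.0
        res = fit_etm(ct, default_aif.scaled(1 / beta), frame_times)
        assert res.params.ktrans == pytest.approx(beta * truth.ktrans, rel=1e-2)
        assert res.params.ve == pytest.approx(beta * truth.ve, rel=1e-2)
        assert res.params.vp == pytest.approx(beta * truth.vp, rel=1e-2)
        assert res.kep == pytest.approx(truth.ktrans / truth.ve, rel=1e-2)

    def test_max_iter_reported_as_nonconvergence(self, default_aif, frame_times):
        truth = PKParams(0.5, 0.3, 0.05)
        ct = etm_forward(truth, default_aif, frame_times)
        res = fit_etm(ct, default_aif, frame_times,
                      ctrl=SolverControls(rel_tol=1e-15, max_iter=1))
        assert not res.converged
        assert res.convergence_reason == "max_iter"

    def test_recovery_under_noise(self, default_aif, frame_times):
        rng = np.random.default_rng(3)
        truth = PKParams(0.2, 0.3, 0.02)
        clean = etm_forward(truth, default_aif, frame_times)
        errs = []
        for _ in range(200):
            ct = clean + rng.normal(0, 0.02, clean.shape)
            res = fit_etm(ct, default_aif, frame_times)
            errs.append(abs(res.params.ktrans - truth.ktrans) / truth.ktrans)
        assert np.median(errs) < 0.10

    def test_too_few_frames_rejected(self, default_aif):
        with pytest.raises(ValueError):
            ExtendedToftsModel(np.zeros(5), np.arange(5.0), default_aif)

    def test_summary_mentions_estimates(self, default_aif, frame_times):
        ct = etm_forward(PKParams(0.15, 0.25, 0.03), default_aif, frame_times)
        text = fit_etm(ct, default_aif, frame_times).summary()
        assert "Ktrans" in text and "converged" in text


class TestFitVolume:
    def _conc_volume(self, traces, n_base=10):
        arr = np.zeros((len(traces), 1, 1, len(traces[0])))
        for i, tr in enumerate(traces):
            arr[i, 0, 0] = tr
        return ConcentrationSeries(conc=arr, valid=np.isfinite(arr),
                                   baseline_frames=n_base)

    def test_assembly_matches_per_voxel_fits(self, default_aif, frame_times):
        p1, p2 = PKParams(0.1, 0.2, 0.01), PKParams(0.3, 0.4, 0.05)
        traces = [etm_forward(p, default_aif, frame_times) for p in (p1, p2)]
        conc = self._conc_volume(traces)
        mask = np.ones((2, 1, 1), dtype=bool)
        out = fit_volume(conc, mask, default_aif, frame_times)
        for i, p in enumerate((p1, p2)):
            single = fit_etm(traces[i], default_aif, frame_times)
            assert out.maps.ktrans[i, 0, 0] == pytest.approx(
                single.params.ktrans, rel=1e-9)
        assert (out.table.category == "GOOD").all()

    def test_necrotic_voxel_not_fitted(self, default_aif, frame_times):
        good = etm_forward(PKParams(0.2, 0.3, 0.02), default_aif, frame_times)
        necrotic = np.full_like(frame_times, 0.004)  # below 0.01 mM mean
        conc = self._conc_volume([good, necrotic])
        mask = np.ones((2, 1, 1), dtype=bool)
        out = fit_volume(conc, mask, default_aif, frame_times)
        assert out.categories[1, 0, 0] == int(ErrorCategory.GD_TOO_SMALL)
        assert np.isnan(out.maps.ktrans[1, 0, 0])
        assert out.categories[0, 0, 0] == int(ErrorCategory.GOOD)

    def test_every_masked_voxel_has_exactly_one_category(self, noiseless_result,
                                                         noiseless_phantom):
        cats = noiseless_result.fits.categories
        mask = noiseless_phantom.tumour_mask
        codes = {int(c) for c in ErrorCategory}
        assert set(np.unique(cats[mask])).issubset(codes)
        assert np.all(cats[~mask] == -1)

    def test_empty_mask_rejected(self, default_aif, frame_times):
        conc = self._conc_volume([np.zeros_like(frame_times)])
        with pytest.raises(ValueError):
            fit_volume(conc, np.zeros((1, 1, 1), dtype=bool), default_aif,
                       frame_times)
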