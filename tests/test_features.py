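"""Feature extraction, photobleaching compensation, tau fitting, Pearson
selection."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from fiberspec.channels import DEFAULT_TAU, SEGMENT_LENGTH
from fiberspec.errors import ConfigError, FitError, InputError, StateError
from fiberspec.features import (
    extract_channel,
    extract_features,
    feature_frame,
    fit_tau,
    pearson_select,
    photobleach_correct,
)
from fiberspec.preprocess import PreprocessPipeline, merge
from fiberspec.sim import NoiseConfig, Simulator, emit_spectrum, lorentzian
from fiberspec.workflow import scans_to_features


class TestExtraction:
    def test_clean_lorentzian_height_position_width(self):
        amp, fwhm, center = 750.0, 24.0, 200
        seg = amp * lorentzian(np.arange(SEGMENT_LENGTH, dtype=float),
                               center, fwhm)
        pf = extract_channel(seg, center)
        assert pf.height == pytest.approx(amp, rel=1e-9)
        assert pf.position == center
        assert pf.width == pytest.approx(fwhm, abs=1.0)
        assert pf.prominence == pytest.approx(amp, rel=0.01)

    def test_triangle_area_is_exact_for_trapezoid_rule(self):
        seg = np.zeros(SEGMENT_LENGTH)
        center, half_width, height = 100, 10, 2.0
        for k in range(-half_width, half_width + 1):
            seg[center + k] = height * (1 - abs(k) / half_width)
        pf = extract_channel(seg, center)
        assert pf.area == pytest.approx(height * half_width, rel=1e-12)

    def test_overlapping_peaks_keep_channel_identity(self, channels,
                                                     ref_state, noiseless):
        ph, glu = channels["pH"], channels["glucose"]
        both = emit_spectrum([ph, glu], ref_state, 0.0, noiseless)
        single_ph = emit_spectrum([ph], ref_state, 0.0, noiseless)
        single_glu = emit_spectrum([glu], ref_state, 0.0, noiseless)
        pf_ph = extract_channel(both.intensities, 34)
        pf_glu = extract_channel(both.intensities, 28)
        assert abs(pf_ph.position - 34) <= 15
        assert abs(pf_glu.position - 28) <= 15
        assert pf_ph.height > single_ph.intensities[34]
        assert pf_glu.height > single_glu.intensities[28]

    def test_fallback_to_nominal_index_without_local_maximum(self):
        seg = np.linspace(0.0, 10.0, SEGMENT_LENGTH)  # monotone, no peak
        pf = extract_channel(seg, 100, search_radius=5)
        assert not pf.located
        assert pf.position == 100
        assert pf.height == pytest.approx(seg[100])

    def test_positions_reported_as_merged_indices(self, channels, ref_state,
                                                  noiseless):
        sim = Simulator(noise=noiseless)
        merged = PreprocessPipeline().process_scan(sim.run_scan(ref_state))
        fv = extract_features(merged, channels)
        assert abs(fv.peaks["calcium"].position - 1262) <= 15
        assert abs(fv.peaks["temperature"].position - 884) <= 15


class TestPhotobleachCorrect:
    def _fv(self, channels, exposure_units=0.0):
        sim = Simulator(noise=NoiseConfig.noiseless())
        from fiberspec.sim import reference_state
        merged = PreprocessPipeline().process_scan(
            sim.run_scan(reference_state()))
        fv = extract_features(merged, channels)
        fv.exposures = {name: exposure_units for name in fv.exposures}
        return fv

    def test_zero_exposure_leaves_features_unchanged(self, channels):
        fv = self._fv(channels, exposure_units=0.0)
        out = photobleach_correct(fv, DEFAULT_TAU)
        for name in fv.peaks:
            assert out.peaks[name].height == fv.peaks[name].height
        assert out.corrected

    def test_one_tau_multiplies_height_by_e(self, channels):
        fv = self._fv(channels)
        fv.exposures = {name: DEFAULT_TAU[name] for name in fv.exposures}
        out = photobleach_correct(fv, DEFAULT_TAU)
        for name in fv.peaks:
            assert out.peaks[name].height == pytest.approx(
                fv.peaks[name].height * math.e, rel=1e-12)

    def test_width_and_position_never_change(self, channels):
        fv = self._fv(channels, exposure_units=3.7)
        out = photobleach_correct(fv, DEFAULT_TAU)
        for name in fv.peaks:
            assert out.peaks[name].width == fv.peaks[name].width
            assert out.peaks[name].position == fv.peaks[name].position

    def test_double_correction_rejected(self, channels):
        fv = self._fv(channels)
        out = photobleach_correct(fv, DEFAULT_TAU)
        with pytest.raises(StateError):
            photobleach_correct(out, DEFAULT_TAU)

    def test_missing_tau_rejected(self, channels):
        fv = self._fv(channels)
        with pytest.raises(ConfigError):
            photobleach_correct(fv, {"pH": 37.0})

    def test_correction_inverts_bleaching_through_the_simulator(
            self, channels, ref_state):
        # headline invariant, per channel on its own single-sensor frame
        # (overlapped peaks mix taus; that residual is the regression
        # layer's job, not the scalar exp(t/tau) correction's)
        from fiberspec.preprocess import baseline_correct, denoise
        noiseless = NoiseConfig.noiseless()
        for name, ch in channels.items():
            out = {}
            for exposure_s in (0.0, 300.0):
                frame = emit_spectrum([ch], ref_state, exposure_s, noiseless)
                seg = baseline_correct(denoise(frame)).intensities
                pf = extract_channel(seg, ch.segment_pixel)
                gain = math.exp((exposure_s / 60.0) / ch.tau)
                out[exposure_s] = (pf.height * gain, pf.area * gain)
            assert out[300.0][0] == pytest.approx(out[0.0][0], rel=0.005)
            assert out[300.0][1] == pytest.approx(out[0.0][1], rel=0.005)


class TestFitTau:
    @pytest.mark.parametrize("tau", [48.8, 133.7])
    def test_exact_trace_recovers_characterized_constant(self, tau):
        t = np.arange(0.0, 181.0, 10.0)
        tau_hat, r2 = fit_tau(t, 3.0 * np.exp(-t / tau))
        assert tau_hat == pytest.approx(tau, rel=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=10.0, max_value=200.0))
    def test_noiseless_recovery_for_any_tau_in_range(self, tau):
        t = np.linspace(0.0, 2.0 * tau, 25)
        tau_hat, _ = fit_tau(t, 1000.0 * np.exp(-t / tau))
        assert abs(tau_hat - tau) / tau < 1e-6

    def test_one_percent_noise_keeps_tau_within_five_percent(self):
        rng = np.random.default_rng(77)
        tau = 51.13
        t = np.arange(0.0, 181.0, 5.0)
        y = 1000.0 * np.exp(-t / tau) * (1 + rng.normal(0, 0.01, t.size))
        tau_hat, _ = fit_tau(t, y)
        assert abs(tau_hat - tau) / tau < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            fit_tau([0, 1], [1.0, 0.5])
        with pytest.raises(InputError):
            fit_tau([0, 1, 2], [1.0, -0.5, 0.2])
        with pytest.raises(FitError):
            fit_tau([0, 1, 2], [2.0, 2.0, 2.0])


class TestPearsonSelect:
    def test_feature_equal_to_label_is_selected(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=200)
        X = pd.DataFrame({"copy": y, "noise": rng.normal(size=200)})
        mask, table = pearson_select(X, pd.DataFrame({"y": y}), threshold=0.5)
        assert bool(mask["copy"]) is True
        assert table.loc["copy", "y"] == pytest.approx(1.0)

    def test_independent_noise_not_selected_at_half_threshold(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=1000)
        X = pd.DataFrame({"noise": rng.normal(size=1000)})
        mask, _ = pearson_select(X, pd.DataFrame({"y": y}), threshold=0.5)
        assert bool(mask["noise"]) is False

    def test_matches_brute_force_pairwise_pearson(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(60, 7)),
                         columns=[f"f{i}" for i in range(7)])
        Y = pd.DataFrame(rng.normal(size=(60, 3)),
                         columns=["a", "b", "c"])
        _, table = pearson_select(X, Y, threshold=0.5)
        for f in X.columns:
            for lab in Y.columns:
                expected = pearsonr(X[f], Y[lab]).statistic
                assert table.loc[f, lab] == pytest.approx(expected,
                                                          abs=1e-12)

    def test_zero_variance_feature_warns_with_r_zero(self):
        X = pd.DataFrame({"flat": np.ones(50),
                          "ok": np.linspace(0, 1, 50)})
        Y = pd.DataFrame({"y": np.linspace(0, 1, 50)})
        with pytest.warns(RuntimeWarning):
            mask, table = pearson_select(X, Y)
        assert table.loc["flat", "y"] == 0.0
        assert bool(mask["flat"]) is False

    def test_simulated_heights_and_areas_pass_selection(
            self, default_noise_scans, channels):
        fvs = scans_to_features(default_noise_scans[:300], channels=channels)
        X, Y = feature_frame(fvs, channels=channels)
        mask, _ = pearson_select(X, Y, threshold=0.5)
        for name in channels:
            assert bool(mask[f"{name}_height"]) is True
            assert bool(mask[f"{name}_area"]) is True
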