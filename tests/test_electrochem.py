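"""Feature extraction from amperometry, DPV and CV."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shuttlekit import electrochem as ec
from shuttlekit.synthetic import (
    AmperometrySegment,
    gen_amperometry,
    gen_cv,
    nernstian_w_half_mV,
)


def constant_trace(value=22.0, t_end=3600.0, dt=10.0):
    t = np.arange(0.0, t_end, dt)
    return ec.AmperometryTrace(t, np.full_like(t, value))


class TestSteadyState:
    def test_constant_trace(self):
        ss = ec.steady_state_current(constant_trace(22.0), (1000.0, 2000.0))
        assert ss.mean == pytest.approx(22.0)
        assert ss.drift_slope == pytest.approx(0.0, abs=1e-12)

    def test_exponential_settling(self):
        # window starting at 10τ: within 0.01% of the plateau
        tau, plateau = 3600.0, 22.0
        trace, _ = gen_amperometry(
            seed=1,
            segments=[AmperometrySegment(0.0, plateau, tau)],
            t_end=15 * tau,
            dt=tau / 50,
        )
        ss = ec.steady_state_current(trace, (10 * tau, 15 * tau))
        assert ss.mean == pytest.approx(plateau, rel=1e-4)

    def test_window_outside_trace(self):
        with pytest.raises(ValueError, match="outside"):
            ec.steady_state_current(constant_trace(), (3000.0, 5000.0))

    def test_window_too_few_samples(self):
        with pytest.raises(ValueError, match="samples"):
            ec.steady_state_current(constant_trace(dt=10.0), (0.0, 50.0))

    def test_decreasing_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ec.AmperometryTrace(np.array([0.0, 2.0, 1.0]), np.zeros(3))


class TestRelativeChange:
    @pytest.mark.parametrize(
        "before, after, pct, fold",
        [(20.0, 2.0, -90.0, 0.1), (1.0, 33.0, 3200.0, 33.0), (5.0, 5.0, 0.0, 1.0)],
    )
    def test_examples(self, before, after, pct, fold):
        ch = ec.relative_change(before, after)
        assert ch.percent_change == pytest.approx(pct)
        assert ch.fold_change == pytest.approx(fold)

    def test_zero_baseline_undefined(self):
        with pytest.raises(ZeroDivisionError):
            ec.relative_change(0.0, 5.0)

    @given(
        before=st.floats(min_value=0.1, max_value=100.0),
        after=st.floats(min_value=0.0, max_value=100.0),
    )
    def test_fold_percent_consistency(self, before, after):
        ch = ec.relative_change(before, after)
        assert ch.fold_change == pytest.approx(1.0 + ch.percent_change / 100.0)


def gaussian_dpv(sigma_mV=28.0, e0=-0.32, height=5.0, offset=0.0, slope=0.0):
    e = np.arange(-0.8, 0.6 + 1e-12, 0.001)
    i = height * np.exp(-((e - e0) ** 2) / (2 * (sigma_mV / 1000.0) ** 2))
    i += offset + slope * e
    return ec.Voltammogram(e, i, mode="dpv")


class TestDpvPeak:
    def test_gaussian_width(self):
        # FWHM of a Gaussian = 2.3548σ → 65.9 mV for σ = 28 mV
        feat = ec.dpv_peak_features(gaussian_dpv(sigma_mV=28.0))
        assert feat.w_half_mV == pytest.approx(65.9, abs=0.5)
        assert feat.peak_potential == pytest.approx(-0.32, abs=0.002)
        assert feat.peak_height == pytest.approx(5.0, rel=0.01)

    def test_offset_invariance(self):
        base = ec.dpv_peak_features(gaussian_dpv())
        shifted = ec.dpv_peak_features(gaussian_dpv(offset=3.7))
        assert shifted.w_half_mV == pytest.approx(base.w_half_mV, abs=1e-9)
        assert shifted.peak_height == pytest.approx(base.peak_height, rel=1e-9)

    def test_sloped_baseline_subtracted(self):
        feat = ec.dpv_peak_features(gaussian_dpv(slope=1.0))
        assert feat.w_half_mV == pytest.approx(65.9, abs=1.0)

    def test_flat_trace_no_peak(self):
        e = np.arange(-0.8, 0.6, 0.001)
        v = ec.Voltammogram(e, np.zeros_like(e), mode="dpv")
        with pytest.raises(ec.NoPeakError):
            ec.dpv_peak_features(v)

    def test_noise_only_no_peak(self):
        rng = np.random.default_rng(0)
        e = np.arange(-0.8, 0.6, 0.001)
        v = ec.Voltammogram(e, rng.normal(0, 0.1, e.shape), mode="dpv")
        with pytest.raises(ec.NoPeakError):
            ec.dpv_peak_features(v)

    def test_wrong_mode(self):
        v = gaussian_dpv()
        v.mode = "cv"
        with pytest.raises(ValueError, match="DPV"):
            ec.dpv_peak_features(v)

    def test_potential_window_enforced(self):
        with pytest.raises(ValueError, match="window"):
            ec.Voltammogram(np.array([-1.0, 0.0]), np.zeros(2), mode="dpv")


class TestElectronCount:
    def test_one_electron_width(self):
        c = ec.apparent_electron_count(90.6)
        assert c.n_apparent == pytest.approx(1.0, abs=0.005)
        assert not c.multielectron

    def test_measured_66_mV_implies_multielectron(self):
        c = ec.apparent_electron_count(66.0)
        assert c.n_apparent == pytest.approx(1.37, abs=0.01)
        assert c.multielectron

    def test_two_electron_width(self):
        c = ec.apparent_electron_count(45.3)
        assert c.n_apparent == pytest.approx(2.0, abs=0.01)

    @pytest.mark.parametrize("n", [0.5, 1.0, 1.7, 2.0, 4.0])
    def test_round_trip_with_nernstian_width(self, n):
        w = nernstian_w_half_mV(n)
        assert ec.apparent_electron_count(w).n_apparent == pytest.approx(n, rel=1e-9)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            ec.apparent_electron_count(0.0)


class TestCvFeatures:
    def test_reversible_couple_midpoint(self):
        v, truth = gen_cv(seed=21, e0=-0.32)
        feat = ec.cv_features(v, noise_window=(-0.8, -0.6))
        assert feat.midpoint_potential == pytest.approx(-0.32, abs=0.005)
        assert feat.anodic_peak > feat.cathodic_peak

    def test_midpoint_is_mean_of_peaks(self):
        v, _ = gen_cv(seed=22)
        feat = ec.cv_features(v, noise_window=(-0.8, -0.6))
        assert feat.midpoint_potential == pytest.approx(
            (feat.anodic_peak + feat.cathodic_peak) / 2
        )

    def test_catalytic_onset_near_foot(self):
        v, _ = gen_cv(
            seed=23,
            peak_current=0.0,
            catalytic={"foot_V": -0.34, "amplitude": 10.0, "rise_V": 0.05},
            noise_sd=0.02,
        )
        feat = ec.cv_features(v, noise_window=(-0.8, -0.5))
        assert feat.onset_potential == pytest.approx(-0.34, abs=0.010)
        assert feat.midpoint_potential is None  # no reversible couple

    def test_flat_trace_no_wave_result(self):
        e = np.linspace(-0.8, 0.2, 1001)
        e = np.concatenate([e, e[-2::-1]])
        v = ec.Voltammogram(e, np.zeros_like(e), mode="cv")
        feat = ec.cv_features(v, noise_window=(-0.8, -0.5))
        assert not feat.has_wave
        assert feat.onset_potential is None
        assert feat.midpoint_potential is None

    def test_wrong_mode(self):
        v = gaussian_dpv()
        with pytest.raises(ValueError, match="CV"):
            ec.cv_features(v, noise_window=(-0.8, -0.6))
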