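import numpy as np
import pytest

from blinkkin import (
    FEATURE_NAMES,
    BlinkSegment,
    SubjectProfile,
    extract_features,
    fwhm,
    impulse_integral,
    make_blink_curve,
    make_segment,
    sample_profiles,
    velocity_ratio,
    work_integral,
)
from blinkkin.errors import InvalidIntervalError, MalformedBlinkError
from blinkkin.features import BlinkLandmarks
from blinkkin.synthdata import ground_truth

T240 = 1.0 / 240.0

TIME_FEATURES = ["t1P", "t2P", "t3P", "t4P", "t5P", "t6P", "t7P", "t8P",
                 "t1a", "t2a", "t3a"]


def _index(name):
    return FEATURE_NAMES.index(name)


class TestLandmarkOracle:
    def test_noiseless_blinks_match_dense_grid_oracle(self):
        """Pipeline landmarks on noiseless 240 fps windows agree with the
        dense-grid (100x oversampled) analytic-curve oracle."""
        rng = np.random.default_rng(99)
        for prof in sample_profiles(30, seed=rng):
            seg, gt = make_segment(prof, noise_sd=0.0, rng=rng, with_truth=True)
            fv = extract_features(seg)
            for name in TIME_FEATURES:
                got = fv.values[_index(name)]
                want = getattr(gt.landmarks, name)
                assert abs(got - want) <= T240, (prof, name)
            for name in ["P_t1P", "P_t3P", "P_t5P", "P_t7P",
                         "a_t1a", "a_t2a", "a_t3a", "v_t2P", "v_t6P"]:
                got = fv.values[_index(name)]
                want = gt.features[_index(name)]
                assert abs(got - want) <= 0.02, (prof, name)
            for name in ["W_0_t2P", "W_t2P_t4P", "W_t4P_t6P", "W_t6P_t8P",
                         "J_0_t2P", "J_t2P_t6P", "J_t6P_t8P"]:
                got = fv.values[_index(name)]
                want = gt.features[_index(name)]
                assert abs(got - want) <= 0.02 * abs(want), (prof, name)

    def test_symmetric_blink_closure_equals_opening(self):
        prof = SubjectProfile(closure_duration_s=0.2, opening_duration_s=0.2,
                              jitter=0.0)
        seg = make_segment(prof, noise_sd=0.0)
        fv = extract_features(seg)
        t4P = fv.values[_index("t4P")]
        t8P = fv.values[_index("t8P")]
        assert abs(t4P - (t8P - t4P)) <= T240

    def test_chronology_enforced_on_every_vector(self, small_dataset):
        ds, _ = small_dataset
        cols = [ds.feature_names.index(n) for n in
                ["t1P", "t2P", "t3P", "t4P", "t5P", "t6P", "t7P", "t8P"]]
        times = ds.X[:, cols]
        assert np.all(times[:, 0] > 0)
        assert np.all(np.diff(times, axis=1) > 0)
        t1a = ds.X[:, ds.feature_names.index("t1a")]
        t2a = ds.X[:, ds.feature_names.index("t2a")]
        t3a = ds.X[:, ds.feature_names.index("t3a")]
        assert np.all(t1a < times[:, 1])
        assert np.all((times[:, 1] < t2a) & (t2a < times[:, 3]))
        assert np.all((times[:, 3] < t3a) & (t3a < times[:, 7]))

    def test_pure_noise_segment_raises_malformed(self):
        rng = np.random.default_rng(0)
        seg = BlinkSegment(subject_id="s", trial_id="t",
                           I_win=rng.normal(size=172),
                           t_win=np.arange(172) * T240,
                           peak_offset=60, T=T240)
        with pytest.raises(MalformedBlinkError):
            extract_features(seg)


class TestIntegrals:
    def test_constant_power_closed_form(self):
        P = np.ones(50)
        # 10 samples at t = 0..9/240 inclusive
        assert work_integral(P, 0.0, 9 * T240, T240) == pytest.approx(10 / 240)

    def test_constant_acceleration_closed_form(self):
        a = np.ones(100)
        k = 17
        assert impulse_integral(a, 0.0, (k - 1) * T240, T240) == pytest.approx(
            k * T240
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_rectangle_sum_matches_trapezoid_within_one_end_term(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=200)
        i0, i1 = sorted(rng.choice(np.arange(200), size=2, replace=False))
        if i1 - i0 < 2:
            i1 = i0 + 2
        rect = work_integral(y, i0 * T240, i1 * T240, T240)
        trap = abs(np.trapezoid(y[i0 : i1 + 1], dx=T240))
        end_term = T240 * (abs(y[i0]) + abs(y[i1])) / 2
        assert abs(rect - trap) <= end_term + 1e-12

    def test_empty_interval_rejected(self):
        with pytest.raises(InvalidIntervalError):
            work_integral(np.ones(10), 0.5, 0.1, T240)
        with pytest.raises(InvalidIntervalError):
            impulse_integral(np.ones(10), 0.0041, 0.00415, T240)


class TestFwhm:
    def test_rectangular_pulse(self):
        s = np.zeros(40)
        s[10:13] = 1.0  # 3-sample-wide pulse
        assert fwhm(s, T240) == pytest.approx(3 * T240)

    def test_gaussian_pulse_analytic_width(self):
        sigma = 0.05  # >> T
        t = np.arange(400) * T240
        s = np.exp(-((t - t[200]) ** 2) / (2 * sigma**2))
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert abs(fwhm(s, T240) - expected) <= T240

    def test_no_crossing_raises(self):
        with pytest.raises(MalformedBlinkError):
            fwhm(np.linspace(0, 1, 20), T240)


class TestVelocityRatio:
    @staticmethod
    def _landmarks(t0_abs, t4P, t8P, T):
        zeros = dict(t1P=t4P / 4, t2P=t4P / 2, t3P=3 * t4P / 4,
                     t5P=t4P + (t8P - t4P) / 4, t6P=t4P + (t8P - t4P) / 2,
                     t7P=t4P + 3 * (t8P - t4P) / 4,
                     t1a=t4P / 4, t2a=3 * t4P / 4,
                     t3a=t4P + 3 * (t8P - t4P) / 4)
        return BlinkLandmarks(
            t0_abs=t0_abs, t4P=t4P, t8P=t8P, **zeros,
            idx_t0=int(round(t0_abs / T)),
            idx_t1P=0, idx_t3P=0, idx_t5P=0, idx_t7P=0,
            idx_t8P=int(round((t0_abs + t8P) / T)),
            idx_t1a=0, idx_t2a=0, idx_t3a=0,
        )

    def test_symmetric_triangle_gives_unity(self):
        T = 0.01
        up = np.linspace(0, 1, 11)
        s = np.concatenate([up, up[-2::-1]])
        lm = self._landmarks(t0_abs=0.0, t4P=0.1, t8P=0.2, T=T)
        assert velocity_ratio(s, lm, T) == pytest.approx(1.0)

    def test_two_to_one_asymmetry(self):
        """Closure in 0.1 s, opening in 0.2 s, equal amplitude: the hand
        evaluation of the ratio formula gives S = 2."""
        T = 0.01
        up = np.linspace(0, 1, 11)      # 0.1 s closure
        down = np.linspace(1, 0, 21)    # 0.2 s opening
        s = np.concatenate([up, down[1:]])
        lm = self._landmarks(t0_abs=0.0, t4P=0.1, t8P=0.3, T=T)
        assert velocity_ratio(s, lm, T) == pytest.approx(2.0)


class TestInvariances:
    @pytest.mark.parametrize("c", [0.5, 3.0, 100.0])
    def test_scale_invariance(self, noiseless_blink, c):
        seg, _ = noiseless_blink
        scaled = BlinkSegment(subject_id=seg.subject_id, trial_id=seg.trial_id,
                              I_win=c * seg.I_win, t_win=seg.t_win,
                              peak_offset=seg.peak_offset, T=seg.T)
        base = extract_features(seg).values
        got = extract_features(scaled).values
        assert np.allclose(got, base, rtol=1e-9)

    def test_window_shift_invariance(self):
        """Cropping the same blink from two differently started traces
        leaves every landmark (relative to the blink start) unchanged."""
        from blinkkin import crop_blinks, detect_peaks, make_trace

        prof = SubjectProfile(jitter=0.0)
        trace, _ = make_trace(prof, duration_s=4.0, noise_sd=0.0,
                              seed=2, n_blinks=1)
        peaks = detect_peaks(trace)
        seg_a = crop_blinks(trace, peaks).segments[0]
        # shift the window start by rebuilding the trace 7 samples later
        from blinkkin import IntensityTrace

        shifted = IntensityTrace(t=trace.t[:-7], I=trace.I[7:], T=trace.T)
        peaks_b = detect_peaks(shifted)
        seg_b = crop_blinks(shifted, peaks_b).segments[0]
        assert np.allclose(extract_features(seg_a).values,
                           extract_features(seg_b).values, rtol=1e-9)

    def test_duplicated_segment_bit_identical(self, noiseless_blink):
        seg, _ = noiseless_blink
        assert np.array_equal(extract_features(seg).values,
                              extract_features(seg).values)


def test_closure_work_exceeds_opening_work_when_closure_faster():
    """Faster closure means the muscles develop more work in the closure
    phase, per blink, whenever the generator's closure really is faster."""
    rng = np.random.default_rng(31)
    for prof in sample_profiles(10, seed=rng):
        assert prof.closure_duration_s < prof.opening_duration_s
        fv = extract_features(make_segment(prof, noise_sd=0.0))
        closure = fv.values[_index("W_0_t2P")] + fv.values[_index("W_t2P_t4P")]
        opening = fv.values[_index("W_t4P_t6P")] + fv.values[_index("W_t6P_t8P")]
        assert closure > opening
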