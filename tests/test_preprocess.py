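"""Temporal preprocessing: detrending, filtering, regression, censoring."""
import numpy as np
import pytest

from scaconn import (CensoringPolicy, MotionTrace, bandpass, censor_frames,
                     detrend_linear, framewise_displacement, global_signal,
                     percent_signal_change, preprocess, regress_nuisance)

from conftest import make_ts


def fft_amplitude(x, freq, tr):
    """Amplitude of the discrete spectrum at the bin nearest ``freq``."""
    spec = np.abs(np.fft.rfft(x)) * 2 / len(x)
    freqs = np.fft.rfftfreq(len(x), d=tr)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestDetrend:
    def test_pure_line_removed_exactly(self):
        t = np.arange(50, dtype=float)
        ts = make_ts(np.column_stack([3 + 2 * t, -1 - 0.5 * t]))
        out = detrend_linear(ts)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_constant_column_becomes_zero(self):
        ts = make_ts(np.full((40, 3), 7.0))
        np.testing.assert_allclose(detrend_linear(ts).data, 0.0, atol=1e-10)

    def test_whole_period_sinusoid_unchanged(self):
        # whole periods, even about the record midpoint: the OLS slope and
        # mean both vanish by symmetry, so the wave passes through unchanged
        t = np.arange(200, dtype=float)
        wave = np.cos(2 * np.pi * 5 * (t - t.mean()) / 200)
        out = detrend_linear(make_ts(wave[:, None]))
        np.testing.assert_allclose(out.data[:, 0], wave, atol=1e-8)

    def test_residual_has_zero_mean_and_slope(self, rng):
        ts = make_ts(rng.normal(size=(80, 4)) + np.arange(80)[:, None] * 0.3)
        out = detrend_linear(ts)
        t = np.arange(80, dtype=float)
        design = np.column_stack([np.ones(80), t])
        beta, *_ = np.linalg.lstsq(design, out.data, rcond=None)
        np.testing.assert_allclose(beta, 0.0, atol=1e-10)


class TestBandpass:
    @pytest.mark.parametrize("tr", [1.0, 2.0, 3.0])
    def test_spectral_contract(self, tr):
        """FFT amplitude oracle: pass-band ratio >= 0.9, stop-band <= 0.1."""
        t = np.arange(2000, dtype=float) * tr
        for freq, check in [(0.04, lambda r: r >= 0.9),
                            (0.005, lambda r: r <= 0.1)]:
            x = np.sin(2 * np.pi * freq * t)
            out = bandpass(make_ts(x[:, None], tr=tr))
            ratio = (fft_amplitude(out.data[:, 0], freq, tr)
                     / fft_amplitude(x, freq, tr))
            assert check(ratio), (tr, freq, ratio)

    def test_zero_phase(self):
        """The filtered pass-band sine keeps its phase (no temporal shift)."""
        tr = 2.0
        t = np.arange(2000, dtype=float) * tr
        x = np.sin(2 * np.pi * 0.04 * t)
        out = bandpass(make_ts(x[:, None], tr=tr))
        # cross-correlation peaks at zero lag
        inner = out.data[200:-200, 0]
        lags = range(-5, 6)
        scores = [np.dot(inner, x[200 + lag:-200 + lag or None]) for lag in lags]
        assert list(lags)[int(np.argmax(scores))] == 0

    def test_band_above_nyquist_rejected(self):
        ts = make_ts(np.random.default_rng(0).normal(size=(100, 2)), tr=2.0)
        with pytest.raises(ValueError, match="band/Nyquist"):
            bandpass(ts, 0.01, 0.3)

    def test_inverted_band_rejected(self):
        ts = make_ts(np.zeros((100, 1)) + np.arange(100)[:, None], tr=2.0)
        with pytest.raises(ValueError, match="band/Nyquist"):
            bandpass(ts, 0.08, 0.01)


class TestNuisanceRegression:
    def test_self_confound_zeroes_signal(self, rng):
        sig = rng.normal(size=(60, 3))
        ts = make_ts(sig)
        out = regress_nuisance(ts, sig[:, :1].repeat(1, axis=1))
        np.testing.assert_allclose(out.data[:, 0], 0.0, atol=1e-10)

    def test_orthogonal_confound_leaves_signal(self):
        t = np.arange(400, dtype=float)
        sine = np.sin(2 * np.pi * 4 * t / 400)
        cosine = np.cos(2 * np.pi * 4 * t / 400)
        out = regress_nuisance(make_ts(sine[:, None]), cosine[:, None])
        np.testing.assert_allclose(out.data[:, 0], sine, atol=1e-8)

    def test_three_point_worked_case(self):
        """Hand OLS via the normal equations: residual = (1, -2, 1)/6."""
        ts = make_ts(np.array([[1.0], [2.0], [4.0]]))
        out = regress_nuisance(ts, np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.data[:, 0],
                                   np.array([1.0, -2.0, 1.0]) / 6, atol=1e-10)

    def test_residual_orthogonal_to_confounds(self, rng):
        ts = make_ts(rng.normal(size=(100, 5)))
        confounds = rng.normal(size=(100, 3))
        out = regress_nuisance(ts, confounds)
        for c in confounds.T:
            dots = out.data.T @ (c / np.linalg.norm(c))
            np.testing.assert_allclose(dots, 0.0, atol=1e-8)

    def test_collinear_confounds_named(self, rng):
        c = rng.normal(size=(50, 1))
        confounds = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="collinear columns \\[0, 1\\]"):
            regress_nuisance(make_ts(rng.normal(size=(50, 2))), confounds)


class TestGlobalSignal:
    def test_mean_across_regions(self):
        ts = make_ts(np.array([[1.0, 3.0], [2.0, 4.0]]))
        np.testing.assert_allclose(global_signal(ts), [2.0, 3.0])

    def test_single_region_is_identity(self, rng):
        data = rng.normal(size=(30, 1))
        np.testing.assert_allclose(global_signal(make_ts(data)), data[:, 0])

    def test_identical_regions_give_the_series(self, rng):
        s = rng.normal(size=30)
        ts = make_ts(np.tile(s[:, None], (1, 7)))
        np.testing.assert_allclose(global_signal(ts), s)


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        m = MotionTrace(np.zeros((10, 6)))
        np.testing.assert_array_equal(framewise_displacement(m), 0.0)

    def test_translation_step(self):
        params = np.zeros((5, 6))
        params[2:, 0] = 0.5
        fd = framewise_displacement(MotionTrace(params))
        np.testing.assert_allclose(fd, [0, 0, 0.5, 0, 0])

    def test_rotation_arc_length(self):
        """0.01 rad on a 50 mm sphere is 0.5 mm of displacement."""
        params = np.zeros((4, 6))
        params[1:, 4] = 0.01
        fd = framewise_displacement(MotionTrace(params), head_radius=50.0)
        np.testing.assert_allclose(fd, [0, 0.5, 0, 0])

    def test_bad_head_radius(self):
        with pytest.raises(ValueError):
            framewise_displacement(MotionTrace(np.zeros((4, 6))),
                                   head_radius=-1.0)


class TestFdProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @settings(derandomize=True, max_examples=50)
    @given(hnp.arrays(float, (12, 6),
                      elements=st.floats(-5, 5, allow_nan=False)))
    def test_fd_nonnegative_and_shift_invariant(self, params):
        """FD is a difference measure: >= 0 and blind to a constant offset."""
        fd = framewise_displacement(MotionTrace(params))
        assert fd[0] == 0.0
        assert np.all(fd >= 0)
        shifted = framewise_displacement(MotionTrace(params + 1.0))
        np.testing.assert_allclose(fd, shifted, atol=1e-9)


class TestCensoring:
    def test_fd_exceedance_drops_frames(self):
        params = np.zeros((3, 6))
        params[1, 0] = 0.6   # FD: (0, 0.6, 0.2)
        params[2, 0] = 0.4
        ts = make_ts(np.full((3, 2), 100.0))
        out = censor_frames(ts, MotionTrace(params), min_frames=1)
        np.testing.assert_array_equal(out.kept_frames, [0, 2])

    def test_no_exceedance_is_identity(self, rng):
        ts = make_ts(1000 + rng.normal(size=(40, 3)))
        out = censor_frames(ts, MotionTrace(np.zeros((40, 6))))
        np.testing.assert_array_equal(out.kept_frames, np.arange(40))
        np.testing.assert_array_equal(out.data, ts.data)

    def test_all_frames_bad_is_an_error(self):
        params = np.zeros((5, 6))
        params[:, 0] = np.arange(5) * 2.0   # every FD = 2 mm
        ts = make_ts(np.full((5, 2), 100.0))
        with pytest.raises(ValueError, match="insufficient data"):
            censor_frames(ts, MotionTrace(params), min_frames=2)

    def test_signal_change_censors_artifact_frames(self):
        data = np.full((40, 4), 1000.0)
        data[20] += 50.0    # 5% one-frame artifact
        ts = make_ts(data)
        out = censor_frames(ts, MotionTrace(np.zeros((40, 6))), min_frames=5)
        # the pulse makes frames 20 and 21 exceed the 0.5% threshold
        assert 20 not in out.kept_frames and 21 not in out.kept_frames
        assert out.kept_frames.size == 38

    def test_low_change_flag_inverts_the_rule(self):
        data = np.full((40, 4), 1000.0)
        data[20] += 50.0
        ts = make_ts(data)
        policy = CensoringPolicy(censor_low_change=True)
        out = censor_frames(ts, MotionTrace(np.zeros((40, 6))), policy,
                            min_frames=1)
        kept = set(out.kept_frames.tolist())
        assert {0, 20, 21} <= kept and len(kept) == 3

    def test_censoring_commutes_with_region_subselection(self, rng):
        data = np.full((60, 6), 1000.0) + np.linspace(0, 1, 60)[:, None]
        params = np.zeros((60, 6))
        params[17, 1] = 1.5
        ts = make_ts(data)
        m = MotionTrace(params)
        direct = censor_frames(ts.select_regions([1, 4]), m, min_frames=5)
        swapped = censor_frames(ts, m, min_frames=5).select_regions([1, 4])
        np.testing.assert_array_equal(direct.kept_frames, swapped.kept_frames)
        np.testing.assert_array_equal(direct.data, swapped.data)


class TestPreprocessChain:
    def test_disabled_stages_reduce_to_detrend_bandpass(self, rng):
        ts = make_ts(1000 + rng.normal(size=(120, 5)))
        full = preprocess(ts, m=None, regress_global=False)
        stages = bandpass(detrend_linear(ts))
        np.testing.assert_allclose(full.data, stages.data, atol=1e-12)

    def test_deterministic_on_rerun(self, small_cohort):
        sid = small_cohort.records[0].id
        ts, m = small_cohort.series[sid], small_cohort.motion[sid]
        a = preprocess(ts, m)
        b = preprocess(ts, m)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.kept_frames, b.kept_frames)

    def test_single_spike_removes_exactly_one_frame(self, rng):
        t = np.linspace(0, 1, 120)[:, None]
        data = 1000 + np.sin(2 * np.pi * 3 * t) * np.ones((120, 4))
        params = np.zeros((120, 6))
        params[60:, 0] = 2.0      # step displacement: one FD exceedance
        out = preprocess(make_ts(data), MotionTrace(params))
        assert out.kept_frames.size == 119
        assert 60 not in out.kept_frames

    def test_linear_stages_are_linear(self, rng):
        x = rng.normal(size=(100, 3))
        y = rng.normal(size=(100, 3))
        confounds = rng.normal(size=(100, 2))

        def chain(d):
            ts = regress_nuisance(bandpass(detrend_linear(make_ts(d))),
                                  confounds)
            return ts.data

        lhs = chain(2.0 * x + 0.5 * y)
        rhs = 2.0 * chain(x) + 0.5 * chain(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestPercentSignalChange:
    def test_flat_signal_has_zero_change(self):
        ts = make_ts(np.full((20, 3), 500.0))
        np.testing.assert_allclose(percent_signal_change(ts), 0.0)

    def test_known_step(self):
        data = np.full((4, 1), 200.0)
        data[2] = 201.0      # 0.5% of the ~200 mean
        dvars = percent_signal_change(make_ts(data))
        assert dvars[2] == pytest.approx(100 * 1.0 / data.mean(), rel=1e-3)
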