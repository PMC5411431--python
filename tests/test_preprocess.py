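"""Filter frequency response, smoothing-kernel exactness and ICA cleanup."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import errpdecode as ed
from errpdecode.preprocess import ICACleanSpec, SGKernel, sg_smooth


def _gain_db(sos, freqs):
    _, h = sps.sosfreqz(sos, worN=freqs, fs=200)
    return 20 * np.log10(np.abs(h) + 1e-300)


class TestBandpassDesign:
    def test_passband_within_ripple(self, sos):
        grid = np.linspace(0.5, 9.0, 200)
        g = _gain_db(sos, grid)
        assert np.all(g <= 1e-6) and np.all(g >= -1.0)
        assert -1.0 <= _gain_db(sos, [5.0])[0] <= 0.0

    def test_stopbands_attenuated(self, sos):
        assert _gain_db(sos, [0.01])[0] <= -50.0
        assert _gain_db(sos, [40.0])[0] <= -50.0
        # DC sits on the equiripple stopband floor of the elliptic
        # design: attenuated by the full stopband spec (not an exact null)
        dc = np.prod([np.sum(s[:3]) / np.sum(s[3:]) for s in sos])
        assert abs(dc) <= 10 ** (-50 / 20) * (1 + 1e-6)

    def test_stable(self, sos):
        _, poles, _ = sps.sos2zpk(sos)
        assert np.all(np.abs(poles) < 1.0)

    def test_response_matches_transfer_function_oracle(self, sos):
        # independent evaluation of H(z) from the polynomial coefficients
        w = np.linspace(0.01, np.pi - 0.01, 1024)
        z = np.exp(1j * w)
        h_oracle = np.ones_like(z)
        for section in sos:
            b, a = section[:3], section[3:]
            h_oracle *= np.polyval(b[::-1], 1 / z) / np.polyval(a[::-1], 1 / z)
        _, h = sps.sosfreqz(sos, worN=w * 200 / (2 * np.pi), fs=200)
        assert np.allclose(h, h_oracle, rtol=1e-8, atol=1e-12)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            ed.BandpassSpec(passband=(10.0, 0.1))


class TestApplyBandpass:
    def test_zero_in_zero_out(self, small_rec, sos):
        zero = ed.ContinuousRecording(
            samples=np.zeros_like(small_rec.samples),
            feedback_marker=small_rec.feedback_marker.copy())
        out = ed.apply_bandpass(zero, sos)
        assert np.all(out.samples == 0.0)
        assert np.array_equal(out.feedback_marker, small_rec.feedback_marker)

    def test_linearity(self, small_rec, sos):
        a, b = 2.5, -1.5
        x = small_rec.samples
        rng = np.random.default_rng(0)
        y = rng.standard_normal(x.shape)
        mk = small_rec.feedback_marker
        f = lambda s: ed.apply_bandpass(
            ed.ContinuousRecording(samples=s, feedback_marker=mk.copy()),
            sos).samples
        assert np.allclose(f(a * x + b * y), a * f(x) + b * f(y), atol=1e-9)

    @pytest.mark.parametrize("freq, check", [
        (5.0, lambda amp: 10 ** (-1 / 20) <= amp <= 10 ** (1 / 20)),
        (50.0, lambda amp: amp <= 10 ** (-50 / 20) * 1.5),
    ])
    def test_sine_steady_state_amplitude(self, sos, freq, check):
        t = np.arange(10 * 200) / 200
        x = np.sin(2 * np.pi * freq * t)[None, :]
        mk = np.zeros(t.size, dtype=np.int8)
        rec = ed.ContinuousRecording(samples=np.vstack([x] * 57),
                                     feedback_marker=mk)
        y = ed.apply_bandpass(rec, sos).samples[0]
        amp = np.max(np.abs(y[-200:]))  # last second: steady state
        assert check(amp)


class TestSavitzkyGolay:
    def test_constant_preserved(self):
        out = sg_smooth(np.full(100, 3.25))
        assert np.allclose(out, 3.25, atol=1e-10)

    def test_cubic_reproduced_exactly_interior(self):
        t = np.arange(100, dtype=float)
        y = t ** 3
        out = sg_smooth(y)
        interior = slice(15, -15)
        assert np.allclose(out[interior], y[interior], rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(coeffs=st.lists(st.floats(-5, 5), min_size=4, max_size=4))
    def test_random_cubics_are_fixed_points(self, coeffs):
        t = np.linspace(-2, 2, 80)
        y = np.polyval(coeffs, t)
        out = sg_smooth(y)
        interior = slice(15, -15)
        assert np.allclose(out[interior], y[interior],
                           rtol=1e-9, atol=1e-9)

    def test_impulse_response_matches_normal_equations_oracle(self):
        # brute-force local cubic least squares on the 31-point window
        n, p = 15, 3
        i = np.arange(-n, n + 1, dtype=float)
        V = np.vander(i, p + 1, increasing=True)      # [1, i, i^2, i^3]
        # fitted value at window centre = e0^T (V^T V)^-1 V^T y
        oracle = (np.linalg.solve(V.T @ V, V.T).T @ np.eye(p + 1)[0])
        kernel = SGKernel()
        assert np.allclose(oracle, kernel.coefficients, atol=1e-12)
        x = np.zeros(101)
        x[50] = 1.0
        out = sg_smooth(x, kernel)
        assert np.allclose(out[50 - n:50 + n + 1], oracle, atol=1e-12)
        # kernel normalisation: coefficients sum to one
        assert kernel.coefficients.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_short_input(self):
        k = SGKernel()
        assert np.allclose(k.coefficients, k.coefficients[::-1])
        with pytest.raises(ValueError):
            sg_smooth(np.zeros(30), k)
        with pytest.raises(ValueError):
            SGKernel(half_window=1, poly_order=3)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 200))
        assert np.allclose(sg_smooth(2 * x - 3 * y),
                           2 * sg_smooth(x) - 3 * sg_smooth(y), atol=1e-10)


@pytest.fixture(scope="module")
def blink_fixture(profile, sos):
    plan = ed.make_session_plan(profile, 1, seed=5)[:16]
    rec = ed.synthesize_recording(plan, profile, seed=7)
    return ed.apply_bandpass(rec, sos)


class TestOcularCleaning:
    @staticmethod
    def _corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    def test_blinks_removed_and_reported(self, blink_fixture):
        fp1 = blink_fixture.channel_names.index("Fp1")
        before = abs(self._corr(blink_fixture.samples[fp1], blink_fixture.eog))
        clean, report = ed.remove_eog(blink_fixture, ICACleanSpec(seed=0))
        after = abs(self._corr(clean.samples[fp1], clean.eog))
        assert len(report.removed) >= 1
        assert after < before

    def test_blink_free_recording_untouched(self, profile, sos):
        quiet = ed.SubjectProfile(blink_rate=1e-9)
        plan = ed.make_session_plan(quiet, 1, seed=5)[:16]
        rec = ed.apply_bandpass(ed.synthesize_recording(plan, quiet, seed=7),
                                sos)
        clean, report = ed.remove_eog(rec, ICACleanSpec(seed=0))
        rms_change = np.sqrt(np.mean((clean.scalp - rec.scalp) ** 2, axis=1))
        rms = np.sqrt(np.mean(rec.scalp ** 2, axis=1))
        assert np.all(rms_change <= 0.05 * rms)

    def test_short_recording_rejected(self, profile):
        plan = ed.make_session_plan(profile, 1, seed=5)[:3]
        rec = ed.synthesize_recording(plan, profile, seed=7)
        with pytest.raises(ed.preprocess.ICAError):
            ed.remove_eog(rec)
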