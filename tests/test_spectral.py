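"""Band-pass filter, analytic signal, and window selection."""

import numpy as np
import pytest

import parcelsync as ps
from parcelsync.errors import BandError, DegenerateInputError, WindowError


def _tone(freq, duration=4.0, rate=250.0, n_parcels=1):
    t = np.arange(int(duration * rate)) / rate
    x = np.cos(2 * np.pi * freq * t)
    return ps.ParcelRecording(
        data=np.tile(x, (1, n_parcels, 1)),
        rate=rate,
        labels=tuple(f"p{i}" for i in range(n_parcels)),
    )


def _central(x, frac=0.8):
    n = x.shape[-1]
    k = int(n * (1 - frac) / 2)
    return x[..., k : n - k]


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = _tone(20.0)
        out = ps.bandpass_filter(rec, 13.0, 30.0)
        amp = np.abs(_central(out.data)).max()
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_stopband_tone_attenuated_20db(self):
        rec = _tone(5.0)
        out = ps.bandpass_filter(rec, 13.0, 30.0)
        amp = np.abs(_central(out.data)).max()
        assert amp < 10 ** (-20 / 20)

    def test_zero_input_gives_zero_output(self):
        rec = ps.ParcelRecording(
            data=np.zeros((2, 3, 500)), rate=250.0, labels=("a", "b", "c")
        )
        out = ps.bandpass_filter(rec, 13.0, 30.0)
        assert np.all(out.data == 0)

    def test_zero_phase_no_lag(self):
        """Cross-correlation between a band-internal tone and its filtered
        version peaks at lag zero (forward-backward filtering)."""
        rec = _tone(20.0)
        out = ps.bandpass_filter(rec, 13.0, 30.0)
        x = _central(rec.data[0, 0])
        y = _central(out.data[0, 0])
        xc = np.correlate(y, x, mode="full")
        lag = np.argmax(xc) - (len(x) - 1)
        assert lag == 0

    def test_linearity(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((1, 1, 600))
        y = rng.standard_normal((1, 1, 600))
        mk = lambda d: ps.ParcelRecording(data=d, rate=250.0, labels=("p",))
        f = lambda d: ps.bandpass_filter(mk(d), 13.0, 30.0).data
        lhs = f(2.5 * x - 1.5 * y)
        rhs = 2.5 * f(x) - 1.5 * f(y)
        assert np.allclose(lhs, rhs, rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize("band", [(0.0, 30.0), (30.0, 13.0), (13.0, 200.0)])
    def test_invalid_band_rejected(self, band):
        rec = _tone(20.0)
        with pytest.raises(BandError):
            ps.bandpass_filter(rec, *band)

    def test_too_short_for_warmup(self):
        rec = ps.ParcelRecording(
            data=np.zeros((1, 1, 20)), rate=250.0, labels=("p",)
        )
        with pytest.raises(DegenerateInputError):
            ps.bandpass_filter(rec, 13.0, 30.0)


class TestAnalyticSignal:
    def test_real_part_equals_input(self, tone_recording):
        out = ps.analytic_signal(tone_recording, (13.0, 30.0))
        assert np.allclose(out.data.real, tone_recording.data, atol=1e-12)

    def test_phase_slope_matches_tone_frequency(self, tone_recording):
        out = ps.analytic_signal(tone_recording, (13.0, 30.0))
        phase = np.unwrap(np.angle(out.data[0, 0]))
        n = phase.size
        k = int(n * 0.1)
        slope = np.polyfit(np.arange(n)[k:-k] / 250.0, phase[k:-k], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 20.0, rel=0.01)

    def test_envelope_constant_for_tone(self, tone_recording):
        out = ps.analytic_signal(tone_recording, (13.0, 30.0))
        n = out.n_samples
        k = int(n * 0.1)
        env = np.abs(out.data[0, 0, k:-k])
        assert env.max() < 1.02 and env.min() > 0.98

    def test_identical_parcels_identical_phase(self, tone_recording):
        out = ps.analytic_signal(tone_recording, (13.0, 30.0))
        assert np.array_equal(np.angle(out.data[0, 0]), np.angle(out.data[0, 1]))

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            ps.ParcelRecording(data=np.zeros((1, 1, 0)), rate=250.0, labels=("p",))


class TestSelectWindow:
    def test_standard_analysis_window_sample_count(self):
        """[0, 1.1) s at 250 Hz with t0=-0.5 keeps exactly 275 samples."""
        rec = ps.ParcelRecording(
            data=np.zeros((2, 1, 500)), rate=250.0, labels=("p",), t0=-0.5
        )
        out = ps.select_window(rec, 0.0, 1.1)
        assert out.n_samples == 275
        assert out.t0 == pytest.approx(0.0)

    def test_full_extent_is_identity(self, tone_recording):
        out = ps.select_window(tone_recording, tone_recording.t0 - 1.0, 100.0)
        assert np.array_equal(out.data, tone_recording.data)
        assert out.t0 == tone_recording.t0

    def test_single_sample_window(self):
        rec = ps.ParcelRecording(
            data=np.zeros((1, 1, 100)), rate=250.0, labels=("p",), t0=0.0
        )
        out = ps.select_window(rec, 0.0, 0.004)
        assert out.n_samples == 1

    def test_empty_intersection_rejected(self, tone_recording):
        with pytest.raises(WindowError):
            ps.select_window(tone_recording, 100.0, 101.0)

    def test_inverted_window_rejected(self, tone_recording):
        with pytest.raises(WindowError):
            ps.select_window(tone_recording, 1.0, 0.5)

    def test_works_on_analytic_type(self, tone_recording):
        an = ps.analytic_signal(tone_recording, (13.0, 30.0))
        out = ps.select_window(an, 1.0, 2.0)
        assert isinstance(out, ps.AnalyticRecording)
        assert out.n_samples == 250
        assert out.band == (13.0, 30.0)


def test_chain_commutes_with_trial_permutation():
    """Filtering + analytic signal act per trial, so permuting trials first
    or last gives the same result."""
    rng = np.random.default_rng(3)
    data = rng.standard_normal((4, 2, 500))
    rec = ps.ParcelRecording(data=data, rate=250.0, labels=("a", "b"))
    perm = np.array([2, 0, 3, 1])

    def chain(r):
        return ps.analytic_signal(ps.bandpass_filter(r, 13.0, 30.0), (13.0, 30.0)).data

    permuted_first = chain(rec.with_data(data[perm]))
    permuted_last = chain(rec)[perm]
    assert np.array_equal(permuted_first, permuted_last)
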