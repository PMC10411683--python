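"""Filtering, resampling, referencing, epoching, rejection, exclusion."""

import numpy as np
import pandas as pd
import pytest

from thetaconflict import preprocessing as pp
from thetaconflict.containers import ContinuousRecording, EpochSet
from thetaconflict.exceptions import InvalidInputError


def _recording(signal, rate=512.0, names=None, events=None):
    names = names or [f"ch{i}" for i in range(signal.shape[0])]
    return ContinuousRecording(signal, rate, names, events)


def _sinusoid(freq, rate=512.0, seconds=30.0):
    t = np.arange(int(seconds * rate)) / rate
    return np.sin(2 * np.pi * freq * t)


def _steady_amplitude(x):
    inner = x[len(x) // 4: -len(x) // 4]
    return (inner.max() - inner.min()) / 2


class TestButterworth:
    def test_highpass_removes_dc(self):
        rec = _recording(np.full((1, 512 * 120), 7.0))
        out = pp.butterworth_filter(rec, "highpass", 0.1)
        assert abs(out.signal[0, 512 * 30: -512 * 30].mean()) < 0.05

    def test_lowpass_attenuates_stopband_below_half(self):
        rec = _recording(_sinusoid(40.0)[None, :])
        out = pp.butterworth_filter(rec, "lowpass", 30.0)
        assert _steady_amplitude(out.signal[0]) < 0.5

    @pytest.mark.parametrize("kind,cutoff", [("lowpass", 30.0), ("highpass", 4.0)])
    def test_half_amplitude_at_cutoff(self, kind, cutoff):
        rec = _recording(_sinusoid(cutoff)[None, :])
        out = pp.butterworth_filter(rec, kind, cutoff)
        assert _steady_amplitude(out.signal[0]) == pytest.approx(0.5, rel=0.05)

    def test_cutoff_beyond_nyquist_rejected(self):
        rec = _recording(np.zeros((1, 1024)))
        with pytest.raises(InvalidInputError):
            pp.butterworth_filter(rec, "lowpass", 300.0)


class TestDownsample:
    def test_2048_to_512_preserves_tone(self):
        rate0 = 2048.0
        t = np.arange(int(rate0 * 8)) / rate0
        rec = _recording(np.sin(2 * np.pi * 10 * t)[None, :], rate=rate0)
        out = pp.downsample(rec, 512.0)
        assert out.rate_hz == 512.0
        spec = np.abs(np.fft.rfft(out.signal[0]))
        f = np.fft.rfftfreq(out.n_samples, 1 / 512.0)
        assert f[np.argmax(spec)] == pytest.approx(10.0, abs=0.2)
        # amplitude preserved within 1% (FFT peak of a pure tone)
        assert _steady_amplitude(out.signal[0]) == pytest.approx(1.0, rel=0.01)

    def test_identity_when_rate_matches(self):
        rec = _recording(np.random.default_rng(0).standard_normal((2, 4096)))
        out = pp.downsample(rec, 512.0)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_event_indices_rescaled(self):
        ev = pd.DataFrame({"sample": [2048], "kind": ["stimulus"],
                           "condition": ["AP-AP"], "trial_id": [0]})
        rec = _recording(np.zeros((1, 8192)), rate=2048.0, events=ev)
        out = pp.downsample(rec, 512.0)
        assert out.events["sample"].iloc[0] == 512

    def test_non_integer_factor_rejected(self):
        rec = _recording(np.zeros((1, 4096)), rate=512.0)
        with pytest.raises(InvalidInputError):
            pp.downsample(rec, 300.0)


class TestAverageReference:
    def test_scalp_mean_zero_and_differences_preserved(self, rng):
        sig = rng.standard_normal((5, 2048))
        rec = _recording(sig, names=["Fz", "FCz", "Cz", "Pz", "EOG"])
        out = pp.rereference_average(rec)
        scalp = out.signal[:4]
        np.testing.assert_allclose(scalp.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.signal[0] - out.signal[1],
                                   rec.signal[0] - rec.signal[1], atol=1e-9)
        np.testing.assert_array_equal(out.signal[4], rec.signal[4])  # EOG untouched

    def test_idempotent(self, rng):
        rec = _recording(rng.standard_normal((3, 1024)))
        once = pp.rereference_average(rec)
        twice = pp.rereference_average(once)
        np.testing.assert_allclose(twice.signal, once.signal, atol=1e-12)

    def test_single_channel_becomes_zero(self, rng):
        rec = _recording(rng.standard_normal((2, 256)), names=["a", "b"])
        out = pp.rereference_average(rec, scalp_channels=["a"])
        np.testing.assert_allclose(out.signal[0], 0.0, atol=1e-12)

    def test_empty_scalp_set_rejected(self, rng):
        rec = _recording(rng.standard_normal((2, 256)))
        with pytest.raises(InvalidInputError):
            pp.rereference_average(rec, scalp_channels=[])


class TestEpochs:
    def _with_events(self, n_events=3, rate=512.0, seconds=60.0):
        g = np.random.default_rng(1)
        sig = g.standard_normal((2, int(rate * seconds)))
        samples = (np.arange(n_events) * 10 + 5) * int(rate)
        ev = pd.DataFrame({"sample": samples,
                           "kind": ["stimulus"] * n_events,
                           "condition": (["AP-AP", "AV-AV"] * (n_events // 2 + 1))[:n_events],
                           "trial_id": np.arange(n_events)})
        return _recording(sig, rate=rate, events=ev)

    @pytest.mark.parametrize("rate,window,n_expected", [
        (512.0, (-500, 2000), 1280),
        (512.0, (-1000, 4000), 2560),
        (256.0, (-500, 2000), 640),
        (256.0, (-1000, 4000), 1280),
    ])
    def test_sample_counts(self, rate, window, n_expected):
        rec = self._with_events(rate=rate)
        eps = pp.extract_epochs(rec, "stimulus", window)
        assert eps.n_samples == n_expected
        assert eps.n_trials == 3

    def test_out_of_bounds_events_dropped_with_warning(self):
        rec = self._with_events()
        ev = pd.concat([rec.events, pd.DataFrame({
            "sample": [rec.n_samples - 10], "kind": ["stimulus"],
            "condition": ["AP-AP"], "trial_id": [99]})], ignore_index=True)
        rec = _recording(rec.signal, events=ev)
        with pytest.warns(UserWarning, match="dropped 1 events"):
            eps = pp.extract_epochs(rec, "stimulus", (-500, 2000))
        assert 99 not in eps.trial_ids

    def test_epoch_content_matches_slice(self):
        rec = self._with_events()
        eps = pp.extract_epochs(rec, "stimulus", (-500, 2000))
        s0 = int(rec.events["sample"].iloc[0]) - 256
        np.testing.assert_array_equal(eps.data[0], rec.signal[:, s0:s0 + 1280])
        assert eps.t0_offset_ms == pytest.approx(-500.0)

    def test_bad_window_rejected(self):
        rec = self._with_events()
        with pytest.raises(InvalidInputError):
            pp.extract_epochs(rec, "stimulus", (100, 100))


class TestBaseline:
    def _epochs(self, data):
        n_tr = data.shape[0]
        return EpochSet(data, -500.0, 512.0, "stimulus", ["ch0"],
                        np.array(["AP-AP"] * n_tr, dtype=object), np.arange(n_tr))

    def test_constant_epoch_zeroed(self):
        eps = self._epochs(np.full((2, 1, 1280), 7.0))
        out = pp.baseline_correct(eps, (-500, 0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_baseline_mean_zero_random(self, rng):
        eps = self._epochs(rng.standard_normal((4, 1, 1280)))
        out = pp.baseline_correct(eps, (-500, 0))
        sl = out.sample_window(-500, 0)
        np.testing.assert_allclose(out.data[:, :, sl].mean(axis=2), 0.0, atol=1e-12)

    def test_linear_ramp_closed_form(self):
        # ramp a*t: baseline window mean is a * mean(t over window)
        t = -500.0 + np.arange(1280) * 1000.0 / 512.0
        a = 0.25
        eps = self._epochs((a * t)[None, None, :])
        out = pp.baseline_correct(eps, (-500, 0))
        sl = eps.sample_window(-500, 0)
        expected = a * t - a * t[sl].mean()
        np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-9)


def brute_force_ptp_flags(data, width, threshold):
    """Exhaustive enumeration over every window start (independent oracle)."""
    n_tr, n_ch, n_s = data.shape
    flags = np.zeros(n_tr, dtype=bool)
    for tr in range(n_tr):
        for ch in range(n_ch):
            for start in range(n_s - width + 1):
                seg = data[tr, ch, start:start + width]
                if seg.max() - seg.min() > threshold:
                    flags[tr] = True
                    break
            if flags[tr]:
                break
    return flags


class TestPeakToPeak:
    def _epochs(self, data, rate=512.0):
        n_tr = data.shape[0]
        return EpochSet(data, 0.0, rate, "stimulus", ["ch0"],
                        np.array(["AP-AP"] * n_tr, dtype=object), np.arange(n_tr))

    def test_constant_epoch_never_rejected(self):
        out = pp.peak_to_peak_reject(self._epochs(np.full((3, 1, 512), 5.0)), 10.0)
        assert not out.rejected.any()

    def test_step_transient_rejected(self):
        data = np.zeros((1, 1, 512))
        data[0, 0, 256:] = 200.0
        out = pp.peak_to_peak_reject(self._epochs(data), 100.0)
        assert out.rejected.all()

    def test_dense_mode_matches_exhaustive_oracle(self, rng):
        data = 40.0 * rng.standard_normal((60, 1, 256))
        eps = self._epochs(data)
        width_ms, thr = 100.0, 150.0
        out = pp.peak_to_peak_reject(eps, thr, width_ms,
                                     window_step_ms=1000.0 / eps.rate_hz)
        width = int(round(width_ms * eps.rate_hz / 1000.0))
        np.testing.assert_array_equal(out.rejected,
                                      brute_force_ptp_flags(data, width, thr))

    def test_monotone_in_threshold(self, rng):
        eps = self._epochs(50.0 * rng.standard_normal((40, 1, 256)))
        low = pp.peak_to_peak_reject(eps, 80.0)
        high = pp.peak_to_peak_reject(eps, 160.0)
        assert set(np.flatnonzero(high.rejected)) <= set(np.flatnonzero(low.rejected))

    def test_flags_never_cleared(self, rng):
        eps = self._epochs(rng.standard_normal((5, 1, 256)))
        eps.rejected[2] = True
        out = pp.peak_to_peak_reject(eps, 1000.0)
        assert out.rejected[2]


class TestParticipantExclusion:
    def _set_with_rejections(self, n_trials, n_rejected):
        data = np.zeros((n_trials, 1, 8))
        eps = EpochSet(data, 0.0, 512.0, "stimulus", ["ch0"],
                       np.array(["AP-AP"] * n_trials, dtype=object),
                       np.arange(n_trials))
        eps.rejected[:n_rejected] = True
        return eps

    def test_just_over_quarter_excluded(self):
        eps = self._set_with_rejections(294, 74)  # 25.17%
        kept, excluded, report = pp.exclude_participants({"P00": eps})
        assert excluded == ["P00"]
        assert report["fraction"].iloc[0] == pytest.approx(74 / 294)

    def test_exactly_quarter_kept(self):
        eps = self._set_with_rejections(100, 25)
        kept, excluded, _ = pp.exclude_participants({"P00": eps})
        assert kept == ["P00"]

    def test_clean_participant_kept(self):
        eps = self._set_with_rejections(100, 0)
        kept, _, _ = pp.exclude_participants({"P00": eps})
        assert kept == ["P00"]
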