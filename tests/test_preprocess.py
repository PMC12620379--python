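"""Deterministic cleaning chain: filters meet their frequency specs, CAR is
exactly zero-sum, repair and rejection behave as constructed."""

import numpy as np
import pytest
from scipy import signal as sps

from eegfd.montage import standard_1020
from eegfd.preprocess import (
    UnrecoverableRecordingError,
    common_average_reference,
    design_bandpass,
    design_notch,
    detect_and_interpolate_bad,
    fir_bandpass,
    notch,
    preprocess_recording,
    reject_segments,
    remove_baseline,
)
from eegfd.recording import Recording
from eegfd.synth import ArtifactParams, CohortConfig, generate_subject, inject_artifacts
from eegfd._seeding import substream

RATE = 250.0


def rec_from(data, **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = standard_1020().names[: data.shape[0]]
    if data.shape[0] > 19:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return Recording(data, rate_hz=RATE, montage=names, **kw)


def sine(freq, dur=30.0, amp=1.0):
    t = np.arange(int(dur * RATE)) / RATE
    return amp * np.sin(2 * np.pi * freq * t)


class TestRemoveBaseline:
    @pytest.mark.parametrize("channel,expected", [
        ([5, 5, 5, 5], [0, 0, 0, 0]),
        ([1, 2, 3], [-1, 0, 1]),
    ])
    def test_worked_examples(self, channel, expected):
        out = remove_baseline(rec_from(channel))
        np.testing.assert_allclose(out.data[0], expected, atol=1e-12)

    def test_idempotent(self):
        rec = rec_from(np.random.default_rng(0).normal(3, 1, (2, 100)))
        once = remove_baseline(rec)
        twice = remove_baseline(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            remove_baseline(rec_from(np.empty((1, 0))))


class TestFirBandpass:
    def test_dc_removed(self):
        out = fir_bandpass(rec_from(np.full(7500, 5.0)))
        assert abs(out.data.mean()) < 0.05

    def test_passband_10hz_gain_near_unity(self):
        x = sine(10.0)
        out = fir_bandpass(rec_from(x))
        ratio = np.std(out.data[0]) / np.std(x)
        assert abs(ratio - 1) < 0.12

    def test_stopband_01hz_suppressed(self):
        x = sine(0.1, dur=60.0)
        out = fir_bandpass(rec_from(x))
        assert np.std(out.data[0]) <= 0.1 * np.std(x)

    def test_frequency_response_specs(self):
        """Designed-filter oracle: >=30 dB (forward-backward) in the
        stopbands, <=1 dB ripple across the passband."""
        taps = design_bandpass(RATE, 1.0, 70.0)
        freqs = [0.5, 80.0]
        _, h = sps.freqz(taps, worN=freqs, fs=RATE)
        db_ff = 40 * np.log10(np.maximum(np.abs(h), 1e-12))
        assert (db_ff <= -30).all()
        pass_f = np.linspace(1.0, 70.0, 200)
        _, hp = sps.freqz(taps, worN=pass_f, fs=RATE)
        assert (40 * np.log10(np.abs(hp)) >= -1.0).all()

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            fir_bandpass(rec_from(sine(10)), low_hz=1, high_hz=200)

    def test_amplitude_linearity(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 5000))
        a = 3.7
        out1 = fir_bandpass(rec_from(a * x))
        out2 = fir_bandpass(rec_from(x))
        np.testing.assert_allclose(out1.data, a * out2.data,
                                   rtol=1e-9, atol=1e-9 * np.abs(x).max())


class TestNotch:
    def test_50hz_attenuated_30db(self):
        x = sine(50.0)
        out = notch(rec_from(x))
        assert np.std(out.data[0]) <= 0.032 * np.std(x)

    def test_10hz_preserved(self):
        x = sine(10.0)
        out = notch(rec_from(x))
        assert abs(np.std(out.data[0]) / np.std(x) - 1) < 0.10

    def test_zero_in_zero_out(self):
        out = notch(rec_from(np.zeros(1000)))
        np.testing.assert_allclose(out.data, 0, atol=1e-12)

    def test_shoulder_attenuation_below_3db(self):
        b, a = design_notch(RATE, 50.0)
        _, h = sps.freqz(b, a, worN=[45.0, 55.0], fs=RATE)
        db_ff = 40 * np.log10(np.abs(h))
        assert (db_ff >= -3.0).all()


class TestCommonAverageReference:
    def test_two_channel_example(self):
        out = common_average_reference(rec_from([[1, 1], [3, 3]]))
        np.testing.assert_allclose(out.data, [[-1, -1], [1, 1]], atol=1e-12)

    def test_three_channel_example(self):
        out = common_average_reference(rec_from([[0], [3], [6]]))
        np.testing.assert_allclose(out.data, [[-3], [0], [3]], atol=1e-12)

    def test_idempotent_and_exactly_zero_sum(self):
        rng = np.random.default_rng(1)
        rec = rec_from(rng.normal(0, 50, (19, 2000)))
        out = common_average_reference(rec)
        tol = 1e-9 * np.abs(rec.data).max()
        assert np.abs(out.data.mean(axis=0)).max() < tol
        again = common_average_reference(out)
        np.testing.assert_allclose(again.data, out.data, atol=tol)
        assert out.reference == "common-average"

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(rec_from([[1, 2, 3]]))


class TestBadChannelRepair:
    def _base(self, rng):
        return rng.normal(0, 20, (19, 500))

    def test_constant_neighbors_give_mean(self):
        mont = standard_1020()
        data = np.random.default_rng(0).normal(0, 20, (19, 100))
        bad = mont.index("Cz")
        data[bad, 50] = 2000.0  # amplitude violation
        for n, v in zip(mont.neighbors_of(bad), [2.0, 4.0, 3.0, 3.0]):
            data[n] = v
        out, repaired = detect_and_interpolate_bad(
            rec_from(data), mont, flat_tol_uv=0.0, amp_tol_uv=500.0)
        assert repaired == [bad]
        np.testing.assert_allclose(out.data[bad], 3.0, atol=1e-12)

    def test_clean_input_untouched(self):
        data = np.random.default_rng(2).normal(0, 20, (19, 500))
        out, repaired = detect_and_interpolate_bad(rec_from(data))
        assert repaired == []
        np.testing.assert_array_equal(out.data, data)

    def test_flat_channel_correlates_with_neighbor_mean(self):
        mont = standard_1020()
        data = np.random.default_rng(3).normal(0, 20, (19, 1000))
        bad = mont.index("P3")
        data[bad] = 0.0
        out, repaired = detect_and_interpolate_bad(rec_from(data), mont)
        nbr_mean = data[mont.neighbors_of(bad)].mean(axis=0)
        assert np.corrcoef(out.data[bad], nbr_mean)[0, 1] > 0.5

    def test_majority_bad_unrecoverable(self):
        data = np.zeros((19, 100))
        data[:5] = np.random.default_rng(1).normal(0, 20, (5, 100))
        with pytest.raises(UnrecoverableRecordingError):
            detect_and_interpolate_bad(rec_from(data))


class TestRejectSegments:
    def test_clean_signal_kept_whole(self):
        data = np.random.default_rng(0).normal(0, 20, (19, 2500))
        out, mask = reject_segments(rec_from(data), window_s=1.0, amp_tol_uv=200)
        assert mask.all()
        np.testing.assert_array_equal(out.data, data)

    def test_transient_window_removed(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 20, (19, 15000))  # 60 s
        data[4, 5130] = 500.0
        out, mask = reject_segments(rec_from(data), window_s=1.0, amp_tol_uv=200)
        # brute-force oracle: windows containing a threshold crossing
        expect = np.array([
            (np.abs(data[:, w * 250:(w + 1) * 250]) <= 200).all()
            for w in range(60)
        ])
        np.testing.assert_array_equal(mask, expect)
        assert not mask[20] and mask.sum() == 59
        assert out.n_samples == 59 * 250

    def test_all_rejected_unrecoverable(self):
        data = np.full((19, 1000), 500.0)
        with pytest.raises(UnrecoverableRecordingError):
            reject_segments(rec_from(data), window_s=1.0, amp_tol_uv=200)


class TestFullChain:
    def test_composite_output_finite_and_car_referenced(self):
        cfg = CohortConfig(duration_s=8.0)
        s = generate_subject("s", "normal", cfg, substream(0, "pp"))
        out = preprocess_recording(s.recordings[0])
        assert np.isfinite(out.data).all()
        assert out.reference == "common-average"
        assert out.n_samples > 0

    def test_artifacts_actually_removed(self):
        """Line noise and drift injected by the generator are attenuated to
        a small fraction of their injected power."""
        cfg = CohortConfig(duration_s=8.0)
        s = generate_subject("s", "normal", cfg, substream(1, "pp"), clean=True)
        clean_rec = s.recordings[0]
        dirty = inject_artifacts(clean_rec, ArtifactParams(transient_rate_per_s=0),
                                 seed=2)
        out = preprocess_recording(dirty)
        freqs = np.fft.rfftfreq(out.n_samples, 1 / RATE)
        spec = np.abs(np.fft.rfft(out.data[0]))
        band_50 = spec[(freqs > 49) & (freqs < 51)].max()
        band_ref = spec[(freqs > 20) & (freqs < 30)].mean()
        assert band_50 < 5 * band_ref  # injected 50 Hz no longer dominates
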