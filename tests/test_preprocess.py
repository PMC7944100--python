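"""Cleaning chain: filtering, referencing, bad channels, simplified ASR."""

import numpy as np
import pytest

from resteeg.errors import (
    CalibrationError,
    InsufficientDataError,
    ModelError,
    ParameterError,
    ReferenceError_,
)
from resteeg.preprocess import (
    asr_calibrate,
    asr_clean,
    bandpass_filter,
    detect_bad_channels,
    ensure_min_duration,
    preprocess_recording,
    rereference_average,
)
from resteeg.synth import (
    ArtifactSpec,
    CohortConfig,
    draw_subject_latents,
    generate_subject_signal,
    inject_artifacts,
)

from conftest import make_recording, white_recording

FS = 128.0


def _sine(freq, duration_s=10.0, amp=1.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        data = np.tile(_sine(10.0), (2, 1))
        out = bandpass_filter(make_recording(data, channels=["O1", "O2"]))
        ratio = np.sqrt(np.mean(out.data[0] ** 2) / np.mean(data[0] ** 2))
        assert ratio >= 0.95

    def test_dc_removed(self):
        data = np.full((2, 1280), 42.0)
        out = bandpass_filter(make_recording(data, channels=["O1", "O2"]))
        assert np.abs(out.data).max() < 1e-6

    def test_slow_drift_attenuated(self):
        data = np.tile(_sine(0.1, duration_s=40.0, amp=100.0), (2, 1))
        out = bandpass_filter(make_recording(data, channels=["O1", "O2"]))
        # steady-state residual, away from filter edge transients
        mid = out.data[0, 1280:-1280]
        assert np.sqrt(2) * np.sqrt(np.mean(mid**2)) <= 10.0

    def test_edge_above_nyquist_rejected(self, rng):
        rec = white_recording(rng, n_channels=2, duration_s=2.0)
        with pytest.raises(ParameterError):
            bandpass_filter(rec, 0.5, 70.0)


class TestRereference:
    def test_column_means_zero(self, rng):
        rec = white_recording(rng, n_channels=5, duration_s=2.0)
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        rec = white_recording(rng, n_channels=5, duration_s=2.0)
        once = rereference_average(rec)
        twice = rereference_average(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_antisymmetric_pair_unchanged(self, rng):
        x = rng.standard_normal(256)
        rec = make_recording(np.stack([x, -x]), channels=["O1", "O2"])
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data, rec.data, atol=1e-12)

    def test_single_channel_rejected(self, rng):
        rec = make_recording(rng.standard_normal((1, 128)), channels=["O1"])
        with pytest.raises(ReferenceError_):
            rereference_average(rec)


class TestBadChannels:
    def test_flat_stretch_flagged(self, rng):
        rec = white_recording(rng, duration_s=20.0)
        data = rec.data.copy()
        data[3, 128 : 128 + 6 * 128] = 0.0  # 6 s of silence
        flagged = detect_bad_channels(rec.with_data(data))
        assert (rec.channels[3], "flat") in flagged

    def test_scaled_channel_flagged_peaky(self, rng):
        rec = white_recording(rng, duration_s=20.0)
        data = rec.data.copy()
        data[5] *= 50.0
        flagged = detect_bad_channels(rec.with_data(data))
        assert (rec.channels[5], "peaky") in flagged
        # brute-force robust z-score agrees with the flag
        ptp = data.max(axis=1) - data.min(axis=1)
        med = np.median(ptp)
        mad = max(np.median(np.abs(ptp - med)), 0.10 * med)
        assert (ptp[5] - med) / (1.4826 * mad) > 5.0

    def test_clean_cohort_signals_pass(self):
        config = CohortConfig(n_subjects=3, master_seed=77,
                              artifact_spec=ArtifactSpec(0, 0, 0, 0))
        false_positives = 0
        for s in range(25):
            lat = draw_subject_latents(config, s)
            rec = generate_subject_signal(config, lat, "eyes_closed", seed=s)
            false_positives += len(detect_bad_channels(rec))
        assert false_positives / (25 * 14) < 0.05


class TestAsr:
    def test_calibration_covariance_matches_stationary_input(self, rng):
        cov_errs = []
        for _ in range(5):
            rec = white_recording(rng, n_channels=6, duration_s=60.0)
            model = asr_calibrate(rec)
            full_cov = np.cov(rec.data)
            err = np.linalg.norm(model.calibration_covariance - full_cov)
            cov_errs.append(err / np.linalg.norm(full_cov))
        assert np.mean(cov_errs) < 0.10

    def test_artifact_windows_excluded_from_calibration(self, rng):
        rec = white_recording(rng, n_channels=4, duration_s=30.0)
        data = rec.data.copy()
        data[:, 1280 : 1280 + 256] += 500.0  # huge 2-s artifact
        model = asr_calibrate(rec.with_data(data))
        # calibration covariance should look like the clean background,
        # not be inflated by the artifact
        assert np.trace(model.calibration_covariance) < 2 * np.trace(np.cov(rec.data))

    def test_identity_on_artifact_free_input(self, rng):
        rec = white_recording(rng, n_channels=6, duration_s=30.0)
        model = asr_calibrate(rec)
        out, report = asr_clean(rec, model)
        assert report.windows_reconstructed == 0
        np.testing.assert_allclose(out.data, rec.data, rtol=1e-6, atol=1e-9)

    def test_infinite_cutoff_reconstructs_nothing(self, rng):
        rec = white_recording(rng, n_channels=6, duration_s=30.0)
        data = rec.data.copy()
        data[:, 640:704] += 300.0
        rec = rec.with_data(data)
        model = asr_calibrate(rec, cutoff_k=np.inf)
        _, report = asr_clean(rec, model)
        assert report.windows_reconstructed == 0

    def test_blink_variance_suppressed_neighbours_untouched(self, rng):
        config = CohortConfig(n_subjects=3, master_seed=11)
        lat = draw_subject_latents(config, 0)
        clean = generate_subject_signal(config, lat, "eyes_open", seed=0)
        blinky, events = inject_artifacts(
            clean,
            ArtifactSpec(blink_rate_per_min=1.0, muscle_rate_per_min=0.0,
                         flat_channel_prob=0.0),
            seed=4,
        )
        assert events, "expected at least one blink at this seed"
        model = asr_calibrate(blinky)
        out, report = asr_clean(blinky, model)
        assert report.windows_reconstructed > 0
        fs = clean.sample_rate
        onset = int(events[0].onset * fs)
        span = slice(onset, onset + int(0.4 * fs))
        blink_excess = np.var(blinky.data[:, span]) - np.var(clean.data[:, span])
        residual_excess = np.var(out.data[:, span]) - np.var(clean.data[:, span])
        assert residual_excess < 0.1 * blink_excess  # >= 90% of excess variance removed
        # a clean window far from the blink is essentially untouched
        far = slice(0, int(2 * fs)) if onset > int(10 * fs) else slice(-int(2 * fs), None)
        rel = np.abs(out.data[:, far] - blinky.data[:, far]).max() / np.abs(
            blinky.data[:, far]
        ).max()
        assert rel < 0.01

    def test_energy_never_increases(self, rng):
        rec = white_recording(rng, n_channels=6, duration_s=30.0)
        data = rec.data.copy()
        data[2, 640:704] += 200.0
        rec = rec.with_data(data)
        model = asr_calibrate(rec)
        out, _ = asr_clean(rec, model)
        assert np.sum(out.data**2) <= np.sum(rec.data**2) * (1 + 1e-9)

    def test_short_recording_rejected(self, rng):
        rec = white_recording(rng, n_channels=4, duration_s=10.0)
        with pytest.raises(CalibrationError):
            asr_calibrate(rec)

    def test_montage_mismatch_rejected(self, rng):
        rec = white_recording(rng, n_channels=6, duration_s=30.0)
        model = asr_calibrate(rec)
        other = white_recording(rng, n_channels=5, duration_s=30.0)
        with pytest.raises(ModelError):
            asr_clean(other, model)


class TestDurationGuard:
    @pytest.mark.parametrize("duration,ok", [(60.0, True), (59.0, False), (90.0, True)])
    def test_minimum_duration(self, rng, duration, ok):
        rec = white_recording(rng, n_channels=2, duration_s=duration)
        if ok:
            assert ensure_min_duration(rec, 60.0) is rec
        else:
            with pytest.raises(InsufficientDataError) as err:
                ensure_min_duration(rec, 60.0)
            assert rec.subject_id in str(err.value)
            assert rec.condition in str(err.value)


class TestFullChain:
    def test_deterministic(self, rng):
        rec = white_recording(rng, duration_s=60.0)
        out1, _ = preprocess_recording(rec)
        out2, _ = preprocess_recording(rec)
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_cleaning_brings_band_power_closer_to_truth(self):
        """After artifact injection, cleaned band powers are closer to the
        artifact-free ones than the contaminated ones are, for most subjects."""
        from resteeg.preprocess import PreprocessConfig
        from resteeg.spectral import band_power, welch_psd

        config = CohortConfig(n_subjects=3, master_seed=21)
        art = ArtifactSpec(blink_rate_per_min=4.0, muscle_rate_per_min=2.0)
        pre = PreprocessConfig(run_asr=True)
        improved = 0
        n_subjects = 12
        for s in range(n_subjects):
            lat = draw_subject_latents(config, s)
            clean = generate_subject_signal(config, lat, "eyes_open", seed=s)
            dirty, _ = inject_artifacts(clean, art, seed=1000 + s)
            ref = band_power(welch_psd(preprocess_recording(clean, pre)[0]))
            raw = band_power(welch_psd(
                rereference_average(bandpass_filter(dirty))
            ))
            cleaned = band_power(welch_psd(preprocess_recording(dirty, pre)[0]))
            err_raw = np.abs(raw.integrated_power - ref.integrated_power).sum()
            err_clean = np.abs(cleaned.integrated_power - ref.integrated_power).sum()
            improved += err_clean < err_raw
        assert improved >= 0.9 * n_subjects
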