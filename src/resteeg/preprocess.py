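"""Cleaning of raw resting recordings.

The chain mirrors standard wearable-EEG practice: remove bad channels
(flat or abnormally peaky), zero-phase band-pass 0.5-46 Hz, re-reference
to the common average, then artifact subspace reconstruction (ASR), and
finally a minimum-retained-duration guard (default 60 s).

The ASR here is the simplified "clip-and-backproject" variant: a
channel-space PCA basis is learned from the cleanest calibration
windows; in each 0.5-s sliding analysis window any principal component
whose variance exceeds ``mean + cutoff_k * SD`` of its calibration
window variances (default cutoff 20 SD) is rescaled down to the
calibration-mean level before back-projection.  Windows are Hann-blended at 50%
overlap so reconstruction introduces no boundary discontinuities.  This
keeps the variance-classification behaviour of full ASR without its
calibration mixing-matrix machinery; see the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hann

from .errors import (
    CalibrationError,
    InsufficientDataError,
    ModelError,
    ParameterError,
    ReferenceError_,
)
from .recording import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable thresholds of the cleaning chain (all units physical)."""

    bandpass_low_hz: float = 0.5
    bandpass_high_hz: float = 46.0
    flat_window_s: float = 5.0
    flat_ptp_uv: float = 0.5
    peak_robust_z: float = 5.0
    asr_window_s: float = 0.5
    asr_cutoff_k: float = 20.0
    asr_calib_fraction: float = 0.5
    min_duration_s: float = 60.0
    run_asr: bool = True


@dataclass
class CleaningReport:
    """What the cleaning chain did to one recording."""

    subject_id: str
    condition: str
    channels_removed: list[tuple[str, str]] = field(default_factory=list)
    windows_reconstructed: int = 0
    seconds_reconstructed: float = 0.0
    retained_duration_s: float = 0.0


def bandpass_filter(
    rec: Recording, low: float = 0.5, high: float = 46.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    nyquist = rec.sample_rate / 2.0
    if not 0 < low < high:
        raise ParameterError(f"invalid band ({low}, {high})")
    if high >= nyquist:
        raise ParameterError(
            f"band edge {high} Hz must be below Nyquist ({nyquist} Hz)"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=rec.sample_rate, output="sos")
    return rec.with_data(sosfiltfilt(sos, rec.data, axis=-1))


def rereference_average(rec: Recording) -> Recording:
    """Common-average reference: subtract the across-channel mean per sample."""
    if rec.data.shape[0] < 2:
        raise ReferenceError_("average reference needs at least 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def detect_bad_channels(
    rec: Recording,
    flat_window_s: float = 5.0,
    flat_ptp_uv: float = 0.5,
    peak_robust_z: float = 5.0,
) -> list[tuple[str, str]]:
    """Flag channels that are flat or have abnormal peak-to-peak amplitude.

    *flat*: some contiguous ``flat_window_s`` stretch has peak-to-peak
    below ``flat_ptp_uv``.  *peaky*: the channel's whole-recording
    peak-to-peak has a robust z-score (median/MAD across channels) above
    ``peak_robust_z``.
    """
    flagged: list[tuple[str, str]] = []
    n = rec.n_samples
    w = int(round(flat_window_s * rec.sample_rate))
    if 0 < w <= n:
        # O(n) rolling peak-to-peak; restrict to windows fully inside.
        rolling_max = maximum_filter1d(rec.data, size=w, axis=-1, mode="nearest")
        rolling_min = minimum_filter1d(rec.data, size=w, axis=-1, mode="nearest")
        ptp = rolling_max - rolling_min
        lo = w // 2
        hi = n - (w - w // 2) + 1
        flat = (ptp[:, lo:hi] < flat_ptp_uv).any(axis=1)
    else:
        flat = np.zeros(rec.data.shape[0], bool)

    total_ptp = rec.data.max(axis=1) - rec.data.min(axis=1)
    median = np.median(total_ptp)
    # MAD floored at 10% of the median: on montages with near-homogeneous
    # amplitudes a raw MAD collapses and would flag ordinary regional
    # differences (e.g. elevated occipital alpha) as abnormal peaks.
    mad = max(np.median(np.abs(total_ptp - median)), 0.10 * median)
    if mad > 0:
        robust_z = (total_ptp - median) / (1.4826 * mad)
    else:
        robust_z = np.zeros_like(total_ptp)

    for i, name in enumerate(rec.channels):
        if flat[i]:
            flagged.append((name, "flat"))
        elif abs(robust_z[i]) > peak_robust_z:
            flagged.append((name, "peaky"))
    return flagged


# ---------------------------------------------------------------------------
# Artifact subspace reconstruction (simplified)


@dataclass
class AsrModel:
    """Calibration state of the simplified ASR.

    ``basis`` columns are the principal axes (eigenvectors of the
    calibration covariance); ``mean_var``/``sd_var`` are per-component
    statistics of 0.5-s calibration-window variances.
    """

    channels: tuple[str, ...]
    calibration_covariance: np.ndarray = field(repr=False)
    basis: np.ndarray = field(repr=False)
    mean_var: np.ndarray = field(repr=False)
    sd_var: np.ndarray = field(repr=False)
    cutoff_k: float = 20.0
    window_s: float = 0.5

    @property
    def thresholds(self) -> np.ndarray:
        return self.mean_var + self.cutoff_k * self.sd_var


def asr_calibrate(
    rec: Recording,
    window_s: float = 0.5,
    calib_fraction: float = 0.5,
    cutoff_k: float = 20.0,
) -> AsrModel:
    """Learn the ASR basis from the cleanest part of the recording.

    Non-overlapping ``window_s`` windows are ranked by total RMS; the
    lowest-RMS windows totalling ``calib_fraction`` of the data form the
    calibration set, whose covariance supplies the component basis and
    whose per-window variances supply the rescaling thresholds.
    """
    if rec.duration_s < 15.0:
        raise CalibrationError(
            f"ASR calibration needs >= 15 s, got {rec.duration_s:.1f} s "
            f"(subject {rec.subject_id}, {rec.condition})"
        )
    w = int(round(window_s * rec.sample_rate))
    n_windows = rec.n_samples // w
    blocks = rec.data[:, : n_windows * w].reshape(rec.data.shape[0], n_windows, w)
    rms = np.sqrt(np.mean(blocks**2, axis=(0, 2)))
    n_keep = max(2, int(np.ceil(calib_fraction * n_windows)))
    keep = np.sort(np.argsort(rms, kind="stable")[:n_keep])
    calib = blocks[:, keep, :].reshape(rec.data.shape[0], -1)
    cov = np.cov(calib)
    _, basis = np.linalg.eigh(cov)  # ascending; orthonormal columns
    comp_windows = np.einsum("kc,cws->wks", basis.T, blocks[:, keep, :])
    window_vars = comp_windows.var(axis=-1)  # (n_keep, C)
    return AsrModel(
        channels=rec.channels,
        calibration_covariance=cov,
        basis=basis,
        mean_var=window_vars.mean(axis=0),
        sd_var=window_vars.std(axis=0),
        cutoff_k=cutoff_k,
        window_s=window_s,
    )


def asr_clean(rec: Recording, model: AsrModel) -> tuple[Recording, CleaningReport]:
    """Rescale high-variance components window-by-window and back-project.

    Sliding 50%-overlapping windows are projected onto the calibration
    basis; components exceeding their calibration threshold
    (``mean + cutoff_k * SD``) are scaled down to the calibration-mean
    variance; windows are Hann-blended back together.
    """
    if model.channels != rec.channels:
        raise ModelError(
            "ASR model channels do not match recording "
            f"({model.channels} vs {rec.channels})"
        )
    w = int(round(model.window_s * rec.sample_rate))
    hop = max(1, w // 2)
    n = rec.n_samples
    starts = list(range(0, n - w + 1, hop))
    if starts[-1] != n - w:
        starts.append(n - w)  # cover the tail
    starts_arr = np.asarray(starts)
    wins = np.stack([rec.data[:, s : s + w] for s in starts_arr])  # (W, C, w)
    comp = np.einsum("kc,wcs->wks", model.basis.T, wins)
    variances = comp.var(axis=-1)  # (W, K)
    thresholds = model.thresholds
    # Components above threshold are reconstructed down to the calibration
    # level (mean calibration window variance), as ASR rebuilds the
    # offending subspace from normal data; the threshold only decides
    # which components count as artifact.
    target = np.maximum(model.mean_var, 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.sqrt(target / variances)
    gain = np.where(variances > thresholds, gain, 1.0)
    reconstructed = np.any(gain < 1.0, axis=1)
    comp *= gain[:, :, None]
    back = np.einsum("ck,wks->wcs", model.basis, comp)

    taper = hann(w, sym=True) + 1e-8  # strictly positive so edges normalize
    out = np.zeros_like(rec.data)
    weight = np.zeros(n)
    for idx, s in enumerate(starts_arr):
        out[:, s : s + w] += back[idx] * taper
        weight[s : s + w] += taper
    out /= weight
    report = CleaningReport(
        subject_id=rec.subject_id,
        condition=rec.condition,
        windows_reconstructed=int(reconstructed.sum()),
        seconds_reconstructed=float(reconstructed.sum() * hop / rec.sample_rate),
        retained_duration_s=rec.duration_s,
    )
    return rec.with_data(out), report


def ensure_min_duration(rec: Recording, min_s: float = 60.0) -> Recording:
    """Guard: at least ``min_s`` seconds must remain after cleaning."""
    if rec.duration_s < min_s:
        raise InsufficientDataError(
            f"subject {rec.subject_id} ({rec.condition}): only "
            f"{rec.duration_s:.1f} s retained, {min_s:.0f} s required"
        )
    return rec


def preprocess_recording(
    rec: Recording, config: PreprocessConfig | None = None
) -> tuple[Recording, CleaningReport]:
    """Full chain: bad channels -> band-pass -> average reference -> ASR -> guard.

    Bad channels are removed before re-referencing so they cannot
    contaminate the common average.
    """
    config = config or PreprocessConfig()
    bad = detect_bad_channels(
        rec, config.flat_window_s, config.flat_ptp_uv, config.peak_robust_z
    )
    if bad:
        logger.info(
            "subject %s (%s): removing channels %s",
            rec.subject_id, rec.condition, bad,
        )
        rec = rec.drop_channels([name for name, _ in bad])
    rec = bandpass_filter(rec, config.bandpass_low_hz, config.bandpass_high_hz)
    rec = rereference_average(rec)
    if config.run_asr:
        model = asr_calibrate(
            rec, config.asr_window_s, config.asr_calib_fraction, config.asr_cutoff_k
        )
        rec, report = asr_clean(rec, model)
    else:
        report = CleaningReport(
            subject_id=rec.subject_id,
            condition=rec.condition,
            retained_duration_s=rec.duration_s,
        )
    report.channels_removed = bad
    report.retained_duration_s = rec.duration_s
    rec = ensure_min_duration(rec, config.min_duration_s)
    return rec, report
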