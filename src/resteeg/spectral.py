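"""Spectral estimation: Welch PSD, band power, magnitude-squared coherence.

All estimates share one segmentation — 4-s epochs with 2-s overlap at
128 Hz, i.e. 512-sample Hann-tapered segments giving a 0.25 Hz grid —
so the coherence

.. math::

    \\mathrm{Coh}_{xy}(f) = \\frac{|G_{xy}(f)|^2}{G_{xx}(f)\\,G_{yy}(f)}

is internally consistent: the auto-spectra :math:`G_{xx}, G_{yy}` and
cross-spectrum :math:`G_{xy}` are averaged over exactly the same
tapered segments, which (by Cauchy-Schwarz) keeps the estimate in
``[0, 1]`` without clipping.

Band powers are bin sums over half-open bands ``[low, high)`` on the
0.25 Hz grid; "absolute" power is reported both as mean density
(uV^2/Hz) and integrated power (uV^2), "relative" power as the fraction
of total integrated power over the 1-46 Hz analysis span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .errors import EstimationError, InsufficientDataError, ParameterError
from .recording import BandScheme, Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectralConfig:
    """Welch segmentation parameters.

    Defaults give 4-s epochs with 2-s overlap: 0.25 Hz resolution at
    any sample rate (the grid spacing is ``1/epoch_s``).
    """

    epoch_s: float = 4.0
    overlap_s: float = 2.0
    taper: str = "hann"
    span: tuple[float, float] = (1.0, 46.0)

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.epoch_s:
            raise ParameterError("overlap_s must be in [0, epoch_s)")

    @property
    def resolution_hz(self) -> float:
        return 1.0 / self.epoch_s

    def nperseg(self, sample_rate: float) -> int:
        return int(round(self.epoch_s * sample_rate))

    def hop(self, sample_rate: float) -> int:
        return self.nperseg(sample_rate) - int(round(self.overlap_s * sample_rate))

    def n_segments(self, n_samples: int, sample_rate: float) -> int:
        nperseg = self.nperseg(sample_rate)
        if n_samples < nperseg:
            return 0
        return 1 + (n_samples - nperseg) // self.hop(sample_rate)


@dataclass
class PsdResult:
    """One-sided Welch power spectral density for every channel."""

    frequencies: np.ndarray
    density: np.ndarray  # (n_channels, n_freqs), uV^2/Hz
    n_segments: int
    channels: tuple[str, ...]

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def _segment_ffts(
    data: np.ndarray, sample_rate: float, cfg: SpectralConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tapered, mean-detrended segment rFFTs.

    Returns ``(freqs, Z, scale)`` where ``Z`` is (channels, freqs,
    segments) and ``scale`` is the one-sided density scaling per bin, so
    that ``scale * mean_k |Z|^2`` is the Welch density estimate.
    """
    nperseg = cfg.nperseg(sample_rate)
    hop = cfg.hop(sample_rate)
    if data.shape[-1] < nperseg:
        raise InsufficientDataError(
            f"recording of {data.shape[-1]} samples is shorter than one "
            f"{cfg.epoch_s}-s epoch ({nperseg} samples)"
        )
    window = get_window(cfg.taper, nperseg)
    segs = sliding_window_view(data, nperseg, axis=-1)[..., ::hop, :]
    segs = segs - segs.mean(axis=-1, keepdims=True)  # constant detrend
    Z = np.fft.rfft(segs * window, axis=-1)  # (ch, seg, freq)
    Z = np.moveaxis(Z, -2, -1)  # (ch, freq, seg)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / sample_rate)
    # One-sided density scaling with taper power compensation; DC and
    # Nyquist bins are not doubled.
    scale = np.full(freqs.shape, 2.0 / (sample_rate * np.sum(window**2)))
    scale[0] /= 2.0
    if nperseg % 2 == 0:
        scale[-1] /= 2.0
    return freqs, Z, scale


def welch_psd(rec: Recording, cfg: SpectralConfig | None = None) -> PsdResult:
    """Welch PSD over the configured segmentation (uV^2/Hz, one-sided)."""
    cfg = cfg or SpectralConfig()
    freqs, Z, scale = _segment_ffts(rec.data, rec.sample_rate, cfg)
    density = scale * np.mean(np.abs(Z) ** 2, axis=-1)
    return PsdResult(
        frequencies=freqs,
        density=density,
        n_segments=Z.shape[-1],
        channels=rec.channels,
    )


def band_bins(frequencies: np.ndarray, low: float, high: float) -> np.ndarray:
    """Boolean mask of bins whose centers fall in the half-open band [low, high)."""
    return (frequencies >= low) & (frequencies < high)


def band_power(psd: PsdResult, scheme: BandScheme | None = None) -> pd.DataFrame:
    """Absolute band power per channel per band.

    Returns a long-format frame with columns ``channel, band,
    absolute_density, integrated_power``; ``integrated_power`` is the
    bin sum times the grid resolution and ``absolute_density`` the mean
    density over the band (integrated power / bandwidth).
    """
    scheme = scheme or BandScheme()
    fmax = psd.frequencies[-1]
    rows = []
    for band in scheme.names:
        low, high = scheme.edges(band)
        if low < 0 or high > fmax + psd.df:
            raise ParameterError(
                f"band {band} ({low}, {high}) outside PSD span (0, {fmax})"
            )
        mask = band_bins(psd.frequencies, low, high)
        integrated = psd.density[:, mask].sum(axis=1) * psd.df
        rows.append(
            pd.DataFrame(
                {
                    "channel": psd.channels,
                    "band": band,
                    "absolute_density": integrated / (high - low),
                    "integrated_power": integrated,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def relative_band_power(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``relative_power``: each band's share of total integrated power.

    The total runs over all bands in the table per (subject, condition,
    channel) group — with the default scheme that is the 1-46 Hz span.
    """
    table = table.copy()
    keys = [k for k in ("subject", "condition", "channel") if k in table.columns]
    totals = table.groupby(keys, sort=False)["integrated_power"].transform("sum")
    if np.any(totals <= 0):
        raise EstimationError("relative power undefined: zero total power")
    table["relative_power"] = table["integrated_power"] / totals
    return table


def band_power_table(
    recordings: list[Recording],
    scheme: BandScheme | None = None,
    cfg: SpectralConfig | None = None,
    relative: bool = True,
) -> pd.DataFrame:
    """Subject x condition x channel x band power table for a cohort."""
    frames = []
    for rec in recordings:
        frame = band_power(welch_psd(rec, cfg), scheme)
        frame.insert(0, "condition", rec.condition)
        frame.insert(0, "subject", rec.subject_id)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return relative_band_power(table) if relative else table


# ---------------------------------------------------------------------------
# Coherence


def ms_coherence(
    rec: Recording, pair: tuple[str, str], cfg: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence spectrum for one channel pair.

    Returns ``(frequencies, coherence)`` on the Welch grid.  Requires at
    least two segments (single-segment coherence is identically 1 and
    carries no information).  Bins with a zero auto-spectrum are set to
    0 with a warning.
    """
    cfg = cfg or SpectralConfig()
    i, j = (rec.montage.index(pair[0]), rec.montage.index(pair[1]))
    freqs, Z, _ = _segment_ffts(rec.data[[i, j]], rec.sample_rate, cfg)
    if Z.shape[-1] < 2:
        raise EstimationError(
            "coherence needs at least 2 Welch segments; recording too short"
        )
    Gxx = np.mean(np.abs(Z[0]) ** 2, axis=-1)
    Gyy = np.mean(np.abs(Z[1]) ** 2, axis=-1)
    Gxy = np.mean(Z[0] * np.conj(Z[1]), axis=-1)
    denom = Gxx * Gyy
    coh = np.zeros_like(Gxx)
    ok = denom > 0
    if not np.all(ok):
        logger.warning(
            "zero auto-spectrum at %d bins for pair %s; coherence set to 0",
            int(np.sum(~ok)), pair,
        )
    coh[ok] = np.abs(Gxy[ok]) ** 2 / denom[ok]
    return freqs, coh


@dataclass
class CoherenceNetwork:
    """Per-band symmetric channel x channel coherence matrices for one recording."""

    subject_id: str
    condition: str
    channels: tuple[str, ...]
    matrices: dict[str, np.ndarray] = field(repr=False)

    def matrix(self, band: str) -> np.ndarray:
        return self.matrices[band]

    def edge(self, band: str, a: str, b: str) -> float:
        i, j = self.channels.index(a), self.channels.index(b)
        return float(self.matrices[band][i, j])

    def edge_list(self) -> pd.DataFrame:
        """Long-format frame of the unordered off-diagonal pairs per band."""
        rows = []
        n = len(self.channels)
        iu, ju = np.triu_indices(n, k=1)
        for band, mat in self.matrices.items():
            rows.append(
                pd.DataFrame(
                    {
                        "subject": self.subject_id,
                        "condition": self.condition,
                        "band": band,
                        "ch_i": np.asarray(self.channels)[iu],
                        "ch_j": np.asarray(self.channels)[ju],
                        "coherence": mat[iu, ju],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def band_coherence_network(
    rec: Recording,
    scheme: BandScheme | None = None,
    cfg: SpectralConfig | None = None,
) -> CoherenceNetwork:
    """Band-averaged magnitude-squared coherence between all channel pairs.

    Auto- and cross-spectra are averaged over the identical Welch
    segmentation, then the coherence spectrum is averaged over each
    band's bins.  The diagonal is exactly 1 and the matrix exactly
    symmetric.
    """
    scheme = scheme or BandScheme()
    cfg = cfg or SpectralConfig()
    freqs, Z, _ = _segment_ffts(rec.data, rec.sample_rate, cfg)
    if Z.shape[-1] < 2:
        raise EstimationError(
            "coherence needs at least 2 Welch segments; recording too short"
        )
    K = Z.shape[-1]
    G = np.einsum("cfs,dfs->cdf", Z, np.conj(Z)) / K  # cross-spectral matrix
    auto = np.real(np.einsum("ccf->cf", G))
    denom = auto[:, None, :] * auto[None, :, :]
    coh = np.zeros_like(denom)
    ok = denom > 0
    np.divide(np.abs(G) ** 2, denom, out=coh, where=ok)
    matrices = {}
    for band in scheme.names:
        low, high = scheme.edges(band)
        mask = band_bins(freqs, low, high)
        if not mask.any():
            raise ParameterError(f"band {band} has no bins on the Welch grid")
        mat = coh[:, :, mask].mean(axis=-1)
        np.fill_diagonal(mat, 1.0)
        matrices[band] = mat
    return CoherenceNetwork(
        subject_id=rec.subject_id,
        condition=rec.condition,
        channels=rec.channels,
        matrices=matrices,
    )
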