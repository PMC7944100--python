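"""Synthetic resting-EEG cohorts with known ground truth.

The study this pipeline targets recorded 43 older adults with a
14-channel wearable headset (128 Hz): 60 s eyes-open rest, 60 s
eyes-closed rest, then a delayed-match-to-sample task.  Its raw data are
not deposited, so this module generates cohorts whose *every* planted
property — band densities, the eyes-closed occipital alpha elevation,
coherent channel pairs, and Pearson correlations between resting
features and behavioral covariates — is known exactly, making each
downstream stage testable.

Signal model
------------
Each recording is a sum over the five canonical bands of independent
band-limited Gaussian processes: complex Gaussian rFFT coefficients,
flat at the target one-sided density inside the band and zero outside.
Per subject, per band, per channel the density is multiplied by a
unit-mean lognormal factor ``exp(sigma * z - sigma^2/2)`` with
independent standard-normal latents ``z``; eyes-closed multiplies the
occipital (O1, O2) alpha density by ``ec_alpha_boost``.

Planted coherence at an edge (i, j, band) shares one band-limited
source between the two channels with mixing weight ``w`` while keeping
each channel's density fixed; the resulting magnitude-squared coherence
is ``w^4``, so ``w = coherence ** 0.25``.

Behavioral covariates (mean RT in ms, accuracy in %) are planted so
that their Pearson correlation with the *true physical feature value*
(the subject's band density, or edge coherence) equals the requested
rho exactly in expectation; they are then affinely mapped to the
published behavioral scale (RT 673 +/- 51 ms; accuracy 91.56 +/- 5.02 %,
clipped to [0, 100]).

Because the analysis pipeline measures densities *after* average
re-referencing, target densities are specified on that scale and the
generator inverts the reference operator (a 14 x 14 linear solve per
band) to find generation densities; the inversion is exact for
independent channels and approximate when coherence edges are planted.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .errors import ConfigurationError, ParameterError
from .montage import CHANNELS_14, FRONTAL, OCCIPITAL, builtin_montage
from .recording import Annotation, BandScheme, Recording

#: Published behavioral scale used for covariate mapping.
RT_MEAN_MS = 673.0
RT_SD_MS = 51.0
ACCURACY_MEAN_PCT = 91.56
ACCURACY_SD_PCT = 5.02

#: Eyes-closed / eyes-open occipital alpha densities (uV^2/Hz) the
#: default configuration targets.
EC_OCCIPITAL_ALPHA = 38.80
EO_OCCIPITAL_ALPHA = 35.65

_N_CH = len(CHANNELS_14)


def default_band_density() -> dict[str, np.ndarray]:
    """Baseline one-sided densities (uV^2/Hz) per band and channel.

    Occipital alpha is elevated to the published eyes-open level; the
    eyes-closed elevation on top of it comes from ``ec_alpha_boost``.
    Non-occipital levels are generic resting-EEG magnitudes.
    """
    dens = {
        "delta": np.full(_N_CH, 12.0),
        "theta": np.full(_N_CH, 8.0),
        "alpha": np.full(_N_CH, 10.0),
        "beta": np.full(_N_CH, 4.0),
        "gamma": np.full(_N_CH, 2.0),
    }
    for ch in OCCIPITAL:
        dens["alpha"][CHANNELS_14.index(ch)] = EO_OCCIPITAL_ALPHA
    return dens


@dataclass(frozen=True)
class PlantedEffect:
    """A Pearson correlation planted between a resting feature and behavior.

    ``feature`` is ``(channel, band)`` for a band-power effect or
    ``(channel_i, channel_j, band)`` for a coherence-edge effect;
    ``behavioral_measure`` is ``mean_rt_ms`` or ``accuracy_pct``.
    """

    feature: tuple
    behavioral_measure: str
    rho: float

    def __post_init__(self) -> None:
        if self.behavioral_measure not in ("mean_rt_ms", "accuracy_pct"):
            raise ConfigurationError(
                f"unknown behavioral measure {self.behavioral_measure!r}"
            )
        if not abs(self.rho) < 1:
            raise ConfigurationError("|rho| must be < 1")
        if len(self.feature) not in (2, 3):
            raise ConfigurationError(
                "feature must be (channel, band) or (channel_i, channel_j, band)"
            )
        for ch in self.channels:
            if ch not in CHANNELS_14:
                raise ConfigurationError(f"unknown channel {ch!r} in planted effect")

    @property
    def kind(self) -> str:
        return "power" if len(self.feature) == 2 else "coherence"

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.feature[:-1])

    @property
    def band(self) -> str:
        return self.feature[-1]


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates and morphology of injected artifacts."""

    blink_rate_per_min: float = 2.0
    #: Blinking is almost entirely suppressed with the eyes closed;
    #: recordings in that condition use this rate instead.
    blink_rate_eyes_closed_per_min: float = 0.0
    muscle_rate_per_min: float = 1.0
    flat_channel_prob: float = 0.0
    blink_amp_uv: float = 300.0
    blink_duration_s: float = 0.4
    blink_spread: float = 0.6  # exponential decay length in head units
    muscle_rms_uv: float = 40.0
    muscle_duration_s: float = 0.5
    muscle_band_hz: tuple[float, float] = (20.0, 46.0)
    flat_duration_s: float = 6.0

    @property
    def silent(self) -> bool:
        return (
            self.blink_rate_per_min == 0
            and self.blink_rate_eyes_closed_per_min == 0
            and self.muscle_rate_per_min == 0
            and self.flat_channel_prob == 0
        )

    def blink_rate_for(self, condition: str) -> float:
        if condition == "eyes_closed":
            return self.blink_rate_eyes_closed_per_min
        return self.blink_rate_per_min


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the published study: 43 subjects, 60 s per resting
    condition at 128 Hz, occipital alpha at the reported eyes-open level
    with the eyes-closed boost reproducing the reported eyes-closed
    level.  ``subject_sd_log`` is the SD of the per-subject, per-band,
    per-channel log-amplitude latents.
    """

    n_subjects: int = 43
    duration_s: float = 60.0
    sample_rate: float = 128.0
    band_density: Mapping[str, object] | None = None
    ec_alpha_boost: float = EC_OCCIPITAL_ALPHA / EO_OCCIPITAL_ALPHA
    subject_sd_log: float = 0.4
    planted_effects: tuple[PlantedEffect, ...] = ()
    fixed_coherence_edges: tuple[tuple[str, str, str, float], ...] = ()
    coherence_base: float = 0.5
    coherence_sd: float = 0.12
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    conditions: tuple[str, ...] = ("eyes_open", "eyes_closed")
    reference_compensation: bool = True
    welch_compensation: bool = True
    welch_epoch_s: float = 4.0
    master_seed: int = 0
    band_scheme: BandScheme = field(default_factory=BandScheme)

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3")
        if self.ec_alpha_boost < 1:
            raise ConfigurationError("ec_alpha_boost must be >= 1")
        if self.subject_sd_log < 0:
            raise ConfigurationError("subject_sd_log must be >= 0")
        for cond in self.conditions:
            if cond not in ("eyes_open", "eyes_closed"):
                raise ConfigurationError(f"invalid resting condition {cond!r}")
        densities = self.densities()
        for band, vec in densities.items():
            if np.any(vec <= 0):
                raise ConfigurationError(f"band {band} has non-positive density")
        for effect in self.planted_effects:
            if effect.band not in self.band_scheme.names:
                raise ConfigurationError(f"planted effect in unknown band {effect.band}")

    def densities(self) -> dict[str, np.ndarray]:
        """Per-band length-14 density vectors (broadcast scalars)."""
        base = default_band_density()
        if self.band_density is not None:
            for band, value in self.band_density.items():
                if band not in base:
                    raise ConfigurationError(f"unknown band {band!r}")
                base[band] = np.broadcast_to(
                    np.asarray(value, dtype=float), (_N_CH,)
                ).copy()
        return base

    def coherence_effects(self) -> list[PlantedEffect]:
        return [e for e in self.planted_effects if e.kind == "coherence"]

    def power_effects(self) -> list[PlantedEffect]:
        return [e for e in self.planted_effects if e.kind == "power"]


@dataclass
class SubjectLatents:
    """Per-subject standard-normal latents behind amplitudes and coherence."""

    z_power: np.ndarray  # (n_bands, n_channels)
    z_edges: dict[tuple[str, str, str], float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery tests."""

    config: CohortConfig
    subjects: list[str]
    latents: list[SubjectLatents]
    multipliers: np.ndarray  # (n_subjects, n_bands, n_channels), unit mean
    edge_coherence: dict[tuple[str, str, str], np.ndarray]
    behavior: pd.DataFrame  # subject, mean_rt_ms, accuracy_pct

    def true_density(self, subject_idx: int, channel: str, band: str) -> float:
        """True eyes-open-scale density for one subject/feature."""
        cfg = self.config
        b = list(cfg.band_scheme.names).index(band)
        c = CHANNELS_14.index(channel)
        return float(
            cfg.densities()[band][c] * self.multipliers[subject_idx, b, c]
        )


# ---------------------------------------------------------------------------
# Measurement-operator compensation
#
# Targets are defined as what the analysis measures on clean data:
# (a) densities after average re-referencing, and (b) Welch band
# averages under the 4-s Hann segmentation.  Both operators are linear
# on band densities and are inverted at generation time: the Hann
# kernel smears band-edge bins into neighbouring bands (a 5 x 5
# band-coupling matrix per channel), and the common-average reference
# mixes channels (a 14 x 14 channel-coupling matrix per band).  The two
# commute (one is diagonal in channels, the other in frequency).


@functools.lru_cache(maxsize=8)
def _welch_band_smear(
    sample_rate: float, epoch_s: float, bands_key: tuple
) -> np.ndarray:
    """Band-coupling matrix M of the Hann-tapered Welch estimator.

    ``M[b, b']`` is the contribution of unit density in band b' to the
    measured band-average density of band b, computed from the exact
    spectral window of the taper on a fine frequency grid.
    """
    nperseg = int(round(epoch_s * sample_rate))
    window = get_window("hann", nperseg)
    fine_factor = 64
    L = nperseg * fine_factor
    # Normalized so a flat spectrum is measured unchanged: sum(kernel) == 1.
    kernel = np.abs(np.fft.fft(window, L)) ** 2 / (np.sum(window**2) * L)
    fine = np.fft.fftfreq(L, 1.0 / sample_rate)
    coarse = np.fft.rfftfreq(nperseg, 1.0 / sample_rate)
    bands = list(bands_key)
    masks = [ (np.abs(fine) >= lo) & (np.abs(fine) < hi) for _, lo, hi in bands ]
    M = np.zeros((len(bands), len(bands)))
    for b, (_, lo, hi) in enumerate(bands):
        bins = np.nonzero((coarse >= lo) & (coarse < hi))[0]
        for k in bins:
            shifted = np.roll(kernel, k * fine_factor)
            for b2, mask in enumerate(masks):
                M[b, b2] += shifted[mask].sum()
        M[b] /= len(bins)
    return M


def _welch_smear_inverse(
    per_channel_targets: np.ndarray, scheme: BandScheme, sample_rate: float,
    epoch_s: float = 4.0,
) -> np.ndarray:
    """Solve for synthesis band densities whose Welch band averages hit the
    targets.  ``per_channel_targets`` is (n_bands, n_channels)."""
    key = tuple((name, *scheme.edges(name)) for name in scheme.names)
    M = _welch_band_smear(sample_rate, epoch_s, key)
    out = np.linalg.solve(M, per_channel_targets)
    return np.maximum(out, 1e-12)


def _reference_inverse(targets: np.ndarray) -> np.ndarray:
    """Solve for generation densities whose average-referenced densities
    equal ``targets`` (independent channels assumed)."""
    c = targets.shape[0]
    A = np.full((c, c), 1.0 / c**2)
    np.fill_diagonal(A, (1.0 - 1.0 / c) ** 2)
    out = np.linalg.solve(A, targets)
    return np.maximum(out, 1e-12)


def _edge_weight(coherence: float) -> float:
    """Mixing weight realizing a target magnitude-squared coherence."""
    return float(np.clip(coherence, 0.0, 0.999)) ** 0.25


def subject_edge_coherence(
    config: CohortConfig, latents: SubjectLatents
) -> dict[tuple[str, str, str], float]:
    """True per-subject coherence at every planted edge."""
    out: dict[tuple[str, str, str], float] = {}
    for ci, cj, band, coh in config.fixed_coherence_edges:
        out[(ci, cj, band)] = float(coh)
    for effect in config.coherence_effects():
        key = (*effect.channels, effect.band)
        z = latents.z_edges[key]
        out[key] = float(
            np.clip(
                config.coherence_base + config.coherence_sd * z, 0.02, 0.98
            )
        )
    return out


def generate_subject_signal(
    config: CohortConfig,
    latents: SubjectLatents,
    condition: str,
    seed,
) -> Recording:
    """One resting recording for one subject.

    Frequency-domain synthesis: for each band, complex Gaussian rFFT
    coefficients flat at the subject's target density inside the band
    (zero outside), with shared sources mixed in at planted edges; a
    single inverse rFFT yields the channel x sample matrix.
    """
    if condition not in ("eyes_open", "eyes_closed"):
        raise ParameterError(f"condition must be a resting state, got {condition!r}")
    rng = np.random.default_rng(seed)
    fs = config.sample_rate
    n = int(round(config.duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    bands = config.band_scheme
    names = list(bands.names)
    densities = config.densities()
    sigma = config.subject_sd_log
    mult = np.exp(sigma * latents.z_power - sigma**2 / 2.0)

    edge_coh = subject_edge_coherence(config, latents)
    edges_by_band: dict[str, list[tuple[int, int, float]]] = {}
    weight_sq = np.zeros((len(names), _N_CH))
    for (ci, cj, band), coh in edge_coh.items():
        w = _edge_weight(coh)
        b = names.index(band)
        i, j = CHANNELS_14.index(ci), CHANNELS_14.index(cj)
        edges_by_band.setdefault(band, []).append((i, j, w))
        weight_sq[b, i] += w**2
        weight_sq[b, j] += w**2
    if np.any(weight_sq > 1.0):
        raise ConfigurationError(
            "planted coherence edges over-commit a channel (sum of w^2 > 1)"
        )

    targets = np.stack([densities[band] * mult[b] for b, band in enumerate(names)])
    if condition == "eyes_closed" and "alpha" in names:
        b_alpha = names.index("alpha")
        for ch in OCCIPITAL:
            targets[b_alpha, CHANNELS_14.index(ch)] *= config.ec_alpha_boost
    if config.welch_compensation:
        targets = _welch_smear_inverse(targets, bands, fs, config.welch_epoch_s)
    if config.reference_compensation:
        targets = np.stack([_reference_inverse(t) for t in targets])

    coeffs = np.zeros((_N_CH, freqs.size), dtype=complex)
    for b, band in enumerate(names):
        low, high = bands.edges(band)
        mask = (freqs >= low) & (freqs < high)
        nb = int(mask.sum())
        if nb == 0:
            continue
        target = targets[b]
        own = rng.standard_normal((_N_CH, nb)) + 1j * rng.standard_normal((_N_CH, nb))
        unit = np.sqrt(1.0 - weight_sq[b])[:, None] * own
        for i, j, w in edges_by_band.get(band, ()):  # share one source per edge
            shared = rng.standard_normal(nb) + 1j * rng.standard_normal(nb)
            unit[i] += w * shared
            unit[j] += w * shared
        scale = np.sqrt(target * fs * n / 4.0)
        coeffs[:, mask] = unit * scale[:, None]
    data = np.fft.irfft(coeffs, n=n, axis=-1)
    return Recording(
        subject_id="synthetic",
        condition=condition,
        sample_rate=fs,
        data=data,
        montage=builtin_montage(),
    )


# ---------------------------------------------------------------------------
# Artifacts

def inject_artifacts(
    rec: Recording, spec: ArtifactSpec | None = None, seed=None
) -> tuple[Recording, list[Annotation]]:
    """Add blink, muscle, and flat-channel artifacts; annotate each event.

    Blinks are frontally-weighted raised-cosine transients (~300 uV at
    AF3/AF4 decaying with head-plane distance); muscle events are
    broadband 20-46 Hz bursts on one random channel; a flat channel is
    one channel zeroed for several seconds.  With all rates zero the
    recording is returned unchanged.
    """
    spec = spec or ArtifactSpec()
    if spec.silent:
        return rec, []
    rng = np.random.default_rng(seed)
    fs = rec.sample_rate
    n = rec.n_samples
    duration_min = rec.duration_s / 60.0
    data = rec.data.copy()
    events: list[Annotation] = []
    montage = rec.montage

    n_blinks = rng.poisson(spec.blink_rate_for(rec.condition) * duration_min)
    blink_len = int(round(spec.blink_duration_s * fs))
    if blink_len > 0 and n_blinks > 0:
        pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(blink_len) / blink_len))
        frontal_pos = [montage.position(ch) for ch in FRONTAL if ch in rec.channels]
        for onset_idx in rng.integers(0, max(1, n - blink_len), n_blinks):
            for c, name in enumerate(rec.channels):
                if frontal_pos:
                    d = min(
                        float(np.linalg.norm(montage.position(name) - p))
                        for p in frontal_pos
                    )
                else:
                    d = 0.0
                amp = spec.blink_amp_uv * np.exp(-d / spec.blink_spread)
                data[c, onset_idx : onset_idx + blink_len] += amp * pulse
            events.append(
                Annotation(onset_idx / fs, spec.blink_duration_s, "blink")
            )

    n_muscle = rng.poisson(spec.muscle_rate_per_min * duration_min)
    muscle_len = int(round(spec.muscle_duration_s * fs))
    if muscle_len > 1 and n_muscle > 0:
        low, high = spec.muscle_band_hz
        f = np.fft.rfftfreq(muscle_len, 1.0 / fs)
        band = (f >= low) & (f < min(high, fs / 2))
        for onset_idx in rng.integers(0, max(1, n - muscle_len), n_muscle):
            ch = int(rng.integers(0, data.shape[0]))
            coeff = np.zeros(f.size, complex)
            coeff[band] = rng.standard_normal(band.sum()) + 1j * rng.standard_normal(
                band.sum()
            )
            burst = np.fft.irfft(coeff, n=muscle_len)
            burst *= spec.muscle_rms_uv / max(np.sqrt(np.mean(burst**2)), 1e-12)
            taper = 0.5 * (1 - np.cos(2 * np.pi * np.arange(muscle_len) / muscle_len))
            data[ch, onset_idx : onset_idx + muscle_len] += burst * taper
            events.append(
                Annotation(onset_idx / fs, spec.muscle_duration_s, "muscle")
            )

    if rng.random() < spec.flat_channel_prob:
        flat_len = int(round(spec.flat_duration_s * fs))
        if flat_len < n:
            ch = int(rng.integers(0, data.shape[0]))
            onset_idx = int(rng.integers(0, n - flat_len))
            data[ch, onset_idx : onset_idx + flat_len] = 0.0
            events.append(
                Annotation(
                    onset_idx / fs, spec.flat_duration_s, f"flat:{rec.channels[ch]}"
                )
            )

    out = rec.with_data(data, annotations=list(rec.annotations) + events)
    return out, events


# ---------------------------------------------------------------------------
# Behavioral covariates

def _standardized_feature(
    config: CohortConfig, truth_mult: np.ndarray, latents: list[SubjectLatents],
    effect: PlantedEffect,
) -> np.ndarray:
    """Per-subject standardized true feature values for one planted effect."""
    names = list(config.band_scheme.names)
    if effect.kind == "power":
        b = names.index(effect.band)
        c = CHANNELS_14.index(effect.channels[0])
        mult = truth_mult[:, b, c]
        sd = np.sqrt(np.expm1(config.subject_sd_log**2))
        if sd == 0:
            raise ConfigurationError(
                "cannot plant a power effect with subject_sd_log = 0"
            )
        return (mult - 1.0) / sd
    key = (*effect.channels, effect.band)
    return np.array([lat.z_edges[key] for lat in latents])


def generate_behavior_covariates(
    config: CohortConfig,
    truth_mult: np.ndarray,
    latents: list[SubjectLatents],
    subjects: list[str],
    seed,
) -> pd.DataFrame:
    """Per-subject behavioral covariates with planted correlations.

    For each measure, ``y = sum_k rho_k x_k + sqrt(1 - sum rho_k^2) eps``
    on the standard scale, where ``x_k`` is the standardized true
    feature of planted effect k; then affine mapping to the published
    scale (accuracy clipped to [0, 100]).
    """
    rng = np.random.default_rng(seed)
    n = len(subjects)
    out = {"subject": subjects}
    for measure, (mean, sd, clip) in {
        "mean_rt_ms": (RT_MEAN_MS, RT_SD_MS, None),
        "accuracy_pct": (ACCURACY_MEAN_PCT, ACCURACY_SD_PCT, (0.0, 100.0)),
    }.items():
        effects = [e for e in config.planted_effects if e.behavioral_measure == measure]
        seen = set()
        for e in effects:
            if e.feature in seen:
                raise ConfigurationError(
                    f"two planted effects on {measure} share feature {e.feature}"
                )
            seen.add(e.feature)
        rho_sq = sum(e.rho**2 for e in effects)
        if rho_sq >= 1:
            raise ConfigurationError(
                f"planted correlations on {measure} are jointly infeasible "
                f"(sum of rho^2 = {rho_sq:.3f} >= 1)"
            )
        y = np.zeros(n)
        for e in effects:
            y += e.rho * _standardized_feature(config, truth_mult, latents, e)
        y += np.sqrt(1.0 - rho_sq) * rng.standard_normal(n)
        y = mean + sd * y
        if clip is not None:
            y = np.clip(y, *clip)
        out[measure] = y
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Cohort assembly

def _subject_seed(master_seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=key)


def draw_subject_latents(config: CohortConfig, subject_idx: int) -> SubjectLatents:
    """Latents for one subject; independent streams per subject."""
    rng = np.random.default_rng(_subject_seed(config.master_seed, 0, subject_idx))
    z_power = rng.standard_normal((len(config.band_scheme.names), _N_CH))
    z_edges = {
        (*e.channels, e.band): float(rng.standard_normal())
        for e in config.coherence_effects()
    }
    return SubjectLatents(z_power=z_power, z_edges=z_edges)


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[Recording], pd.DataFrame, GroundTruth]:
    """A full cohort: recordings per subject and condition, behavioral
    covariates, and the ground truth behind both.

    Deterministic and bit-reproducible given ``config`` (including
    ``master_seed``); per-subject streams are independent, so changing
    one subject's seed leaves every other subject's data unchanged.
    """
    config = config or CohortConfig()
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    latents = [draw_subject_latents(config, i) for i in range(config.n_subjects)]
    sigma = config.subject_sd_log
    mult = np.exp(
        sigma * np.stack([lat.z_power for lat in latents]) - sigma**2 / 2.0
    )
    behavior = generate_behavior_covariates(
        config, mult, latents, subjects,
        seed=_subject_seed(config.master_seed, 1),
    )
    recordings: list[Recording] = []
    for i, subject in enumerate(subjects):
        for k, condition in enumerate(config.conditions):
            rec = generate_subject_signal(
                config, latents[i], condition,
                seed=_subject_seed(config.master_seed, 2, i, k),
            )
            rec, _ = inject_artifacts(
                rec, config.artifact_spec,
                seed=_subject_seed(config.master_seed, 3, i, k),
            )
            recordings.append(
                replace_subject(rec, subject)
            )
    edge_coherence = {}
    for key in (
        [(*e.channels, e.band) for e in config.coherence_effects()]
        + [(ci, cj, band) for ci, cj, band, _ in config.fixed_coherence_edges]
    ):
        edge_coherence[key] = np.array(
            [subject_edge_coherence(config, lat).get(key, np.nan) for lat in latents]
        )
    truth = GroundTruth(
        config=config,
        subjects=subjects,
        latents=latents,
        multipliers=mult,
        edge_coherence=edge_coherence,
        behavior=behavior,
    )
    return recordings, behavior, truth


def replace_subject(rec: Recording, subject_id: str) -> Recording:
    return rec.with_data(rec.data, subject_id=subject_id)


def ground_truth_dict(truth: GroundTruth) -> dict:
    """JSON-serializable view of a cohort's ground truth (for export)."""
    names = list(truth.config.band_scheme.names)
    return {
        "subjects": truth.subjects,
        "bands": names,
        "channels": list(CHANNELS_14),
        "master_seed": truth.config.master_seed,
        "subject_sd_log": truth.config.subject_sd_log,
        "multipliers": truth.multipliers.tolist(),
        "planted_effects": [
            {
                "feature": list(e.feature),
                "behavioral_measure": e.behavioral_measure,
                "rho": e.rho,
            }
            for e in truth.config.planted_effects
        ],
        "edge_coherence": {
            "|".join(key): values.tolist()
            for key, values in truth.edge_coherence.items()
        },
        "behavior": truth.behavior.to_dict(orient="list"),
    }
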