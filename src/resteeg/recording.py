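"""Core containers: recordings, annotations, and the band scheme.

A :class:`Recording` is a dense channel x sample matrix in microvolts at
a fixed sample rate, with a montage naming its rows.  Channels that are
rejected downstream are *removed* from both the data and the montage
(never padded), so the invariant ``data.shape[0] == montage.n_channels``
holds throughout the pipeline.  Time is seconds from recording start,
samples are 0-based, and epoch windows are half-open ``[t0, t0 + T)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import MontageError, ParameterError
from .montage import Montage, builtin_montage

#: Valid recording conditions.
CONDITIONS = ("eyes_open", "eyes_closed", "task")


@dataclass(frozen=True)
class Annotation:
    """A labelled event: onset and duration in seconds from recording start."""

    onset: float
    duration: float
    label: str

    def as_tuple(self) -> tuple[float, float, str]:
        return (self.onset, self.duration, self.label)


@dataclass
class Recording:
    """One subject/condition multichannel EEG time series.

    Parameters
    ----------
    subject_id
        Subject identifier; carried through every exported table.
    condition
        One of ``eyes_open``, ``eyes_closed``, ``task``.
    sample_rate
        Sampling rate in Hz (the wearable headset records at 128 Hz).
    data
        ``(n_channels, n_samples)`` float64 array in microvolts.
    montage
        Montage naming the rows of ``data``.
    annotations
        Event list (artifact markers, stimulus onsets, ...).
    """

    subject_id: str
    condition: str
    sample_rate: float
    data: np.ndarray = field(repr=False)
    montage: Montage = field(default_factory=builtin_montage)
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ParameterError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ParameterError("data must be a (channels, samples) matrix")
        if self.data.shape[0] != self.montage.n_channels:
            raise MontageError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("data contains non-finite samples")
        self.annotations = [
            a if isinstance(a, Annotation) else Annotation(*a)
            for a in self.annotations
        ]

    @property
    def channels(self) -> tuple[str, ...]:
        return self.montage.channel_names

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        """The time series of a single electrode, by name."""
        return self.data[self.montage.index(name)]

    def with_data(self, data: np.ndarray, **kwargs) -> "Recording":
        """Copy of this recording with new data (and optional field overrides)."""
        return Recording(
            subject_id=kwargs.get("subject_id", self.subject_id),
            condition=kwargs.get("condition", self.condition),
            sample_rate=kwargs.get("sample_rate", self.sample_rate),
            data=data,
            montage=kwargs.get("montage", self.montage),
            annotations=kwargs.get("annotations", list(self.annotations)),
        )

    def drop_channels(self, names: Iterable[str]) -> "Recording":
        """Remove channels by name; rows are deleted, never padded."""
        drop = set(names)
        keep = [n for n in self.channels if n not in drop]
        if not keep:
            raise MontageError("cannot drop every channel")
        idx = [self.montage.index(n) for n in keep]
        return self.with_data(self.data[idx], montage=self.montage.subset(keep))


# ---------------------------------------------------------------------------
# Frequency bands

#: Canonical EEG bands over the 1-46 Hz analysis span (Hz, half-open).
DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 28.0),
    "gamma": (28.0, 46.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous, non-overlapping frequency bands covering a span.

    The default scheme is delta 1-4, theta 4-8, alpha 8-13, beta 13-28,
    gamma 28-46 Hz over the analysis span (1, 46) Hz.  Bands are
    half-open ``[low, high)`` so shared edges are counted exactly once.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    analysis_span: tuple[float, float] = (1.0, 46.0)

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        if not edges:
            raise ParameterError("band scheme must define at least one band")
        lo, hi = self.analysis_span
        if edges[0][0] != lo or edges[-1][1] != hi:
            raise ParameterError(
                f"bands must cover the analysis span {self.analysis_span}"
            )
        for (name_a, (a0, a1)), (name_b, (b0, b1)) in zip(
            list(self.bands.items())[:-1], list(self.bands.items())[1:]
        ):
            if a1 != b0:
                raise ParameterError(
                    f"bands {name_a} and {name_b} must be contiguous"
                )
        for name, (low, high) in self.bands.items():
            if not low < high:
                raise ParameterError(f"band {name} has empty range ({low}, {high})")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        try:
            return self.bands[name]
        except KeyError:
            raise ParameterError(f"unknown band {name!r}") from None

    def bandwidth(self, name: str) -> float:
        low, high = self.edges(name)
        return high - low


def default_band_scheme() -> BandScheme:
    return BandScheme()


def replace_recording(rec: Recording, **kwargs) -> Recording:
    """Dataclass-style replace helper for :class:`Recording`."""
    return rec.with_data(kwargs.pop("data", rec.data), **kwargs)
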