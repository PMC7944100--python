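"""Electrode montage for the 14-channel wearable headset.

The montage covers the 10-20 positions AF3, F7, F3, FC5, T7, P7, O1, O2,
P8, T8, FC6, F4, F8, AF4 (in that fixed order).  Positions are 2-D
head-plane coordinates under the usual top-view polar projection: the
nose points along +y, the right ear along +x, and the head rim is the
unit circle.  Coordinates are unitless; they are used for distance
weighting (artifact topographies) and for export to external plotting,
never for analysis itself — all tables index channels by *name*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MontageError

#: Channel order of the built-in montage (fixed; all outputs follow it).
CHANNELS_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

# Top-view polar projection of standard 10-20 positions. Outer-ring
# electrodes (F7/8, T7/8, P7/8, O1/2) sit at radius 0.8; the angle is
# measured from the nose (+y) toward the ears. Intermediate electrodes
# use conventional projected positions. Left/right homologs are exact
# mirror images in x.
def _pol(radius: float, angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return (radius * math.sin(a), radius * math.cos(a))


_POSITIONS: dict[str, tuple[float, float]] = {
    "AF3": _pol(0.72, -21.0),
    "AF4": _pol(0.72, 21.0),
    "F7": _pol(0.80, -54.0),
    "F8": _pol(0.80, 54.0),
    "F3": _pol(0.55, -39.0),
    "F4": _pol(0.55, 39.0),
    "FC5": _pol(0.64, -69.0),
    "FC6": _pol(0.64, 69.0),
    "T7": _pol(0.80, -90.0),
    "T8": _pol(0.80, 90.0),
    "P7": _pol(0.80, -126.0),
    "P8": _pol(0.80, 126.0),
    "O1": _pol(0.80, -162.0),
    "O2": _pol(0.80, 162.0),
}

#: Occipital sites used for the eyes-closed/eyes-open alpha contrast.
OCCIPITAL = ("O1", "O2")

#: Frontal sites where blink artifacts are largest.
FRONTAL = ("AF3", "AF4")


@dataclass(frozen=True)
class Montage:
    """An ordered set of named electrodes with head-plane positions.

    Parameters
    ----------
    channel_names
        Ordered, unique channel labels.
    positions
        ``(n_channels, 2)`` array of (x, y) head-plane coordinates,
        head radius 1.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            raise MontageError("channel names must be unique")
        if pos.shape != (len(names), 2):
            raise MontageError(
                f"positions shape {pos.shape} does not match {len(names)} channels"
            )
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(radii >= 1.0):
            raise MontageError("all electrode positions must lie inside the unit circle")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise MontageError(f"channel {name!r} not in montage") from None

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]

    def distance(self, a: str, b: str) -> float:
        """Euclidean head-plane distance between two electrodes."""
        return float(np.linalg.norm(self.position(a) - self.position(b)))

    def subset(self, names: list[str] | tuple[str, ...]) -> "Montage":
        """Montage restricted to *names*, keeping this montage's order."""
        keep = [n for n in self.channel_names if n in set(names)]
        missing = set(names) - set(self.channel_names)
        if missing:
            raise MontageError(f"channels not in montage: {sorted(missing)}")
        idx = [self.index(n) for n in keep]
        return Montage(tuple(keep), self.positions[idx])


def builtin_montage() -> Montage:
    """The 14-channel wearable-headset montage in its canonical order."""
    pos = np.array([_POSITIONS[name] for name in CHANNELS_14])
    return Montage(CHANNELS_14, pos)
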