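"""Shared fixtures: montages, small recordings, synthetic file writers."""

from __future__ import annotations

import numpy as np
import pytest

from resteeg.montage import builtin_montage
from resteeg.recording import Recording


@pytest.fixture(scope="session")
def montage():
    return builtin_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(
    data: np.ndarray,
    sample_rate: float = 128.0,
    subject_id: str = "S01",
    condition: str = "eyes_closed",
    channels: list[str] | None = None,
) -> Recording:
    """Recording over the built-in montage (or a named subset of it)."""
    mont = builtin_montage()
    if channels is not None:
        mont = mont.subset(channels)
    return Recording(
        subject_id=subject_id,
        condition=condition,
        sample_rate=sample_rate,
        data=data,
        montage=mont,
    )


def white_recording(
    rng: np.random.Generator,
    n_channels: int = 14,
    duration_s: float = 60.0,
    sample_rate: float = 128.0,
    scale: float = 1.0,
    **kwargs,
) -> Recording:
    """Gaussian white-noise recording on the first n montage channels."""
    mont = builtin_montage()
    channels = list(mont.channel_names[:n_channels])
    data = scale * rng.standard_normal((n_channels, int(duration_s * sample_rate)))
    return make_recording(data, sample_rate, channels=channels, **kwargs)


def write_synthetic_edf(path, data_uv, fs: float, labels: list[str]) -> None:
    """Minimal synthetic EDF writer (int16 records, physical unit uV).

    Exists only so tests can build EDF inputs programmatically; not a
    general-purpose exporter.
    """
    data_uv = np.asarray(data_uv, float)
    ns, n = data_uv.shape
    spr = int(fs)  # one-second records
    n_records = n // spr
    pmin, pmax = -3276.8, 3276.7
    dmin, dmax = -32768, 32767

    def pad(s: str, w: int) -> bytes:
        return s.ljust(w)[:w].encode("ascii")

    header = b"".join(
        [
            pad("0", 8), pad("X X X X", 80), pad("Startdate X", 80),
            pad("01.01.20", 8), pad("00.00.00", 8),
            pad(str(256 + ns * 256), 8), pad("", 44),
            pad(str(n_records), 8), pad("1", 8), pad(str(ns), 4),
        ]
    )
    per_signal = [
        ("".join(lab.ljust(16) for lab in labels), 16),
        ("".join("".ljust(80) for _ in labels), 80),
        ("".join("uV".ljust(8) for _ in labels), 8),
        ("".join(str(pmin).ljust(8) for _ in labels), 8),
        ("".join(str(pmax).ljust(8) for _ in labels), 8),
        ("".join(str(dmin).ljust(8) for _ in labels), 8),
        ("".join(str(dmax).ljust(8) for _ in labels), 8),
        ("".join("".ljust(80) for _ in labels), 80),
        ("".join(str(spr).ljust(8) for _ in labels), 8),
        ("".join("".ljust(32) for _ in labels), 32),
    ]
    header += b"".join(f[0].encode("ascii") for f in per_signal)
    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for c in range(ns):
                seg = data_uv[c, r * spr : (r + 1) * spr]
                dig = np.round((seg - pmin) * scale + dmin).astype("<i2")
                fh.write(dig.tobytes())
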