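"""Reading and writing recordings: internal fixture format, EDF, XDF.

The internal fixture format is one ``.npy`` float64 matrix (channels x
samples, microvolts) plus a JSON sidecar with the same stem carrying
subject, condition, sample rate, channel names/positions, and
annotations.  The round trip is bit-exact, which is what makes fixture-
based regression tests trustworthy.

External formats are read-only: EDF/EDF+ through :mod:`mne`, XDF through
the in-package chunk reader.  On ingest, channels are matched to the
built-in montage by label (case-insensitive, ``EEG``-prefix tolerant),
unknown channels are dropped with a logged warning, and rows are
reordered to montage order.  Everything is standardized to microvolts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from ._xdf import read_xdf
from .errors import FormatError, MontageError, ParameterError
from .montage import Montage, builtin_montage
from .recording import Annotation, Recording

logger = logging.getLogger(__name__)

#: EDF physical-dimension strings accepted, with scale to microvolts.
_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "mv": 1e3, "v": 1e6}


def _fixture_paths(path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix == ".json":
        return path.with_suffix(".npy"), path
    if path.suffix == ".npy":
        return path, path.with_suffix(".json")
    return path.with_suffix(path.suffix + ".npy"), path.with_suffix(path.suffix + ".json")


def write_fixture(rec: Recording, path) -> Path:
    """Persist a recording as ``<stem>.npy`` + ``<stem>.json``.

    Returns the data-file path.  ``read_recording`` inverts this exactly
    (values and metadata).
    """
    data_path, sidecar_path = _fixture_paths(path)
    meta = {
        "format": "resteeg-fixture",
        "version": 1,
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "sample_rate": rec.sample_rate,
        "channels": list(rec.channels),
        "positions": [[float(x), float(y)] for x, y in rec.montage.positions],
        "annotations": [[a.onset, a.duration, a.label] for a in rec.annotations],
    }
    try:
        data_path.parent.mkdir(parents=True, exist_ok=True)
        np.save(data_path, rec.data, allow_pickle=False)
        sidecar_path.write_text(json.dumps(meta, indent=1))
    except OSError as exc:
        raise FormatError(f"cannot write fixture at {path}: {exc}") from exc
    return data_path


def _read_fixture(path) -> Recording:
    data_path, sidecar_path = _fixture_paths(path)
    try:
        meta = json.loads(sidecar_path.read_text())
        data = np.load(data_path, allow_pickle=False)
    except (OSError, json.JSONDecodeError, ValueError) as exc:
        raise FormatError(f"cannot read fixture at {path}: {exc}") from exc
    if meta.get("format") != "resteeg-fixture":
        raise FormatError(f"{sidecar_path} is not a resteeg fixture sidecar")
    montage = Montage(tuple(meta["channels"]), np.asarray(meta["positions"]))
    return Recording(
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        sample_rate=float(meta["sample_rate"]),
        data=data,
        montage=montage,
        annotations=[Annotation(o, d, lab) for o, d, lab in meta["annotations"]],
    )


def _normalize_label(label: str) -> str:
    label = label.strip()
    for prefix in ("EEG ", "eeg "):
        if label.startswith(prefix):
            label = label[len(prefix):]
    return label.split("-")[0].strip().upper()


def _map_to_montage(
    labels: list[str], data_uv: np.ndarray, source: str
) -> tuple[Montage, np.ndarray]:
    """Match channel labels to the built-in montage; reorder rows to it."""
    montage = builtin_montage()
    canon = {name.upper(): name for name in montage.channel_names}
    found: dict[str, int] = {}
    for i, raw_label in enumerate(labels):
        name = canon.get(_normalize_label(raw_label))
        if name is None:
            logger.warning("%s: dropping unknown channel %r", source, raw_label)
        elif name in found:
            logger.warning("%s: duplicate channel %r ignored", source, raw_label)
        else:
            found[name] = i
    if not found:
        raise MontageError(f"{source}: no channels map onto the built-in montage")
    sub = montage.subset(list(found))
    rows = np.array([found[name] for name in sub.channel_names])
    return sub, np.ascontiguousarray(data_uv[rows])


def _edf_physical_dimensions(path) -> list[str]:
    """Per-signal physical-dimension strings from an EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        ns = int(header[252:256].decode("ascii", "replace").strip() or 0)
        fh.seek(256 + ns * (16 + 80))
        dims = fh.read(ns * 8).decode("ascii", "replace")
    return [dims[i * 8 : (i + 1) * 8].strip() for i in range(ns)]


def _read_edf(path, subject_id: str, condition: str) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises several types for bad files
        raise FormatError(f"cannot read EDF {path}: {exc}") from exc
    dims = _edf_physical_dimensions(path)
    for label, dim in zip(raw.ch_names, dims):
        key = dim.strip().lower().replace("μ", "µ")
        if key and key not in _UNIT_TO_UV and "annotation" not in label.lower():
            raise FormatError(
                f"{path}: channel {label!r} has unsupported physical dimension {dim!r}"
            )
    data_uv = raw.get_data() * 1e6  # mne loads EDF voltages in SI volts
    montage, data = _map_to_montage(list(raw.ch_names), data_uv, str(path))
    annotations = [
        Annotation(float(on), float(du), str(de))
        for on, du, de in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    return Recording(
        subject_id=subject_id,
        condition=condition,
        sample_rate=float(raw.info["sfreq"]),
        data=data,
        montage=montage,
        annotations=annotations,
    )


def _read_xdf_recording(path, subject_id: str, condition: str) -> Recording:
    streams = [s for s in read_xdf(path) if s.time_series is not None]
    eeg = [s for s in streams if s.stream_type.upper() == "EEG"] or streams
    if not eeg:
        raise FormatError(f"{path}: no streams found")
    stream = eeg[0]
    if stream.nominal_srate <= 0:
        raise FormatError(f"{path}: stream {stream.name!r} has no nominal rate")
    labels = stream.channel_labels or [f"ch{i}" for i in range(stream.channel_count)]
    montage, data = _map_to_montage(labels, stream.time_series.T, str(path))
    return Recording(
        subject_id=subject_id,
        condition=condition,
        sample_rate=float(stream.nominal_srate),
        data=data,
        montage=montage,
    )


def read_recording(
    path,
    format: str | None = None,
    subject_id: str | None = None,
    condition: str = "eyes_closed",
) -> Recording:
    """Read a recording from ``fixture``, ``edf``, or ``xdf`` storage.

    ``format`` is inferred from the file suffix when not given.  EDF and
    XDF carry no subject/condition metadata this pipeline recognizes, so
    ``subject_id`` (default: the file stem) and ``condition`` apply to
    those formats; the fixture format stores both.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".edf": "edf", ".xdf": "xdf", ".npy": "fixture", ".json": "fixture"}.get(
            suffix, "fixture"
        )
    if subject_id is None:
        subject_id = path.stem
    if format == "fixture":
        return _read_fixture(path)
    if format == "edf":
        return _read_edf(path, subject_id, condition)
    if format == "xdf":
        return _read_xdf_recording(path, subject_id, condition)
    raise ParameterError(f"unknown format {format!r} (expected edf, xdf, or fixture)")
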