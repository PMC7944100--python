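"""Compact reader (and synthetic writer) for XDF multi-stream files.

XDF is the chunked container produced by Lab Streaming Layer recorders:
a ``XDF:`` magic followed by length-prefixed chunks (file header, stream
header XML, sample chunks, clock offsets, boundaries, stream footer).
This module implements the subset needed to ingest recorded EEG streams
with numeric sample formats and regular (nominal-rate) sampling; string
streams and clock resynchronisation are out of scope.

:func:`write_minimal_xdf` emits a minimal, valid single-stream file and
exists so tests and examples can build synthetic XDF inputs; it is not a
general-purpose recorder.
"""

from __future__ import annotations

import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

_MAGIC = b"XDF:"

_FORMATS = {
    "float32": ("<f4", 4),
    "double64": ("<f8", 8),
    "int8": ("<i1", 1),
    "int16": ("<i2", 2),
    "int32": ("<i4", 4),
    "int64": ("<i8", 8),
}


@dataclass
class XdfStream:
    """One stream recovered from an XDF file."""

    stream_id: int
    name: str
    stream_type: str
    channel_count: int
    nominal_srate: float
    channel_format: str
    channel_labels: list[str] = field(default_factory=list)
    time_series: np.ndarray | None = None  # (n_samples, n_channels)
    timestamps: np.ndarray | None = None


def _read_varlen_uint(buf: bytes, pos: int) -> tuple[int, int]:
    nbytes = buf[pos]
    pos += 1
    if nbytes == 1:
        return buf[pos], pos + 1
    if nbytes == 4:
        return struct.unpack_from("<I", buf, pos)[0], pos + 4
    if nbytes == 8:
        return struct.unpack_from("<Q", buf, pos)[0], pos + 8
    raise FormatError(f"invalid XDF varlen size {nbytes}")


def _parse_stream_header(stream_id: int, xml_text: str) -> XdfStream:
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise FormatError(f"bad XDF stream header XML: {exc}") from exc

    def txt(tag: str, default: str = "") -> str:
        node = root.find(tag)
        return node.text.strip() if node is not None and node.text else default

    labels = [
        (ch.findtext("label") or "").strip()
        for ch in root.findall("./desc/channels/channel")
    ]
    return XdfStream(
        stream_id=stream_id,
        name=txt("name"),
        stream_type=txt("type"),
        channel_count=int(txt("channel_count", "0")),
        nominal_srate=float(txt("nominal_srate", "0")),
        channel_format=txt("channel_format", "float32"),
        channel_labels=labels,
    )


def read_xdf(path) -> list[XdfStream]:
    """Parse an XDF file and return its numeric streams with sample data."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if not buf.startswith(_MAGIC):
        raise FormatError(f"{path}: not an XDF file (bad magic)")

    streams: dict[int, XdfStream] = {}
    chunks: dict[int, list[np.ndarray]] = {}
    stamps: dict[int, list[np.ndarray]] = {}
    pos = len(_MAGIC)
    n = len(buf)
    while pos < n:
        length, pos = _read_varlen_uint(buf, pos)
        if pos + length > n:
            raise FormatError(f"{path}: truncated XDF chunk")
        tag = struct.unpack_from("<H", buf, pos)[0]
        content_start = pos + 2
        content_end = pos + length
        if tag == 2:  # StreamHeader
            sid = struct.unpack_from("<I", buf, content_start)[0]
            xml_text = buf[content_start + 4 : content_end].decode("utf-8")
            streams[sid] = _parse_stream_header(sid, xml_text)
            chunks.setdefault(sid, [])
            stamps.setdefault(sid, [])
        elif tag == 3:  # Samples
            sid = struct.unpack_from("<I", buf, content_start)[0]
            if sid not in streams:
                raise FormatError(f"{path}: samples for unknown stream {sid}")
            stream = streams[sid]
            if stream.channel_format not in _FORMATS:
                raise FormatError(
                    f"{path}: unsupported channel format {stream.channel_format!r}"
                )
            dtype, itemsize = _FORMATS[stream.channel_format]
            p = content_start + 4
            n_samples, p = _read_varlen_uint(buf, p)
            nch = stream.channel_count
            rows = np.empty((n_samples, nch))
            ts = np.full(n_samples, np.nan)
            for i in range(n_samples):
                ts_bytes = buf[p]
                p += 1
                if ts_bytes == 8:
                    ts[i] = struct.unpack_from("<d", buf, p)[0]
                    p += 8
                elif ts_bytes != 0:
                    raise FormatError(f"{path}: invalid timestamp length {ts_bytes}")
                rows[i] = np.frombuffer(buf, dtype=dtype, count=nch, offset=p)
                p += itemsize * nch
            if p != content_end:
                raise FormatError(f"{path}: malformed sample chunk for stream {sid}")
            chunks[sid].append(rows)
            stamps[sid].append(ts)
        # tags 1 (file header), 4 (clock offset), 5 (boundary), 6 (footer):
        # nothing needed for offline ingest at nominal rate.
        pos = content_end

    out = []
    for sid, stream in streams.items():
        if chunks[sid]:
            stream.time_series = np.concatenate(chunks[sid], axis=0)
            stream.timestamps = np.concatenate(stamps[sid])
        else:
            stream.time_series = np.empty((0, stream.channel_count))
            stream.timestamps = np.empty(0)
        out.append(stream)
    return out


# ---------------------------------------------------------------------------
# Minimal synthetic writer (test/example support only)

def _varlen(value: int) -> bytes:
    if value < 256:
        return bytes([1, value])
    return b"\x04" + struct.pack("<I", value)


def _chunk(tag: int, content: bytes) -> bytes:
    payload = struct.pack("<H", tag) + content
    return _varlen(len(payload)) + payload


def write_minimal_xdf(
    path,
    data: np.ndarray,
    srate: float,
    labels: list[str],
    name: str = "synthetic-eeg",
    stream_type: str = "EEG",
    stream_id: int = 1,
) -> None:
    """Write a synthetic single-stream XDF file (float32 samples, no clock info).

    ``data`` is (n_channels, n_samples) and is stored sample-major as XDF
    requires.  Intended only for constructing test inputs.
    """
    data = np.asarray(data, dtype=np.float32)
    nch, nsamp = data.shape
    if len(labels) != nch:
        raise FormatError("one label per channel required")
    chan_xml = "".join(
        f"<channel><label>{lab}</label><unit>microvolts</unit></channel>"
        for lab in labels
    )
    header_xml = (
        f"<info><name>{name}</name><type>{stream_type}</type>"
        f"<channel_count>{nch}</channel_count>"
        f"<nominal_srate>{srate:g}</nominal_srate>"
        f"<channel_format>float32</channel_format>"
        f"<desc><channels>{chan_xml}</channels></desc></info>"
    )
    sid = struct.pack("<I", stream_id)
    body = bytearray()
    body += _chunk(1, b"<info><version>1.0</version></info>")
    body += _chunk(2, sid + header_xml.encode())
    samples = bytearray()
    samples += sid
    samples += _varlen(nsamp)
    cols = np.ascontiguousarray(data.T)
    for i in range(nsamp):
        if i == 0:
            samples += b"\x08" + struct.pack("<d", 0.0)
        else:
            samples += b"\x00"
        samples += cols[i].tobytes()
    body += _chunk(3, bytes(samples))
    body += _chunk(6, sid + b"<info></info>")
    with open(path, "wb") as fh:
        fh.write(_MAGIC + bytes(body))
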