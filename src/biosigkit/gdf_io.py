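"""Reading and writing biosignal files: a documented GDF-v2 subset and EDF.

The GDF container has five components: a mandatory 256-byte fixed header,
a variable header of 256 bytes per channel, an optional tag-length-value
(TLV) header, the data records, and a table of events.  All multi-byte
numerics are little-endian and the version field is plain text at byte 0,
so the format can be identified from the leading bytes alone.  The exact
field offsets used here are documented in FORMAT.md at the repository root.

EDF (European Data Format) is supported read-only: a 256-byte ASCII header,
256 ASCII bytes per channel, then 16-bit little-endian data records.
EDF+ annotation channels are ignored.
"""

from __future__ import annotations

import struct
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "FixedHeader",
    "ChannelSpec",
    "EventTable",
    "SignalRecording",
    "TlvBlock",
    "write_gdf",
    "read_gdf",
    "read_edf",
    "detect_format",
    "read_segment",
]

GDF_MAGIC = b"GDF"
GDF_VERSION = "GDF 2.20"
FIXED_HEADER_SIZE = 256
CHANNEL_HEADER_SIZE = 256

# GDF numeric type codes for the supported sample types
TYPE_INT16 = 3
TYPE_FLOAT32 = 16
_DTYPES = {TYPE_INT16: np.dtype("<i2"), TYPE_FLOAT32: np.dtype("<f4")}
_TYPE_NAMES = {"int16": TYPE_INT16, "float32": TYPE_FLOAT32}


class FormatError(ValueError):
    """Raised when a file violates the GDF/EDF layout or a field cannot be serialized."""


def _pack_str(text: str, size: int, what: str) -> bytes:
    raw = text.encode("ascii", errors="strict")
    if len(raw) > size:
        raise FormatError(f"{what} too long: {len(raw)} bytes > {size} ('{text}')")
    return raw.ljust(size, b"\x00")


def _unpack_str(raw: bytes) -> str:
    return raw.rstrip(b"\x00 ").decode("ascii", errors="replace")


@dataclass
class FixedHeader:
    """Header 1 of a GDF file: recording-level metadata (256 bytes on disk)."""

    version_id: str = GDF_VERSION
    recording_id: str = ""
    patient_info: str = ""
    start_datetime: float = 0.0  # seconds since the Unix epoch
    n_channels: int = 0
    n_records: int = 0
    samples_per_record: int = 1  # reference rate; event positions use this time base
    sampling_rate: float = 1.0

    def validate(self) -> None:
        if not self.version_id.startswith("GDF"):
            raise FormatError(f"version_id must start with 'GDF', got '{self.version_id}'")
        if self.n_channels < 0 or self.n_records < 0:
            raise FormatError("n_channels and n_records must be non-negative")
        if self.samples_per_record <= 0:
            raise FormatError("samples_per_record must be positive")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")


@dataclass
class ChannelSpec:
    """Header-2 entry: per-channel metadata and affine calibration (256 bytes on disk)."""

    label: str = ""
    physical_dimension: str = "uV"
    physical_min: float = -1.0
    physical_max: float = 1.0
    digital_min: int = -32768
    digital_max: int = 32767
    sample_type: str = "float32"  # "int16" or "float32"
    samples_per_record: int = 1

    @property
    def gain(self) -> float:
        return (self.physical_max - self.physical_min) / (self.digital_max - self.digital_min)

    @property
    def offset(self) -> float:
        return self.physical_min - self.gain * self.digital_min

    def validate(self) -> None:
        if self.physical_min >= self.physical_max:
            raise FormatError(f"channel '{self.label}': physical_min >= physical_max")
        if self.digital_min >= self.digital_max:
            raise FormatError(f"channel '{self.label}': digital_min >= digital_max")
        if self.sample_type not in _TYPE_NAMES:
            raise FormatError(
                f"channel '{self.label}': unsupported sample_type '{self.sample_type}' "
                "(supported: int16, float32)"
            )
        if self.samples_per_record <= 0:
            raise FormatError(f"channel '{self.label}': samples_per_record must be positive")


@dataclass
class EventTable:
    """Sparse annotations: (sample position, 16-bit code), optionally channel + duration.

    Positions are 0-based sample indices on the recording's reference
    sampling rate and must be sorted nondecreasing.
    """

    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint16))
    channels: np.ndarray | None = None
    durations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.uint16)
        if self.channels is not None:
            self.channels = np.asarray(self.channels, dtype=np.int64)
        if self.durations is not None:
            self.durations = np.asarray(self.durations, dtype=np.int64)

    @property
    def mode(self) -> int:
        return 3 if (self.channels is not None or self.durations is not None) else 1

    def __len__(self) -> int:
        return len(self.positions)

    def validate(self) -> None:
        if len(self.codes) != len(self.positions):
            raise FormatError("event positions and codes must have equal length")
        if np.any(np.diff(self.positions) < 0):
            raise FormatError("event positions must be sorted nondecreasing")
        if self.mode == 3:
            if self.channels is None or self.durations is None:
                raise FormatError("mode-3 event table needs both channels and durations")
            if len(self.channels) != len(self.positions) or len(self.durations) != len(self.positions):
                raise FormatError("event table parallel fields must have equal length")


@dataclass
class TlvBlock:
    """Opaque tag-length-value blob from header 3; tag semantics are not interpreted."""

    tag: int
    value: bytes


@dataclass
class SignalRecording:
    """In-memory image of a GDF/EDF file: headers, calibrated data, events.

    ``data`` holds one 1-D float64 array of *physical* values per channel;
    channels may have different lengths when their sampling rates differ.
    """

    fixed_header: FixedHeader
    channels: list[ChannelSpec] = field(default_factory=list)
    data: list[np.ndarray] = field(default_factory=list)
    events: EventTable = field(default_factory=EventTable)
    tlv_blocks: list[TlvBlock] = field(default_factory=list)

    def validate(self) -> None:
        self.fixed_header.validate()
        if len(self.channels) != self.fixed_header.n_channels:
            raise FormatError(
                f"channel spec count {len(self.channels)} != n_channels "
                f"{self.fixed_header.n_channels}"
            )
        if len(self.data) != self.fixed_header.n_channels:
            raise FormatError("data channel count != n_channels")
        for ch, x in zip(self.channels, self.data):
            ch.validate()
            expect = self.fixed_header.n_records * ch.samples_per_record
            if len(x) != expect:
                raise FormatError(
                    f"channel '{ch.label}': {len(x)} samples, expected "
                    f"{expect} (n_records × samples_per_record)"
                )
        self.events.validate()

    @property
    def sampling_rate(self) -> float:
        return self.fixed_header.sampling_rate

    def channel_rate(self, index: int) -> float:
        """Sampling rate of one channel in Hz (per-channel rates allowed)."""
        fh = self.fixed_header
        return self.channels[index].samples_per_record * fh.sampling_rate / fh.samples_per_record

    def to_array(self) -> np.ndarray:
        """Stack channels into a (n_channels, n_samples) array; requires equal rates."""
        lengths = {len(x) for x in self.data}
        if len(lengths) > 1:
            raise ValueError("channels have different lengths; cannot stack uniformly")
        return np.vstack(self.data) if self.data else np.empty((0, 0))

    @property
    def duration(self) -> float:
        fh = self.fixed_header
        return fh.n_records * fh.samples_per_record / fh.sampling_rate


# ---------------------------------------------------------------------------
# GDF writing

_FIXED_STRUCT = struct.Struct("<8s64s64sdIQId QQB")  # + 71 reserved bytes
_CHAN_STRUCT = struct.Struct("<16s16sddqqII")  # + 184 reserved bytes


def _pack_fixed_header(fh: FixedHeader, tlv_length: int, events: EventTable) -> bytes:
    raw = _FIXED_STRUCT.pack(
        _pack_str(fh.version_id, 8, "version_id"),
        _pack_str(fh.recording_id, 64, "recording_id"),
        _pack_str(fh.patient_info, 64, "patient_info"),
        float(fh.start_datetime),
        fh.n_channels,
        fh.n_records,
        fh.samples_per_record,
        float(fh.sampling_rate),
        tlv_length,
        len(events),
        events.mode,
    )
    return raw.ljust(FIXED_HEADER_SIZE, b"\x00")


def _pack_channel(ch: ChannelSpec) -> bytes:
    raw = _CHAN_STRUCT.pack(
        _pack_str(ch.label, 16, "label"),
        _pack_str(ch.physical_dimension, 16, "physical_dimension"),
        float(ch.physical_min),
        float(ch.physical_max),
        ch.digital_min,
        ch.digital_max,
        _TYPE_NAMES[ch.sample_type],
        ch.samples_per_record,
    )
    return raw.ljust(CHANNEL_HEADER_SIZE, b"\x00")


def _physical_to_digital(x: np.ndarray, ch: ChannelSpec) -> np.ndarray:
    if ch.sample_type == "float32":
        digital = (x - ch.offset) / ch.gain
        return digital.astype("<f4")
    digital = np.rint((x - ch.offset) / ch.gain)
    digital = np.clip(digital, ch.digital_min, ch.digital_max)
    return digital.astype("<i2")


def write_gdf(recording: SignalRecording, destination: str | Path) -> int:
    """Serialize a recording to the GDF2-subset layout; returns bytes written.

    Layout: [fixed header 256 B][n_channels × 256 B][TLV header][data
    records][event table].  Re-reading the file yields an equal recording
    (bit-exact for float32 channels whose calibration is the identity,
    within one quantization step for int16 channels).
    """
    recording.validate()
    fh = recording.fixed_header
    tlv_raw = b"".join(
        struct.pack("<BI", blk.tag, len(blk.value)) + blk.value for blk in recording.tlv_blocks
    )

    digital = [_physical_to_digital(x, ch) for x, ch in zip(recording.data, recording.channels)]

    n = 0
    with open(destination, "wb") as f:
        n += f.write(_pack_fixed_header(fh, len(tlv_raw), recording.events))
        for ch in recording.channels:
            n += f.write(_pack_channel(ch))
        n += f.write(tlv_raw)
        for rec in range(fh.n_records):
            for ch, dig in zip(recording.channels, digital):
                spr = ch.samples_per_record
                n += f.write(dig[rec * spr : (rec + 1) * spr].tobytes())
        ev = recording.events
        n += f.write(ev.positions.astype("<u4").tobytes())
        n += f.write(ev.codes.astype("<u2").tobytes())
        if ev.mode == 3:
            n += f.write(ev.channels.astype("<u2").tobytes())
            n += f.write(ev.durations.astype("<u4").tobytes())
    return n


# ---------------------------------------------------------------------------
# GDF reading


def _read_exact(f: BinaryIO, size: int, what: str) -> bytes:
    raw = f.read(size)
    if len(raw) != size:
        raise FormatError(
            f"truncated file while reading {what}: wanted {size} bytes at offset "
            f"{f.tell() - len(raw)}, got {len(raw)}"
        )
    return raw


def _parse_headers(f: BinaryIO) -> tuple[FixedHeader, list[ChannelSpec], list[TlvBlock], int, int]:
    """Parse headers 1-3; returns (fixed, channels, tlv, n_events, event_mode)."""
    raw = _read_exact(f, FIXED_HEADER_SIZE, "fixed header")
    if not raw.startswith(GDF_MAGIC):
        raise FormatError(f"not a GDF file: leading bytes {raw[:8]!r}")
    (version, rec_id, pat, start, n_ch, n_rec, spr, fs, tlv_len, n_ev, ev_mode) = (
        _FIXED_STRUCT.unpack(raw[: _FIXED_STRUCT.size])
    )
    fh = FixedHeader(
        version_id=_unpack_str(version),
        recording_id=_unpack_str(rec_id),
        patient_info=_unpack_str(pat),
        start_datetime=start,
        n_channels=n_ch,
        n_records=n_rec,
        samples_per_record=spr,
        sampling_rate=fs,
    )
    channels = []
    for i in range(n_ch):
        craw = _read_exact(f, CHANNEL_HEADER_SIZE, f"channel header {i}")
        (label, dim, pmin, pmax, dmin, dmax, stype, cspr) = _CHAN_STRUCT.unpack(
            craw[: _CHAN_STRUCT.size]
        )
        if stype not in _DTYPES:
            raise FormatError(f"channel {i}: unsupported sample type code {stype}")
        channels.append(
            ChannelSpec(
                label=_unpack_str(label),
                physical_dimension=_unpack_str(dim),
                physical_min=pmin,
                physical_max=pmax,
                digital_min=dmin,
                digital_max=dmax,
                sample_type="int16" if stype == TYPE_INT16 else "float32",
                samples_per_record=cspr,
            )
        )
    tlv_blocks = []
    remaining = tlv_len
    while remaining > 0:
        head = _read_exact(f, 5, "TLV block header")
        tag, vlen = struct.unpack("<BI", head)
        value = _read_exact(f, vlen, f"TLV value (tag {tag})")
        tlv_blocks.append(TlvBlock(tag=tag, value=value))
        remaining -= 5 + vlen
    if remaining < 0:
        raise FormatError("TLV header overruns its declared length")
    return fh, channels, tlv_blocks, n_ev, ev_mode


def _record_layout(channels: Sequence[ChannelSpec]) -> tuple[list[int], int]:
    """Byte offset of each channel's chunk within one data record, and record size."""
    offsets, pos = [], 0
    for ch in channels:
        offsets.append(pos)
        pos += ch.samples_per_record * _DTYPES[_TYPE_NAMES[ch.sample_type]].itemsize
    return offsets, pos


def _read_events(f: BinaryIO, n_ev: int, mode: int) -> EventTable:
    positions = np.frombuffer(_read_exact(f, 4 * n_ev, "event positions"), dtype="<u4")
    codes = np.frombuffer(_read_exact(f, 2 * n_ev, "event codes"), dtype="<u2")
    channels = durations = None
    if mode == 3:
        channels = np.frombuffer(_read_exact(f, 2 * n_ev, "event channels"), dtype="<u2")
        durations = np.frombuffer(_read_exact(f, 4 * n_ev, "event durations"), dtype="<u4")
    return EventTable(positions=positions, codes=codes, channels=channels, durations=durations)


def read_gdf(source: str | Path) -> SignalRecording:
    """Read a GDF2-subset file into a calibrated :class:`SignalRecording`."""
    with open(source, "rb") as f:
        fh, channels, tlv_blocks, n_ev, ev_mode = _parse_headers(f)
        data = []
        raw_per_chan: list[list[bytes]] = [[] for _ in channels]
        offsets, rec_size = _record_layout(channels)
        for rec in range(fh.n_records):
            raw = _read_exact(f, rec_size, f"data record {rec}")
            for i, ch in enumerate(channels):
                nbytes = ch.samples_per_record * _DTYPES[_TYPE_NAMES[ch.sample_type]].itemsize
                raw_per_chan[i].append(raw[offsets[i] : offsets[i] + nbytes])
        for ch, chunks in zip(channels, raw_per_chan):
            dig = np.frombuffer(b"".join(chunks), dtype=_DTYPES[_TYPE_NAMES[ch.sample_type]])
            data.append(dig.astype(np.float64) * ch.gain + ch.offset)
        events = _read_events(f, n_ev, ev_mode)
    rec = SignalRecording(fixed_header=fh, channels=channels, data=data, events=events,
                          tlv_blocks=tlv_blocks)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# EDF reading (per the public EDF standard; annotations ignored)


def read_edf(source: str | Path) -> SignalRecording:
    """Read an EDF file; 16-bit samples calibrated to physical units.

    EDF+ annotation channels ("EDF Annotations") are skipped.  The returned
    recording's reference rate is the highest per-channel rate.
    """
    with open(source, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise FormatError(f"EDF header truncated: {len(head)} < 256 bytes")
        try:
            head.decode("ascii")
        except UnicodeDecodeError as exc:
            raise FormatError("EDF header is not ASCII") from exc

        def fld(lo: int, hi: int) -> str:
            return head[lo:hi].decode("ascii").strip()

        patient = fld(8, 88)
        recording_id = fld(88, 168)
        startdate, starttime = fld(168, 176), fld(176, 184)
        n_records = int(fld(236, 244))
        record_duration = float(fld(244, 252))
        ns = int(fld(252, 256))

        chead = f.read(256 * ns)
        if len(chead) < 256 * ns:
            raise FormatError("EDF channel headers truncated")

        def cfld(width: int, block_start: int, i: int) -> str:
            start = block_start * ns + i * width
            return chead[start : start + width].decode("ascii").strip()

        labels = [cfld(16, 0, i) for i in range(ns)]
        # field order per the standard: label(16) transducer(80) dim(8)
        # phys_min(8) phys_max(8) dig_min(8) dig_max(8) prefilter(80) spr(8) reserved(32)
        base = 0
        offsets = {}
        for name, width in [("label", 16), ("transducer", 80), ("dim", 8), ("pmin", 8),
                            ("pmax", 8), ("dmin", 8), ("dmax", 8), ("prefilter", 80),
                            ("spr", 8), ("reserved", 32)]:
            offsets[name] = base
            base += width

        def col(name: str, width: int, i: int) -> str:
            start = offsets[name] * ns + i * width
            return chead[start : start + width].decode("ascii").strip()

        dims = [col("dim", 8, i) for i in range(ns)]
        pmins = [float(col("pmin", 8, i)) for i in range(ns)]
        pmaxs = [float(col("pmax", 8, i)) for i in range(ns)]
        dmins = [int(col("dmin", 8, i)) for i in range(ns)]
        dmaxs = [int(col("dmax", 8, i)) for i in range(ns)]
        sprs = [int(col("spr", 8, i)) for i in range(ns)]

        keep = [i for i in range(ns) if labels[i] != "EDF Annotations"]
        rec_words = sum(sprs)
        raw = f.read(2 * rec_words * n_records)
        if len(raw) < 2 * rec_words * n_records:
            raise FormatError("EDF data section truncated")
        samples = np.frombuffer(raw, dtype="<i2").reshape(n_records, rec_words)

        word_offsets = np.concatenate([[0], np.cumsum(sprs)])
        channels, data = [], []
        ref_spr = max((sprs[i] for i in keep), default=1)
        for i in keep:
            gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
            offset = pmins[i] - gain * dmins[i]
            dig = samples[:, word_offsets[i] : word_offsets[i] + sprs[i]].reshape(-1)
            channels.append(
                ChannelSpec(
                    label=labels[i], physical_dimension=dims[i],
                    physical_min=pmins[i], physical_max=pmaxs[i],
                    digital_min=dmins[i], digital_max=dmaxs[i],
                    sample_type="int16", samples_per_record=sprs[i],
                )
            )
            data.append(dig.astype(np.float64) * gain + offset)

    fh = FixedHeader(
        version_id="GDF 2.20",
        recording_id=recording_id,
        patient_info=patient,
        start_datetime=_edf_datetime(startdate, starttime),
        n_channels=len(keep),
        n_records=n_records,
        samples_per_record=ref_spr,
        sampling_rate=ref_spr / record_duration if record_duration > 0 else 1.0,
    )
    rec = SignalRecording(fixed_header=fh, channels=channels, data=data)
    rec.validate()
    return rec


def _edf_datetime(startdate: str, starttime: str) -> float:
    try:
        t = time.strptime(f"{startdate} {starttime}", "%d.%m.%y %H.%M.%S")
        return float(time.mktime(t))
    except ValueError:
        return 0.0


# ---------------------------------------------------------------------------
# Format detection and block reading


def detect_format(source: str | Path) -> str:
    """Identify the file format from its leading bytes: 'GDF', 'EDF' or 'unknown'.

    Never reads beyond the first 8 bytes.
    """
    with open(source, "rb") as f:
        head = f.read(8)
    if head.startswith(GDF_MAGIC):
        return "GDF"
    if head == b"0       ":  # EDF version field: "0" padded to 8 ASCII bytes
        return "EDF"
    return "unknown"


def read_segment(
    source: str | Path,
    start_sample: int,
    n_samples: int,
    channels: Sequence[int],
) -> list[np.ndarray]:
    """Read a block of calibrated data without loading the whole file.

    ``start_sample`` and ``n_samples`` are counted on each requested
    channel's own sampling grid.  Returns one array per requested channel,
    equal to the corresponding slice of a full :func:`read_gdf`.
    """
    if start_sample < 0 or n_samples < 0:
        raise IndexError("start_sample and n_samples must be non-negative")
    with open(source, "rb") as f:
        fh, chan_specs, _tlv, _n_ev, _mode = _parse_headers(f)
        data_start = f.tell()
        offsets, rec_size = _record_layout(chan_specs)
        out = []
        for ci in channels:
            if not 0 <= ci < fh.n_channels:
                raise IndexError(f"channel index {ci} out of range [0, {fh.n_channels})")
            ch = chan_specs[ci]
            total = fh.n_records * ch.samples_per_record
            if start_sample + n_samples > total:
                raise IndexError(
                    f"requested samples [{start_sample}, {start_sample + n_samples}) "
                    f"exceed channel length {total}"
                )
            if n_samples == 0:
                out.append(np.empty(0, dtype=np.float64))
                continue
            dtype = _DTYPES[_TYPE_NAMES[ch.sample_type]]
            spr = ch.samples_per_record
            first_rec = start_sample // spr
            last_rec = (start_sample + n_samples - 1) // spr
            chunks = []
            for rec in range(first_rec, last_rec + 1):
                f.seek(data_start + rec * rec_size + offsets[ci])
                chunks.append(_read_exact(f, spr * dtype.itemsize, f"record {rec}"))
            dig = np.frombuffer(b"".join(chunks), dtype=dtype)
            lo = start_sample - first_rec * spr
            dig = dig[lo : lo + n_samples]
            out.append(dig.astype(np.float64) * ch.gain + ch.offset)
    return out
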