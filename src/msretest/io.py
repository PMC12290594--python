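"""Reading and writing recordings.

Three on-disk formats are supported:

``container``
    A lossless HDF5 container holding the float64 data, rate, channel
    metadata, events and provenance.  This is the canonical intermediate
    between pipeline stages (EDF quantizes to 16 bit, so repeatedly
    round-tripping through EDF mid-pipeline would accumulate error).
``edf``
    EDF+C with a 16-bit physical/digital scaling per channel and events
    stored as EDF+ annotations.  Written by this module, read back via
    :func:`mne.io.read_raw_edf`.
``brainvision``
    The BrainProducts triplet (.vhdr/.vmrk/.eeg) with IEEE float 32
    multiplexed data; read back via :func:`mne.io.read_raw_brainvision`.

Amplitudes are microvolts in memory everywhere; EDF physical dimensions
and mne's Volt convention are converted at the boundary.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import h5py
import numpy as np

from .core import Recording, RecordingError

__all__ = ["load_recording", "save_recording"]

_FORMATS = ("brainvision", "edf", "container")


class FormatError(ValueError):
    """File does not parse as the named format."""


def _infer_ch_type(name: str) -> str:
    u = name.upper()
    if u.startswith("CWL"):
        return "cwl"
    if u.startswith("ECG") or u.startswith("EKG"):
        return "ecg"
    return "eeg"


# ---------------------------------------------------------------------
# container (HDF5)
# ---------------------------------------------------------------------

def _save_container(rec: Recording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["rate"] = rec.rate
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("ch_names", data=np.array(rec.ch_names, dtype=object), dtype=str_dt)
        f.create_dataset("ch_types", data=np.array(rec.ch_types, dtype=object), dtype=str_dt)
        f.create_dataset("event_samples", data=np.array([s for s, _ in rec.events], dtype=np.int64))
        f.create_dataset("event_labels", data=np.array([l for _, l in rec.events], dtype=object), dtype=str_dt)
        if rec.positions is not None:
            f.create_dataset("positions", data=rec.positions)
        f.create_dataset("meta", data=np.array(rec.meta, dtype=object), dtype=str_dt)


def _load_container(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        rate = float(f.attrs["rate"])
        ch_names = [s.decode() if isinstance(s, bytes) else s for s in f["ch_names"][()]]
        ch_types = [s.decode() if isinstance(s, bytes) else s for s in f["ch_types"][()]]
        samples = f["event_samples"][()]
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["event_labels"][()]]
        events = [(int(s), l) for s, l in zip(samples, labels)]
        positions = f["positions"][()] if "positions" in f else None
        meta = [s.decode() if isinstance(s, bytes) else s for s in f["meta"][()]]
    return Recording(data=data, rate=rate, ch_names=ch_names, ch_types=ch_types,
                     events=events, positions=positions, meta=meta)


# ---------------------------------------------------------------------
# EDF+ writer
# ---------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {value!r}")
    return b.ljust(width)


def _save_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF+C writer: one data record per second (padded at the
    end with the edge value), 16-bit digital range, one annotation signal
    carrying all events as text annotations."""
    rate = rec.rate
    spr = int(round(rate))
    if abs(spr - rate) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_sig = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    if n_records == 0:
        raise FormatError("empty recording")

    # physical scaling per channel
    pmins, pmaxs = [], []
    for ch in rec.data:
        lo, hi = float(np.min(ch)), float(np.max(ch))
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
    dmin, dmax = -32768, 32767

    # annotations: timestamp TAL per record, all events in record 0
    tals = []
    for rec_i in range(n_records):
        parts = [f"+{rec_i}\x14\x14\x00"]
        if rec_i == 0:
            for s, lab in rec.events:
                onset = s / rate
                lab_ascii = lab.encode("ascii", "replace").decode()
                parts.append(f"+{onset:.7f}\x14{lab_ascii}\x14\x00")
        tals.append("".join(parts).encode("ascii"))
    ann_bytes = max(len(t) for t in tals)
    ann_spr = max((ann_bytes + 1) // 2 + 1, 8)   # int16 samples

    total_sig = n_sig + 1
    header_bytes = 256 * (1 + total_sig)

    h = bytearray()
    h += _edf_field("0", 8)
    h += _edf_field("X X X X", 80)                      # patient
    h += _edf_field("Startdate X X X X", 80)            # recording
    h += _edf_field("01.01.00", 8)
    h += _edf_field("00.00.00", 8)
    h += _edf_field(str(header_bytes), 8)
    h += _edf_field("EDF+C", 44)
    h += _edf_field(str(n_records), 8)
    h += _edf_field("1", 8)                             # record duration s
    h += _edf_field(str(total_sig), 4)

    labels = [n[:16] for n in rec.ch_names] + ["EDF Annotations"]
    h += b"".join(_edf_field(l, 16) for l in labels)
    h += b"".join(_edf_field("", 80) for _ in range(total_sig))          # transducer
    h += b"".join(_edf_field("uV", 8) for _ in range(n_sig)) + _edf_field("", 8)
    h += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmins) + _edf_field("-1", 8)
    h += b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmaxs) + _edf_field("1", 8)
    h += b"".join(_edf_field(str(dmin), 8) for _ in range(total_sig))
    h += b"".join(_edf_field(str(dmax), 8) for _ in range(total_sig))
    h += b"".join(_edf_field("", 80) for _ in range(total_sig))          # prefilter
    h += b"".join(_edf_field(str(spr), 8) for _ in range(n_sig))
    h += _edf_field(str(ann_spr), 8)
    h += b"".join(_edf_field("", 32) for _ in range(total_sig))          # reserved
    assert len(h) == header_bytes

    # digitize
    scale = [(pmaxs[i] - pmins[i]) / (dmax - dmin) for i in range(n_sig)]
    with open(path, "wb") as f:
        f.write(bytes(h))
        for rec_i in range(n_records):
            start = rec_i * spr
            stop = min(start + spr, rec.n_samples)
            for i in range(n_sig):
                chunk = rec.data[i, start:stop]
                if stop - start < spr:   # pad last record with edge value
                    pad = np.full(spr - (stop - start), chunk[-1] if len(chunk) else 0.0)
                    chunk = np.concatenate([chunk, pad])
                dig = np.round((chunk - pmins[i]) / scale[i]) + dmin
                f.write(np.clip(dig, dmin, dmax).astype("<i2").tobytes())
            tal = tals[rec_i].ljust(ann_spr * 2, b"\x00")
            f.write(tal)


# ---------------------------------------------------------------------
# BrainVision writer
# ---------------------------------------------------------------------

def _save_brainvision(rec: Recording, path: Path) -> None:
    path = Path(path)
    if path.suffix != ".vhdr":
        raise FormatError("BrainVision path must end in .vhdr")
    stem = path.stem
    vmrk = path.with_suffix(".vmrk")
    eeg = path.with_suffix(".eeg")

    interval_us = 1e6 / rec.rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.ch_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (s, lab) in enumerate(rec.events, start=2):
        mlines.append(f"Mk{k}=Stimulus,{lab},{s + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    eeg.write_bytes(np.asarray(rec.data, dtype="<f4").T.tobytes())


# ---------------------------------------------------------------------
# mne-backed readers
# ---------------------------------------------------------------------

def _events_from_annotations(raw, rate: float, n: int) -> list[tuple[int, str]]:
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        label = re.sub(r"^(Stimulus|Comment|Response)/", "", desc)
        if label in ("New Segment/", "New Segment"):
            continue
        s = int(round(onset * rate))
        if 0 <= s < n:
            events.append((s, label))
    events.sort(key=lambda e: e[0])
    return events


def _recording_from_raw(raw) -> Recording:
    data = raw.get_data() * 1e6    # V -> uV
    rate = float(raw.info["sfreq"])
    ch_names = list(raw.ch_names)
    if len(set(ch_names)) != len(ch_names):
        raise RecordingError(f"duplicate channel labels in file: {ch_names}")
    ch_types = [_infer_ch_type(n) for n in ch_names]
    events = _events_from_annotations(raw, rate, data.shape[1])
    return Recording(data=data, rate=rate, ch_names=ch_names,
                     ch_types=ch_types, events=events,
                     meta=["loaded"])


def _load_edf(path: Path) -> Recording:
    import mne
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:   # noqa: BLE001 - surface as format error
        raise FormatError(f"not a readable EDF file: {exc}") from exc
    return _recording_from_raw(raw)


def _load_brainvision(path: Path) -> Recording:
    import mne
    path = Path(path)
    # verify the triplet is consistent before handing to mne
    header = path.read_text(encoding="utf-8", errors="replace")
    m = re.search(r"^DataFile=(.+)$", header, re.M)
    if m is None:
        raise FormatError("header missing DataFile field")
    if not (path.parent / m.group(1).strip()).exists():
        raise FormatError(f"mismatched triplet: data file {m.group(1).strip()} missing")
    m = re.search(r"^MarkerFile=(.+)$", header, re.M)
    if m is not None and not (path.parent / m.group(1).strip()).exists():
        raise FormatError(f"mismatched triplet: marker file {m.group(1).strip()} missing")
    try:
        raw = mne.io.read_raw_brainvision(str(path), preload=True, verbose="error")
    except Exception as exc:   # noqa: BLE001
        raise FormatError(f"not a readable BrainVision file: {exc}") from exc
    return _recording_from_raw(raw)


# ---------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------

def save_recording(rec: Recording, path: str | os.PathLike, format: str) -> Path:
    """Write ``rec`` to ``path`` in the named format and return the path."""
    if format not in _FORMATS:
        raise FormatError(f"unsupported format {format!r}; choose from {_FORMATS}")
    if rec.n_samples == 0:
        raise RecordingError("empty recording")
    path = Path(path)
    if format == "container":
        _save_container(rec, path)
    elif format == "edf":
        _save_edf(rec, path)
    else:
        _save_brainvision(rec, path)
    return path


def load_recording(path: str | os.PathLike, format: str) -> Recording:
    """Read a recording from ``path`` (data in microvolts)."""
    if format not in _FORMATS:
        raise FormatError(f"unsupported format {format!r}; choose from {_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "container":
        return _load_container(path)
    if format == "edf":
        return _load_edf(path)
    return _load_brainvision(path)
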