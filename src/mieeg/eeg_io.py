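"""Reading/writing continuous recordings, events and epoched datasets.

Conventions (asserted throughout the package): sample indices are 0-based,
windows are half-open ``[a, b)``, signals are in microvolts.

Formats
-------
* Continuous: EDF (16-bit; read through MNE, written by a minimal EDF
  writer implemented here) or CSV (one column per channel, microvolts) with
  a JSON sidecar ``<name>.json`` carrying at least ``{"fs": <Hz>}``.
* Events: CSV with columns ``onset_sample,label``.
* Epochs container: one little-endian float32 binary blob holding the
  trial-major ``[trial, channel, sample]`` array (``epochs_f32.bin``) plus a
  JSON sidecar (``epochs.json``) with shape, fs, labels, channel names,
  cue index, provenance and a SHA-256 checksum of the blob.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LABELS, EpochSet

logger = logging.getLogger(__name__)

EPOCHS_BLOB = "epochs_f32.bin"
EPOCHS_SIDECAR = "epochs.json"


class FormatError(ValueError):
    """Malformed file or header."""


class CorruptionError(IOError):
    """Checksum mismatch in the epochs container."""


@dataclass
class ContinuousRecording:
    """Continuous multichannel signal, ``[channel, sample]`` in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    start_time: str = "2020-01-01T00:00:00"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} names for {self.data.shape[0]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EventTable:
    """Cue events: 0-based onset samples with class labels."""

    onsets: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.onsets.ndim != 1 or len(self.onsets) != len(self.labels):
            raise ValueError("onsets and labels must be 1-D and equal length")
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {LABELS}")

    def __len__(self) -> int:
        return len(self.onsets)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        df = pd.read_csv(path)
        missing = {"onset_sample", "label"} - set(df.columns)
        if missing:
            raise FormatError(f"events CSV missing columns {sorted(missing)}")
        return cls(df["onset_sample"].to_numpy(), df["label"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"onset_sample": self.onsets, "label": self.labels}).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# continuous I/O
# ---------------------------------------------------------------------------

def read_continuous(path, format: str | None = None) -> ContinuousRecording:
    """Read an EDF or CSV(+JSON sidecar) continuous recording, in microvolts."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")


def _read_edf(path: Path) -> ContinuousRecording:
    import mne

    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various error types for bad headers
        raise FormatError(f"cannot parse EDF {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return ContinuousRecording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        start_time=str(raw.info.get("meas_date") or "unknown"),
    )


def _read_csv(path: Path) -> ContinuousRecording:
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar} with sampling rate")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise FormatError(f"sidecar {sidecar} lacks 'fs'")
    df = pd.read_csv(path)
    return ContinuousRecording(
        data=df.to_numpy(dtype=float).T,
        fs=float(meta["fs"]),
        channel_names=list(df.columns),
        start_time=str(meta.get("start_time", "unknown")),
    )


def write_continuous(rec: ContinuousRecording, path, format: str | None = None) -> Path:
    """Write a recording as EDF (16-bit) or CSV(+sidecar). Returns the path."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "csv":
        pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(path, index=False)
        path.with_suffix(".json").write_text(
            json.dumps({"fs": rec.fs, "start_time": rec.start_time})
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: ContinuousRecording, path: Path) -> None:
    """Minimal EDF writer: 1-second data records, int16, physical unit uV.

    The recording is zero-padded to a whole number of records; EDF encodes
    each channel with 16-bit quantization over its physical range.
    """
    if rec.fs != int(rec.fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(rec.fs)  # samples per 1 s record
    n_ch, n = rec.data.shape
    n_records = math.ceil(n / spr)
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n] = rec.data

    phys_min = np.floor(np.min(padded, axis=1))
    phys_max = np.ceil(np.max(padded, axis=1))
    flat = phys_max <= phys_min
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("synthetic subject", 80),
        _edf_field("mieeg recording", 80),
        _edf_field("01.01.20", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field("1", 8),
        _edf_field(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(c, 16) for c in rec.channel_names),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{phys_min[c]:.0f}", 8) for c in range(n_ch)),
        b"".join(_edf_field(f"{phys_max[c]:.0f}", 8) for c in range(n_ch)),
        b"".join(_edf_field(dig_min, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dig_max, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(spr, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            chunk = padded[:, r * spr : (r + 1) * spr]
            dig = np.rint(
                (chunk - phys_min[:, None]) * scale[:, None] + dig_min
            ).astype("<i2")
            fh.write(dig.tobytes())


# ---------------------------------------------------------------------------
# epoch extraction
# ---------------------------------------------------------------------------

def epoch_extract(
    rec: ContinuousRecording, events: EventTable, window: tuple[float, float]
) -> EpochSet:
    """Cut half-open epochs ``[onset+round(a*fs), onset+round(b*fs))``.

    The window must span the cue (``a < 0 <= b``).  Events whose window
    falls outside the recording are dropped (count logged); an empty result
    is an error.  Second-to-sample conversion uses round-half-even, applied
    once per edge.
    """
    a, b = window
    if not (a < 0 <= b) or a == b:
        raise ValueError(f"window {window} must satisfy a < 0 <= b")
    off_lo = int(np.round(a * rec.fs))
    off_hi = int(np.round(b * rec.fs))
    if off_hi <= off_lo:
        raise ValueError(f"window {window} is degenerate at fs={rec.fs}")
    n_per = off_hi - off_lo

    trials, labels, dropped = [], [], 0
    for onset, label in zip(events.onsets, events.labels):
        lo, hi = onset + off_lo, onset + off_hi
        if lo < 0 or hi > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.data[:, lo:hi])
        labels.append(label)
    if dropped:
        logger.info("epoch_extract: dropped %d/%d out-of-bounds events",
                    dropped, len(events))
    if not trials:
        raise ValueError("no valid epochs: every event window is out of bounds")
    return EpochSet(
        data=np.stack(trials),
        labels=np.array(labels, dtype=object),
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        cue_index=-off_lo,
        provenance={"source": "epoch_extract", "window_s": [a, b],
                    "n_dropped": dropped, "n_samples_per_trial": n_per},
    )


# ---------------------------------------------------------------------------
# epochs container
# ---------------------------------------------------------------------------

def write_epochs(es: EpochSet, directory) -> Path:
    """Persist an EpochSet losslessly (within float32) to a directory."""
    if es.n_trials == 0:
        raise ValueError("refusing to write an empty EpochSet")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    blob = np.ascontiguousarray(es.data, dtype="<f4").tobytes()
    sidecar = {
        "shape": list(es.data.shape),
        "dtype": "<f4",
        "order": "trial-major (trial, channel, sample), C-order",
        "fs": es.fs,
        "labels": list(es.labels),
        "channel_names": list(es.channel_names),
        "cue_index": es.cue_index,
        "provenance": es.provenance,
        "sha256": hashlib.sha256(blob).hexdigest(),
    }
    (directory / EPOCHS_BLOB).write_bytes(blob)
    (directory / EPOCHS_SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return directory


def read_epochs(directory) -> EpochSet:
    """Load an epochs container; verifies the blob checksum."""
    directory = Path(directory)
    sidecar_path = directory / EPOCHS_SIDECAR
    blob_path = directory / EPOCHS_BLOB
    if not sidecar_path.exists() or not blob_path.exists():
        raise FileNotFoundError(f"no epochs container in {directory}")
    meta = json.loads(sidecar_path.read_text())
    blob = blob_path.read_bytes()
    if hashlib.sha256(blob).hexdigest() != meta["sha256"]:
        raise CorruptionError(f"checksum mismatch for {blob_path}")
    shape = tuple(meta["shape"])
    if len(meta["labels"]) != shape[0]:
        raise FormatError(
            f"sidecar has {len(meta['labels'])} labels for {shape[0]} trials"
        )
    data = np.frombuffer(blob, dtype="<f4").reshape(shape).astype(np.float64)
    return EpochSet(
        data=data,
        labels=np.array(meta["labels"], dtype=object),
        fs=float(meta["fs"]),
        channel_names=list(meta["channel_names"]),
        cue_index=int(meta["cue_index"]),
        provenance=meta.get("provenance", {}),
    )
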