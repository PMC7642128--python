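"""Core containers shared across the pipeline.

The central object is :class:`EpochSet`: a labelled stack of fixed-length
``[trial, channel, sample]`` EEG segments cut around a cue, in microvolts.
All sample indices in the package are 0-based and all windows are half-open
``[a, b)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The two motor-imagery classes handled by the pipeline.
LABELS = ("left", "right")


@dataclass
class EpochSet:
    """Labelled collection of fixed-length channel x time trials.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)`` in microvolts.
    labels
        One label per trial, each ``"left"`` or ``"right"``.
    fs
        Sampling rate in Hz.
    channel_names
        One 10-20 style name per channel (e.g. ``"C3"``).
    cue_index
        Sample index of the cue (t = 0) within each trial.
    provenance
        Free-form metadata (generator config hash, seed, processing history).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    cue_index: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be [trial, channel, sample], got ndim={self.data.ndim}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} trials"
            )
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {LABELS}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 <= self.cue_index < self.data.shape[2]:
            raise ValueError(
                f"cue_index {self.cue_index} outside [0, {self.data.shape[2]})"
            )

    # -- shape accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample time in seconds relative to the cue."""
        return (np.arange(self.n_samples) - self.cue_index) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in montage ({len(self.channel_names)} channels)"
            ) from None

    def select_label(self, label: str) -> "EpochSet":
        """Sub-set of trials with the given class label."""
        if label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {label!r}")
        mask = self.labels == label
        return EpochSet(
            data=self.data[mask],
            labels=self.labels[mask],
            fs=self.fs,
            channel_names=list(self.channel_names),
            cue_index=self.cue_index,
            provenance=dict(self.provenance),
        )

    def class_counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}


def config_hash(obj) -> str:
    """Stable short hash of a configuration-like object.

    Dataclasses, dicts, sequences and scalars are serialised to canonical
    JSON (sorted keys) and hashed with SHA-256; the first 12 hex digits are
    returned.  Used to stamp provenance on generated and derived data.
    """

    def _plain(o):
        if hasattr(o, "__dataclass_fields__"):
            return {k: _plain(getattr(o, k)) for k in o.__dataclass_fields__}
        if isinstance(o, dict):
            return {str(k): _plain(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [_plain(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, float) and np.isinf(o):
            return "inf" if o > 0 else "-inf"
        return o

    blob = json.dumps(_plain(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
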