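"""Core domain types shared by the whole pipeline.

A :class:`Recording` is the package's in-memory representation of a
multichannel EEG recording: a channels x samples matrix in microvolts,
a sampling rate, labelled channels with per-channel roles (``eeg``,
``ecg``, ``cwl``, ``other``), a list of ``(sample_index, label)`` events
(fMRI volume triggers, ECG R-peaks, stimulus markers, ...) and optional
3D sensor positions.  Every processing operation appends one entry to
the provenance log so a recording carries its own history.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace

import numpy as np

CHANNEL_TYPES = ("eeg", "ecg", "cwl", "other")


class RecordingError(ValueError):
    """Raised when a recording violates its structural invariants."""


@dataclass
class Recording:
    data: np.ndarray                      # channels x samples, microvolts
    rate: float                           # Hz
    ch_names: list[str]
    ch_types: list[str] | None = None     # per channel, defaults to "eeg"
    events: list[tuple[int, str]] = field(default_factory=list)
    positions: np.ndarray | None = None   # channels x 3, unit sphere
    meta: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise RecordingError("data must be a channels x samples matrix")
        if self.rate <= 0:
            raise RecordingError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise RecordingError(
                f"{len(self.ch_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            dupes = sorted({n for n in self.ch_names if self.ch_names.count(n) > 1})
            raise RecordingError(f"duplicate channel labels: {dupes}")
        if self.ch_types is None:
            self.ch_types = ["eeg"] * len(self.ch_names)
        if len(self.ch_types) != len(self.ch_names):
            raise RecordingError("ch_types length mismatch")
        for t in self.ch_types:
            if t not in CHANNEL_TYPES:
                raise RecordingError(f"unknown channel type {t!r}")
        n = self.data.shape[1]
        for idx, label in self.events:
            if not (0 <= idx < n):
                raise RecordingError(
                    f"event ({idx}, {label!r}) outside [0, {n})"
                )
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (len(self.ch_names), 3):
                raise RecordingError("positions must be channels x 3")

    # -- convenience -------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel_indices(self, ch_type: str) -> np.ndarray:
        """Indices of channels of a given role, in channel order."""
        return np.array(
            [i for i, t in enumerate(self.ch_types) if t == ch_type], dtype=int
        )

    @property
    def eeg_indices(self) -> np.ndarray:
        return self.channel_indices("eeg")

    def eeg_data(self) -> np.ndarray:
        return self.data[self.eeg_indices]

    def with_data(self, data: np.ndarray, log: str, **changes) -> "Recording":
        """Copy with new data and one appended provenance entry."""
        rec = replace(
            self,
            data=np.asarray(data, dtype=float),
            ch_names=list(changes.pop("ch_names", self.ch_names)),
            ch_types=list(changes.pop("ch_types", self.ch_types)),
            events=list(changes.pop("events", self.events)),
            meta=self.meta + [log],
            **changes,
        )
        return rec

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            ch_names=list(self.ch_names),
            ch_types=list(self.ch_types),
            events=list(self.events),
            positions=None if self.positions is None else self.positions.copy(),
            meta=list(self.meta),
        )


@dataclass
class EventSelection:
    """Sorted, de-duplicated sample indices of events matching a pattern."""

    label_pattern: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise RecordingError("indices must be 1-D")
        if len(self.indices) > 1:
            if np.any(np.diff(self.indices) <= 0):
                raise RecordingError("indices must be strictly ascending")

    def __len__(self) -> int:
        return len(self.indices)


def select_events(rec: Recording, label_pattern: str) -> EventSelection:
    """Select events whose label matches ``label_pattern``.

    The pattern is a shell-style glob (``fnmatch``), so a plain label
    matches exactly and ``"R*"`` matches all labels starting with R.
    Matching indices are returned sorted with duplicates removed; an
    empty selection is allowed.
    """
    idx = sorted(
        {s for s, lab in rec.events if fnmatch.fnmatchcase(lab, label_pattern)}
    )
    return EventSelection(label_pattern=label_pattern, indices=np.array(idx, dtype=int))
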