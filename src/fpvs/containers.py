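"""Core in-memory containers: events, continuous recordings, epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AS_RECORDED = "as-recorded"
AVERAGE = "average"


@dataclass(frozen=True)
class Event:
    """A train-onset marker: sample index plus decoded condition labels."""

    sample: int
    condition: str | None
    stimulus_type: str | None
    code: str = ""


@dataclass
class Recording:
    """Continuous multichannel EEG in µV.

    ``data`` is channels x samples; ``events`` mark train onsets.
    """

    labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    events: list[Event] = field(default_factory=list)
    reference: str = AS_RECORDED

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_channels, n_samples)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        n = self.data.shape[1]
        for ev in self.events:
            if not 0 <= ev.sample < n:
                raise ValueError(f"event sample {ev.sample} out of range")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(),
                       events=list(self.events))


@dataclass
class Epoch:
    """One condition's segment of a recording.

    ``n_cycles`` is None until the epoch has been cropped to an integer
    number of oddball cycles.
    """

    labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    condition: str
    stimulus_type: str
    reference: str = AS_RECORDED
    n_cycles: int | None = None

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_channels, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy(self) -> "Epoch":
        return replace(self, data=self.data.copy())
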