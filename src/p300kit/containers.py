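"""Core data containers shared across the toolkit.

Amplitudes are in microvolts throughout; sample indices are 0-based and
windows are half-open ``[start, stop)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

#: number of distinct flashing stimuli per paradigm
PARADIGM_CODES = {"four_choice": 4, "speller6x6": 12}


class StimulusEvent(NamedTuple):
    onset_sample: int
    code: int
    is_target: bool


@dataclass
class EEGRecording:
    """Continuous multichannel EEG: ``signal`` is (channels, samples) in µV."""

    signal: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (channels, samples) matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.signal.shape[0])]
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class StimulusSchedule:
    """Flash event log: onset sample, stimulus code, target flag per event."""

    onset_sample: np.ndarray
    code: np.ndarray
    is_target: np.ndarray

    def __post_init__(self) -> None:
        self.onset_sample = np.asarray(self.onset_sample, dtype=int)
        self.code = np.asarray(self.code, dtype=int)
        self.is_target = np.asarray(self.is_target, dtype=bool)
        n = len(self.onset_sample)
        if len(self.code) != n or len(self.is_target) != n:
            raise ValueError("schedule columns must have equal length")
        if n and (self.onset_sample < 0).any():
            raise ValueError("onset_sample must be non-negative")

    def __len__(self) -> int:
        return len(self.onset_sample)

    def __iter__(self) -> Iterator[StimulusEvent]:
        for o, c, t in zip(self.onset_sample, self.code, self.is_target):
            yield StimulusEvent(int(o), int(c), bool(t))

    def __getitem__(self, i: int) -> StimulusEvent:
        return StimulusEvent(
            int(self.onset_sample[i]), int(self.code[i]), bool(self.is_target[i])
        )


@dataclass
class GroundTruth:
    """Attended stimulus per selection.

    For ``four_choice`` sessions ``attended`` holds one direction code
    (1..4) per selection.  For ``speller6x6`` it is an ``(n_selections, 2)``
    array of (row code 1..6, column code 7..12): both codes flash as targets
    within every repetition of the selection.
    """

    paradigm: str
    n_repetitions: int
    attended: np.ndarray

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGM_CODES:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        self.attended = np.asarray(self.attended, dtype=int)

    @property
    def n_selections(self) -> int:
        return self.attended.shape[0]

    def target_codes(self, selection: int) -> set[int]:
        if self.paradigm == "four_choice":
            return {int(self.attended[selection])}
        row, col = self.attended[selection]
        return {int(row), int(col)}


@dataclass
class ConfusionCounts:
    """Binary contingency counts for single-trial P300 detection."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=bool)
        yp = np.asarray(y_pred, dtype=bool)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            tp=int(np.sum(yt & yp)),
            tn=int(np.sum(~yt & ~yp)),
            fp=int(np.sum(~yt & yp)),
            fn=int(np.sum(yt & ~yp)),
        )
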