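"""Trial-level preprocessing: epoching, baseline correction, winsorizing
and 1D local-binary-pattern (LBP) symbolization.

The pipeline turns a continuous recording plus its flash schedule into
per-trial symbol sequences.  Stage order is fixed: extract the
[0.1 s, 0.8 s] post-onset window, subtract the mean of its first 50 ms
(local baseline), clip amplitudes to per-channel 1st/99th-percentile
bounds estimated on training data (winsorizing), then symbolize.

The LBP symbolizer slides an onset index along each channel with a step
of 3 samples; the symbol at onset ``j`` is the number of the following
``n`` = 8 samples whose amplitude strictly exceeds the amplitude at
``j``.  Symbols are therefore integers in {0..8}, invariant under any
strictly increasing amplitude transform, and a 168-sample trial yields
54 of them per channel.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .containers import EEGRecording, StimulusEvent, StimulusSchedule

CANONICAL_FS = 240.0


@dataclass
class Trial:
    """One epoch: ``window`` is (channels, T) in µV, time-locked to a flash."""

    window: np.ndarray
    fs: float = CANONICAL_FS
    onset_offset: float = 0.1

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.window.ndim != 2:
            raise ValueError("trial window must be (channels, samples)")

    @property
    def n_channels(self) -> int:
        return self.window.shape[0]

    @property
    def n_samples(self) -> int:
        return self.window.shape[1]


@dataclass
class WinsorThresholds:
    """Per-channel clip bounds (1st/99th percentiles of the training set)."""

    p_low: np.ndarray
    p_high: np.ndarray

    def __post_init__(self) -> None:
        self.p_low = np.atleast_1d(np.asarray(self.p_low, dtype=float))
        self.p_high = np.atleast_1d(np.asarray(self.p_high, dtype=float))
        if self.p_low.shape != self.p_high.shape:
            raise ValueError("p_low and p_high must have the same shape")
        if np.any(self.p_low > self.p_high):
            raise ValueError("p_low must not exceed p_high")

    @property
    def n_channels(self) -> int:
        return len(self.p_low)


@dataclass
class SymbolizedTrialSet:
    """Symbol sequences for a set of trials.

    ``symbols`` has shape (n_trials, L_s, channels) with integer entries in
    {0..n}; ``labels`` carries the per-trial target flags when known.
    """

    symbols: np.ndarray
    n: int = 8
    step: int = 3
    labels: Optional[np.ndarray] = None
    thresholds: Optional[WinsorThresholds] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols)
        if self.symbols.ndim != 3:
            raise ValueError("symbols must be (n_trials, L_s, channels)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if len(self.labels) != len(self.symbols):
                raise ValueError("labels length must match trial count")

    def __len__(self) -> int:
        return len(self.symbols)


def lbp_length(T: int, n: int = 8, step: int = 3) -> int:
    """Number of symbols emitted for a T-sample trial: onsets run over
    {0, step, 2 step, ...} with onset + n <= T - 1."""
    if T < n + 1:
        raise ValueError(f"trial of {T} samples is shorter than n+1={n + 1}")
    return (T - n - 1) // step + 1


def bandpass(recording: EEGRecording, lo: float = 0.1, hi: float = 20.0,
             order: int = 8) -> EEGRecording:
    """Zero-phase Butterworth band-pass; optional when the source is
    pre-filtered by the acquisition device."""
    if not (0 < lo < hi < recording.fs / 2):
        raise ValueError(
            f"band ({lo}, {hi}) Hz invalid for fs={recording.fs}: need 0 < lo < hi < fs/2"
        )
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=recording.fs, output="sos")
    # the low edge implies a very long impulse response; extend the
    # reflection padding accordingly so startup transients stay small
    padlen = min(recording.n_samples - 1, int(3 * recording.fs / lo))
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1, padlen=padlen)
    return EEGRecording(filtered, recording.fs, list(recording.channel_labels))


def resample_to_240(recording: EEGRecording) -> EEGRecording:
    """Reduce a 250 Sa/s recording to the canonical 240 Sa/s (identity at 240)."""
    if recording.fs == CANONICAL_FS:
        return recording
    if recording.fs != 250:
        raise ValueError(f"only 250 Sa/s input is supported, got fs={recording.fs}")
    out = sps.resample_poly(recording.signal, up=24, down=25, axis=1,
                            padtype="mean")
    return EEGRecording(out, CANONICAL_FS, list(recording.channel_labels))


def extract_trial(recording: EEGRecording, event: StimulusEvent,
                  w_start: float = 0.1, w_end: float = 0.8) -> Trial:
    """Half-open window [onset + round(w_start fs), onset + round(w_end fs))."""
    fs = recording.fs
    start = event.onset_sample + int(round(w_start * fs))
    stop = event.onset_sample + int(round(w_end * fs))
    if stop > recording.n_samples:
        raise ValueError(
            f"event at sample {event.onset_sample} (code {event.code}): window "
            f"[{start}, {stop}) exceeds recording length {recording.n_samples}"
        )
    return Trial(recording.signal[:, start:stop].copy(), fs=fs, onset_offset=w_start)


def baseline_correct(trial: Trial, baseline_len: int = 12) -> Trial:
    """Subtract, per channel, the mean of the first ``baseline_len`` samples."""
    if baseline_len <= 0:
        raise ValueError("baseline_len must be positive")
    if baseline_len > trial.n_samples:
        raise ValueError("baseline_len exceeds trial length")
    base = trial.window[:, :baseline_len].mean(axis=1, keepdims=True)
    return Trial(trial.window - base, fs=trial.fs, onset_offset=trial.onset_offset)


def fit_winsor(trials: list[Trial] | np.ndarray) -> WinsorThresholds:
    """1st/99th percentile per channel over all samples of the training trials.

    Percentiles use linear interpolation between order statistics.
    """
    if isinstance(trials, np.ndarray):
        data = np.asarray(trials, dtype=float)
        if data.ndim != 3:
            raise ValueError("array input must be (n_trials, channels, T)")
    else:
        if len(trials) == 0:
            raise ValueError("cannot fit winsor thresholds on an empty training set")
        data = np.stack([t.window for t in trials])
    if data.size == 0:
        raise ValueError("cannot fit winsor thresholds on an empty training set")
    per_channel = data.transpose(1, 0, 2).reshape(data.shape[1], -1)
    if per_channel.shape[1] < 100:
        warnings.warn(
            "fewer than 100 training samples per channel: percentile "
            "estimates are degenerate", stacklevel=2,
        )
    p_low = np.percentile(per_channel, 1, axis=1)
    p_high = np.percentile(per_channel, 99, axis=1)
    return WinsorThresholds(p_low, p_high)


def apply_winsor(trial: Trial, thresholds: WinsorThresholds) -> Trial:
    """Clip each channel to its [p_low, p_high] band (idempotent)."""
    if trial.n_channels != thresholds.n_channels:
        raise ValueError(
            f"trial has {trial.n_channels} channels, thresholds {thresholds.n_channels}"
        )
    clipped = np.clip(trial.window, thresholds.p_low[:, None], thresholds.p_high[:, None])
    return Trial(clipped, fs=trial.fs, onset_offset=trial.onset_offset)


def symbolize_lbp(trial: Trial, n: int = 8, step: int = 3) -> np.ndarray:
    """1D-LBP symbol sequence, shape (L_s, channels), entries in {0..n}.

    The symbol at onset j counts how many of the n samples following j
    strictly exceed the amplitude at j (ties count as 0).
    """
    T = trial.n_samples
    L = lbp_length(T, n, step)
    onsets = np.arange(L) * step
    x = trial.window  # (C, T)
    windows = x[:, onsets[:, None] + np.arange(1, n + 1)]  # (C, L, n)
    ref = x[:, onsets][:, :, None]
    return (windows > ref).sum(axis=2).T.astype(np.int8)  # (L, C)


def preprocess_pipeline(
    recording: EEGRecording,
    schedule: StimulusSchedule,
    thresholds: Optional[WinsorThresholds] = None,
    *,
    w_start: float = 0.1,
    w_end: float = 0.8,
    baseline_len: int = 12,
    n: int = 8,
    step: int = 3,
) -> SymbolizedTrialSet:
    """extract -> baseline -> winsorize -> symbolize, one trial per event.

    When ``thresholds`` is None (training data) the winsor bounds are
    fitted on the baseline-corrected trials of this very set and attached
    to the result for later reuse on test data.
    """
    trials = [
        baseline_correct(extract_trial(recording, ev, w_start, w_end), baseline_len)
        for ev in schedule
    ]
    if thresholds is None:
        thresholds = fit_winsor(trials)
    symbols = np.stack(
        [symbolize_lbp(apply_winsor(t, thresholds), n, step) for t in trials]
    )
    return SymbolizedTrialSet(
        symbols, n=n, step=step, labels=schedule.is_target.copy(),
        thresholds=thresholds,
    )
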