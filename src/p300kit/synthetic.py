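"""Synthetic odd-ball EEG sessions with known ground truth.

Every downstream stage (preprocessing, detector, decision aggregation)
is testable against sessions produced here, with no recorded data needed.
A session emulates either a 4-choice direction paradigm (one of four
stimuli flashes at a time, the attended one is the rare target, 25 %
occurrence) or the classic 6x6 row/column speller (12 codes, the attended
character's row and column are targets, 2/12 occurrence).

Target flashes carry an additive ERP-like deflection: a half-sine of
0.3 s width centred 0.35 s after stimulus onset, strongest over the
posterior channels of the montage.  The background is an order-2
autoregressive noise process band-limited to 0.1-20 Hz.  Optional
large-amplitude excursions emulate movement/blink artifacts and exercise
the winsorizing stage.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from .containers import PARADIGM_CODES, EEGRecording, GroundTruth, StimulusSchedule

# pause after each selection, seconds; matches the paradigm timing used by
# the selection-time analytics (T = 0.5 + 0.7 n_rep and T = 2.5 + 2.1 n_rep)
SELECTION_PAUSE = {"four_choice": 0.5, "speller6x6": 2.5}

TEMPLATE_CENTER_S = 0.35
TEMPLATE_WIDTH_S = 0.30


@dataclass
class SessionSpec:
    """Parameters of one simulated odd-ball session.

    snr is the ratio of the ERP template peak amplitude (on a full-weight
    channel) to the background noise standard deviation; snr=0 produces a
    session with no evoked signal at all.
    """

    paradigm: str = "four_choice"
    n_channels: int = 6
    fs: float = 240.0
    isi: float = 0.175
    flash_duration: float = 0.100
    n_repetitions: int = 2
    n_selections: int = 10
    snr: float = 1.0
    artifact_rate: float = 0.0
    noise_sigma: float = 10.0
    spatial_weights: Optional[np.ndarray] = None
    seed: int = 0

    def validate(self) -> None:
        if self.paradigm not in PARADIGM_CODES:
            raise ValueError(f"paradigm must be one of {sorted(PARADIGM_CODES)}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (0 < self.flash_duration <= self.isi):
            raise ValueError("flash_duration must satisfy 0 < flash_duration <= isi")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if not (0 <= self.artifact_rate <= 1):
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.n_channels < 1:
            raise ValueError("n_channels must be at least 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be at least 1")
        if self.n_selections < 1:
            raise ValueError("n_selections must be at least 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def resolved_weights(self) -> np.ndarray:
        """Per-channel template scaling; posterior-dominant by default."""
        if self.spatial_weights is not None:
            w = np.asarray(self.spatial_weights, dtype=float)
            if w.shape != (self.n_channels,):
                raise ValueError("spatial_weights must have length n_channels")
            return w
        w = np.full(self.n_channels, 0.4)
        w[-min(3, self.n_channels):] = 1.0
        return w


def erp_template(fs: float, length: int) -> np.ndarray:
    """Half-sine deflection with unit peak, sampled on ``length`` samples
    relative to the stimulus onset."""
    t = np.arange(length) / fs
    lo = TEMPLATE_CENTER_S - TEMPLATE_WIDTH_S / 2
    inside = (t >= lo) & (t <= lo + TEMPLATE_WIDTH_S)
    out = np.zeros(length)
    out[inside] = np.sin(np.pi * (t[inside] - lo) / TEMPLATE_WIDTH_S)
    return np.maximum(out, 0.0)


def _colored_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                   fs: float, sigma: float) -> np.ndarray:
    """1/f-style AR(2) noise band-limited to 0.1-20 Hz, std ``sigma``.

    Poles at 0.9 and 0.8 give a pink-noise-like power spectrum falling
    roughly as 1/f^2 across the 2-20 Hz band, the standard surrogate for
    resting EEG background activity.
    """
    pad = int(fs)  # discard AR burn-in
    white = rng.standard_normal((n_channels, n_samples + pad))
    ar = sps.lfilter([1.0], [1.0, -1.7, 0.72], white, axis=1)[:, pad:]
    hi = min(20.0, 0.45 * fs)
    sos = sps.butter(4, [0.1, hi], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, ar, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std * sigma


def generate_session(
    spec: SessionSpec,
) -> Tuple[EEGRecording, StimulusSchedule, GroundTruth]:
    """Simulate one session: continuous EEG, flash schedule and ground truth.

    Flash order is randomized independently within every repetition block,
    so the target occurrence probability per flash is exactly 1/4
    (four_choice) or 2/12 (speller6x6).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_codes = PARADIGM_CODES[spec.paradigm]
    fs = spec.fs

    isi_samp = int(round(spec.isi * fs))
    pause_samp = int(round(SELECTION_PAUSE[spec.paradigm] * fs))

    onsets, codes, flags = [], [], []
    attended = []
    cursor = 0
    for _ in range(spec.n_selections):
        if spec.paradigm == "four_choice":
            att = int(rng.integers(1, n_codes + 1))
            target_set = {att}
            attended.append(att)
        else:
            row = int(rng.integers(1, 7))
            col = int(rng.integers(7, 13))
            target_set = {row, col}
            attended.append((row, col))
        for _ in range(spec.n_repetitions):
            order = rng.permutation(n_codes) + 1
            for code in order:
                onsets.append(cursor)
                codes.append(int(code))
                flags.append(int(code) in target_set)
                cursor += isi_samp
        cursor += pause_samp

    onsets = np.asarray(onsets, dtype=int)
    n_samples = int(onsets[-1] + round(1.0 * fs))
    noise = _colored_noise(rng, spec.n_channels, n_samples, fs, spec.noise_sigma)

    template_len = int(round(0.8 * fs))
    template = erp_template(fs, template_len)
    weights = spec.resolved_weights()
    peak = spec.snr * spec.noise_sigma

    signal = noise
    for onset, is_target in zip(onsets, flags):
        stop = min(onset + template_len, n_samples)
        seg = slice(onset, stop)
        if is_target and peak > 0:
            signal[:, seg] += peak * weights[:, None] * template[: stop - onset]
        if spec.artifact_rate > 0 and rng.random() < spec.artifact_rate:
            ch = int(rng.integers(spec.n_channels))
            center = onset + int(rng.integers(template_len))
            amp = 8.0 * spec.noise_sigma * (1 if rng.random() < 0.5 else -1)
            width = 0.05 * fs
            t = np.arange(n_samples)
            bump = amp * np.exp(-0.5 * ((t - center) / width) ** 2)
            signal[ch] += bump

    recording = EEGRecording(signal=signal, fs=fs)
    schedule = StimulusSchedule(onsets, np.asarray(codes), np.asarray(flags))
    truth = GroundTruth(
        paradigm=spec.paradigm,
        n_repetitions=spec.n_repetitions,
        attended=np.asarray(attended),
    )
    return recording, schedule, truth


def event_counts(schedule: StimulusSchedule, truth: GroundTruth) -> Tuple[int, int]:
    """(n_target, n_nontarget) for a schedule, validated against the truth."""
    n_codes = PARADIGM_CODES[truth.paradigm]
    expected = truth.n_selections * truth.n_repetitions * n_codes
    if len(schedule) != expected:
        raise ValueError(
            f"schedule has {len(schedule)} events but ground truth implies {expected}"
        )
    n_target = int(schedule.is_target.sum())
    return n_target, len(schedule) - n_target


def spec_to_dict(spec: SessionSpec) -> dict:
    d = dataclasses.asdict(spec)
    if d["spatial_weights"] is not None:
        d["spatial_weights"] = [float(x) for x in d["spatial_weights"]]
    return d
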