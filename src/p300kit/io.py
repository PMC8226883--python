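"""File I/O: tab-delimited event logs, recording containers, YAML configs
and detector serialization.

Recordings are stored as a compressed numpy array container with a YAML
sidecar carrying the sampling rate and channel labels; events, decisions
and reports travel as tab-delimited text so every artifact of a run is
inspectable with standard tools.
"""
from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
import yaml

from .containers import EEGRecording, GroundTruth, StimulusSchedule
from .model import NetworkConfig, P300Detector
from .preprocessing import WinsorThresholds

EVENT_COLUMNS = ["onset_sample", "code", "is_target"]


def write_events(schedule: StimulusSchedule, path: str | Path) -> None:
    df = pd.DataFrame({
        "onset_sample": schedule.onset_sample,
        "code": schedule.code,
        "is_target": schedule.is_target.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> StimulusSchedule:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse event file {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file {path} lacks columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        if row.onset_sample < 0:
            raise ValueError(f"{path}:{i}: negative onset_sample {row.onset_sample}")
        if row.is_target not in (0, 1):
            raise ValueError(f"{path}:{i}: is_target must be 0 or 1")
    return StimulusSchedule(
        df["onset_sample"].to_numpy(int),
        df["code"].to_numpy(int),
        df["is_target"].to_numpy(bool),
    )


def save_recording(recording: EEGRecording, path: str | Path) -> None:
    """Write ``<path>.npz`` (signal) and ``<path>.yaml`` (fs, labels)."""
    base = Path(path)
    np.savez_compressed(base.with_suffix(".npz"), signal=recording.signal)
    meta = {"fs": float(recording.fs), "channel_labels": list(recording.channel_labels)}
    base.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_recording(path: str | Path) -> EEGRecording:
    base = Path(path)
    with np.load(base.with_suffix(".npz")) as data:
        signal = data["signal"]
    meta = yaml.safe_load(base.with_suffix(".yaml").read_text())
    return EEGRecording(signal, float(meta["fs"]), list(meta["channel_labels"]))


def save_truth(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "paradigm": truth.paradigm,
        "n_repetitions": int(truth.n_repetitions),
        "attended": truth.attended.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(doc))


def load_truth(path: str | Path) -> GroundTruth:
    doc = yaml.safe_load(Path(path).read_text())
    return GroundTruth(doc["paradigm"], int(doc["n_repetitions"]),
                       np.asarray(doc["attended"]))


def save_thresholds(thresholds: WinsorThresholds, path: str | Path) -> None:
    doc = {"p_low": thresholds.p_low.tolist(), "p_high": thresholds.p_high.tolist()}
    Path(path).write_text(yaml.safe_dump(doc))


def load_thresholds(path: str | Path) -> WinsorThresholds:
    doc = yaml.safe_load(Path(path).read_text())
    return WinsorThresholds(np.asarray(doc["p_low"]), np.asarray(doc["p_high"]))


def save_detector(detector: P300Detector, path: str | Path) -> None:
    """Self-describing weights container (.npz) with embedded YAML config."""
    arrays = {f"ae_{i}": a for i, a in enumerate(detector.ae.state())}
    arrays.update({f"head_{i}": a for i, a in enumerate(detector.head.state())})
    arrays["scaler_mean"] = detector.scaler_mean
    arrays["scaler_std"] = detector.scaler_std
    cfg = yaml.safe_dump(detector.config.__dict__ | {
        "ae_units": list(detector.config.ae_units),
        "dense_units": list(detector.config.dense_units),
    })
    np.savez_compressed(Path(path), config=np.frombuffer(cfg.encode(), dtype=np.uint8),
                        **arrays)


def load_detector(path: str | Path) -> P300Detector:
    with np.load(Path(path)) as data:
        cfg_doc = yaml.safe_load(bytes(data["config"]).decode())
        cfg_doc["ae_units"] = tuple(cfg_doc["ae_units"])
        cfg_doc["dense_units"] = tuple(cfg_doc["dense_units"])
        detector = P300Detector(NetworkConfig(**cfg_doc))
        for i, a in enumerate(detector.ae.state()):
            a[...] = data[f"ae_{i}"]
        for i, a in enumerate(detector.head.state()):
            a[...] = data[f"head_{i}"]
        detector.scaler_mean = data["scaler_mean"]
        detector.scaler_std = data["scaler_std"]
    detector.ae_frozen = True
    return detector


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan a single global seed out to n deterministic sub-seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def session_paths(outdir: str | Path) -> Tuple[Path, Path, Path]:
    out = Path(outdir)
    return out / "recording", out / "events.tsv", out / "truth.yaml"
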