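"""Offline recursive channel elimination.

Starting from the full montage, each round removes the channel whose
elimination yields the highest selection criterion

    criterion = TP / (TP + FP + FN)

computed from a provisional classifier's validation confusion counts on
the remaining channels, until ``stop_at`` channels survive.  The
provisional classifier is pluggable: any callable
``factory(features, labels, seed) -> ConfusionCounts`` works, where
``features`` is (n_trials, L, n_channels_subset).  Two factories ship
with the module: a regularized logistic regression on flattened symbol
vectors (fast, used for large candidate scans) and the detector's own
CNN head without the autoencoder branch.

A cross-subject step then ranks channels by how often they appear in the
per-subject surviving sets, breaking ties by how late in the elimination
they were removed (later removal = more informative).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .containers import ConfusionCounts
from .model import NetworkConfig, P300Detector
from . import nnet

ClassifierFactory = Callable[[np.ndarray, np.ndarray, int], ConfusionCounts]


def criterion(counts: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); 0 when the denominator is 0."""
    denom = counts.tp + counts.fp + counts.fn
    return counts.tp / denom if denom else 0.0


@dataclass
class EliminationTrace:
    """Record of one backward-elimination run."""

    rounds: list[tuple[int, float]] = field(default_factory=list)  # (removed, criterion)
    surviving: list[list[int]] = field(default_factory=list)       # after each round

    @property
    def final_channels(self) -> list[int]:
        return self.surviving[-1] if self.surviving else []

    def removal_round(self, channel: int, n_channels: int) -> int:
        """1-based round at which ``channel`` was removed; survivors get
        ``n_rounds + 1`` (the best possible value)."""
        for i, (removed, _) in enumerate(self.rounds):
            if removed == channel:
                return i + 1
        return len(self.rounds) + 1


def logistic_factory(features: np.ndarray, labels: np.ndarray, seed: int) -> ConfusionCounts:
    """Provisional classifier: standardized logistic regression, 70/30 holdout."""
    X = np.asarray(features, dtype=float).reshape(len(features), -1)
    y = np.asarray(labels).astype(int).ravel()
    Xtr, Xva, ytr, yva = train_test_split(
        X, y, test_size=0.30, random_state=seed, stratify=y
    )
    scaler = StandardScaler().fit(Xtr)
    clf = LogisticRegression(max_iter=300, C=0.1)
    clf.fit(scaler.transform(Xtr), ytr)
    pred = clf.predict(scaler.transform(Xva))
    return ConfusionCounts.from_labels(yva, pred)


def cnn_factory(features: np.ndarray, labels: np.ndarray, seed: int,
                epochs: int = 30) -> ConfusionCounts:
    """Provisional classifier: the detector's sequential head alone (batch
    norm, temporal conv, dense stack) on the raw feature tensor, without
    the autoencoder branch."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(float).ravel()
    N, L, C = X.shape
    mean, std = X.mean(axis=(0, 1)), X.std(axis=(0, 1))
    std[std == 0] = 1.0
    X = (X - mean) / std
    cfg = NetworkConfig(channels=C, symbols_per_channel=L,
                        conv_kernel=min(8, L), conv_stride=min(8, L))
    det = P300Detector(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    det.set_dropout_rng(rng)
    idx = rng.permutation(N)
    n_val = max(1, int(round(0.30 * N)))
    va, tr = idx[:n_val], idx[n_val:]
    opt = nnet.Adam(lr=1e-3)
    for _ in range(epochs):
        order = rng.permutation(len(tr))
        for i in range(0, len(order), 64):
            mb = tr[order[i: i + 64]]
            logits = det.head.forward(X[mb], train=True)
            _, grad = nnet.bce_with_logits(logits, y[mb])
            det.head.backward(grad)
            opt.step(det.head.params(), det.head.grads())
    probs = nnet.sigmoid(det.head.forward(X[va], train=False).ravel())
    return ConfusionCounts.from_labels(y[va] > 0.5, probs > 0.5)


def recursive_elimination(
    features: np.ndarray,
    labels: np.ndarray,
    classifier_factory: ClassifierFactory = logistic_factory,
    stop_at: int = 10,
    seed: int = 0,
) -> EliminationTrace:
    """Greedy backward elimination down to ``stop_at`` channels.

    ``features`` is (n_trials, L, n_channels).  Each round evaluates the
    criterion once per candidate removal and discards the channel whose
    removal scores highest (ties: lowest channel index removed).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 3:
        raise ValueError("features must be (n_trials, L, n_channels)")
    channels = list(range(X.shape[2]))
    if len(channels) <= stop_at:
        raise ValueError(
            f"need more than stop_at={stop_at} channels, got {len(channels)}"
        )
    trace = EliminationTrace()
    while len(channels) > stop_at:
        best_score, best_ch = -1.0, None
        for ch in channels:
            remaining = [c for c in channels if c != ch]
            try:
                counts = classifier_factory(X[:, :, remaining], labels, seed)
            except Exception as exc:  # surface the round context
                raise RuntimeError(
                    f"provisional classifier failed removing channel {ch} "
                    f"(round {len(trace.rounds) + 1})"
                ) from exc
            score = criterion(counts)
            if score > best_score:
                best_score, best_ch = score, ch
        channels = [c for c in channels if c != best_ch]
        trace.rounds.append((best_ch, best_score))
        trace.surviving.append(list(channels))
    return trace


def cross_subject_select(
    traces: Sequence[EliminationTrace], n_final: int = 6,
    n_channels: int | None = None,
) -> list[int]:
    """Channels ranked by (membership count in per-subject surviving sets,
    then mean removal round — later is better), top ``n_final`` returned."""
    if not traces:
        raise ValueError("need at least one elimination trace")
    if n_channels is None:
        n_channels = 1 + max(
            max((c for s in t.surviving for c in s), default=0)
            for t in traces
        )
        n_channels = max(
            n_channels,
            1 + max(max((r for r, _ in t.rounds), default=0) for t in traces),
        )
    membership = np.zeros(n_channels)
    mean_round = np.zeros(n_channels)
    for t in traces:
        final = set(t.final_channels)
        for ch in range(n_channels):
            membership[ch] += ch in final
            mean_round[ch] += t.removal_round(ch, n_channels)
    mean_round /= len(traces)
    order = sorted(
        range(n_channels), key=lambda ch: (-membership[ch], -mean_round[ch], ch)
    )
    return order[:n_final]
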