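"""Class rebalancing for P300 trial sets.

Odd-ball sessions are intrinsically imbalanced (1 target : 3 non-targets
in a 4-choice paradigm, 1 : 5 in the 6x6 speller).  Training data are
rebalanced in two stages: NearMiss-2 undersampling of the majority class
down to a configurable majority:minority ratio, followed by random
duplication of minority samples up to exact parity.  NearMiss-2 retains
the majority samples whose average Euclidean distance to their k
FARTHEST minority samples is smallest — majority points that sit deep
inside the majority cloud, far from every minority point, are dropped
first.  No feature vector is ever fabricated: every output row is a row
of the input.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class ResampleConfig:
    nearmiss_k: int = 3
    target_ratio_after_undersample: float = 2.0  # majority : minority
    seed: int = 0

    def validate(self) -> None:
        if self.nearmiss_k < 1:
            raise ValueError("nearmiss_k must be >= 1")
        if self.target_ratio_after_undersample < 1:
            raise ValueError("undersample ratio must be >= 1")


def _flatten(features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    return X.reshape(len(X), -1)


def _classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels).astype(bool).ravel()
    minority, majority = np.flatnonzero(y), np.flatnonzero(~y)
    if len(minority) > len(majority):
        minority, majority = majority, minority
    return minority, majority


def nearmiss2_undersample(features, labels, cfg: ResampleConfig | None = None):
    """Reduce the majority class by the NearMiss-2 rule.

    Deterministic given inputs and config; ties in the average-distance
    ranking are broken by original index order.  Returns
    (features, labels, kept_indices) with minority rows untouched.
    """
    cfg = cfg or ResampleConfig()
    cfg.validate()
    X = _flatten(features)
    y = np.asarray(labels).astype(bool).ravel()
    minority, majority = _classes(y)
    if len(minority) == 0:
        raise ValueError("minority class is empty")
    n_keep = int(np.ceil(cfg.target_ratio_after_undersample * len(minority)))
    if len(majority) <= n_keep:
        kept = np.arange(len(y))
    else:
        d = cdist(X[majority], X[minority])  # (n_maj, n_min)
        k = min(cfg.nearmiss_k, len(minority))
        farthest = np.sort(d, axis=1)[:, -k:]
        score = farthest.mean(axis=1)
        keep_maj = majority[np.argsort(score, kind="stable")[:n_keep]]
        kept = np.sort(np.concatenate([minority, keep_maj]))
    feats = np.asarray(features)
    return feats[kept], y[kept], kept


def random_oversample(features, labels, cfg: ResampleConfig | None = None):
    """Duplicate minority samples uniformly at random (with replacement)
    until the classes are at exact parity.  Returns
    (features, labels, source_indices): every output row's index in the
    input, duplicates included."""
    cfg = cfg or ResampleConfig()
    y = np.asarray(labels).astype(bool).ravel()
    minority, majority = _classes(y)
    if len(minority) == 0 or len(minority) == len(majority):
        idx = np.arange(len(y))
    else:
        rng = np.random.default_rng(cfg.seed)
        extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
        idx = np.concatenate([np.arange(len(y)), extra])
    feats = np.asarray(features)
    return feats[idx], y[idx], idx


def rebalance(features, labels, cfg: ResampleConfig | None = None):
    """NearMiss-2 to the intermediate ratio, then oversample to 1:1.

    Returns (features, labels, audit) where ``audit`` records the kept
    majority indices and the duplicated minority indices (both relative
    to the original input).
    """
    cfg = cfg or ResampleConfig()
    Xu, yu, kept = nearmiss2_undersample(features, labels, cfg)
    Xb, yb, src = random_oversample(Xu, yu, cfg)
    audit = {"kept": kept, "source": kept[src]}
    return Xb, yb, audit
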