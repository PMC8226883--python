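"""Single-trial classification metrics and BCI speed analytics.

Metrics follow the standard contingency-table definitions, reported as
percentages:

    precision = 100 TP/(TP+FP)      recall = 100 TP/(TP+FN)
    accuracy  = 100 (TP+TN)/total   F1 = 100 * 2TP/(2TP+FP+FN)

The information transfer rate uses the Wolpaw formula

    ITR = 60/T * [ P log2 P + (1-P) log2((1-P)/(N-1)) + log2 N ]  bits/min

with N classes, selection accuracy P and selection time T seconds.  The
selection time includes the paradigm's flash train and post-selection
pause: T = 0.5 + 0.7 n_rep for the 4-choice paradigm and
T = 2.5 + 2.1 n_rep for the 6x6 speller.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ConfusionCounts

SELECTION_TIME = {  # (fixed pause s, seconds per repetition)
    "four_choice": (0.5, 0.7),
    "speller6x6": (2.5, 2.1),
}


@dataclass
class MetricsReport:
    """Percentages in [0, 100]."""

    precision: float
    recall: float
    accuracy: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
        }


@dataclass
class ITRSpec:
    P: float       # selection accuracy in [0, 1]
    N: int         # number of selectable classes
    T: float       # seconds per selection
    n_rep: int = 1

    def validate(self) -> None:
        if not (0 <= self.P <= 1):
            raise ValueError("P must lie in [0, 1]")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.T <= 0:
            raise ValueError("T must be positive")


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} is 0/0; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Precision/recall/accuracy/F1 (%) from contingency counts."""
    if counts.total == 0:
        raise ValueError("empty contingency table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    return MetricsReport(
        precision=100 * _ratio(tp, tp + fp, "precision"),
        recall=100 * _ratio(tp, tp + fn, "recall"),
        accuracy=100 * (tp + tn) / counts.total,
        f1=100 * _ratio(2 * tp, 2 * tp + fp + fn, "F1"),
    )


def selection_time(paradigm: str, n_rep: int) -> float:
    """Seconds per selection, including the post-selection pause."""
    if paradigm not in SELECTION_TIME:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if n_rep <= 0:
        raise ValueError("n_rep must be positive")
    limits = {"four_choice": 2, "speller6x6": 15}
    if n_rep > limits[paradigm]:
        warnings.warn(
            f"n_rep={n_rep} outside the nominal range for {paradigm}", stacklevel=2
        )
    base, per_rep = SELECTION_TIME[paradigm]
    return base + per_rep * n_rep


def itr(spec: ITRSpec) -> float:
    """Information transfer rate in bits/min.

    Limits are handled analytically: P=1 gives 60 log2(N)/T, P=0 gives
    60 log2(N/(N-1))/T, and chance level P=1/N gives exactly 0 (values
    within numerical noise of zero are snapped to it).
    """
    spec.validate()
    P, N = spec.P, spec.N
    if P == 1.0:
        bits = math.log2(N)
    elif P == 0.0:
        bits = math.log2(N / (N - 1))
    else:
        bits = P * math.log2(P) + (1 - P) * math.log2((1 - P) / (N - 1)) + math.log2(N)
        if abs(bits) < 1e-12:
            bits = 0.0
    return 60.0 * bits / spec.T


def aggregate(reports: list[MetricsReport]) -> dict:
    """Mean and (n-1)-denominator standard deviation of each metric.

    A single report yields its own values with sd reported as 0 and
    ``sd_defined`` False.
    """
    if not reports:
        raise ValueError("need at least one report")
    out: dict = {"n": len(reports), "sd_defined": len(reports) > 1}
    for key in ("precision", "recall", "accuracy", "f1"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[key] = {"mean": float(vals.mean()), "sd": sd}
    return out


def itr_from_counts(paradigm: str, accuracy: float, n_rep: int) -> float:
    """Convenience: ITR at a paradigm's class count and selection time."""
    N = 4 if paradigm == "four_choice" else 36
    return itr(ITRSpec(P=accuracy, N=N, T=selection_time(paradigm, n_rep), n_rep=n_rep))
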