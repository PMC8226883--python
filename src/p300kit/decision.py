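"""Paradigm-level decision aggregation.

Single-trial detector outputs are grouped per selection (one direction
choice or one speller character epoch) and aggregated by maximum
occurrence: the stimulus code with the most positive single-trial labels
wins.  Ties are broken by the highest summed probability, then by the
lowest code.  A speller character is the intersection of the winning row
(codes 1-6) and the winning column (codes 7-12), so the 36-way decision
reduces to two independent 6-way ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import PARADIGM_CODES, GroundTruth, StimulusSchedule

DEFAULT_GRID = [
    "ABCDEF",
    "GHIJKL",
    "MNOPQR",
    "STUVWX",
    "YZ1234",
    "56789_",
]


@dataclass
class SpellerMatrix:
    """6x6 character grid; rows flash as codes 1-6, columns as codes 7-12."""

    grid: list[str] = field(default_factory=lambda: list(DEFAULT_GRID))

    def __post_init__(self) -> None:
        if len(self.grid) != 6 or any(len(r) != 6 for r in self.grid):
            raise ValueError("grid must be 6 rows of 6 characters")
        chars = "".join(self.grid)
        if len(set(chars)) != 36:
            raise ValueError("grid characters must be distinct")

    def char(self, row_code: int, col_code: int) -> str:
        if not (1 <= row_code <= 6 and 7 <= col_code <= 12):
            raise ValueError(f"invalid (row, col) codes ({row_code}, {col_code})")
        return self.grid[row_code - 1][col_code - 7]


@dataclass
class SelectionBlock:
    """Detector outputs for the flashes of one selection, in flash order."""

    codes: np.ndarray
    probs: np.ndarray
    labels: np.ndarray
    n_rep: int
    paradigm: str = "four_choice"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.codes) == len(self.probs) == len(self.labels)):
            raise ValueError("codes, probs and labels must be aligned")
        n_codes = PARADIGM_CODES[self.paradigm]
        if len(self.codes) != n_codes * self.n_rep:
            raise ValueError(
                f"{self.paradigm} block needs {n_codes}*{self.n_rep} events, "
                f"got {len(self.codes)}"
            )

    def truncate(self, n_rep: int) -> "SelectionBlock":
        """First ``n_rep`` repetitions only (flash order is by repetition)."""
        if n_rep > self.n_rep:
            raise ValueError(f"block holds {self.n_rep} repetitions, asked {n_rep}")
        k = PARADIGM_CODES[self.paradigm] * n_rep
        return SelectionBlock(self.codes[:k], self.probs[:k], self.labels[:k],
                              n_rep, self.paradigm)


def _vote(codes: Sequence[int], block: SelectionBlock, use_probabilities: bool) -> int:
    occ = {c: 0 for c in codes}
    sump = {c: 0.0 for c in codes}
    for c, p, l in zip(block.codes, block.probs, block.labels):
        if c in occ:
            occ[c] += int(l)
            sump[c] += p
    if not any(c in occ for c in block.codes):
        raise ValueError(f"block contains no events for codes {list(codes)}")
    if use_probabilities:
        return min(codes, key=lambda c: (-sump[c], c))
    return min(codes, key=lambda c: (-occ[c], -sump[c], c))


def decide_direction(block: SelectionBlock, use_probabilities: bool = False) -> int:
    """Winning direction of a 4-choice block by maximum occurrence of
    positive labels; ties by summed probability, then lowest code.  With
    ``use_probabilities`` the accumulated probabilities decide directly."""
    if len(block.codes) == 0:
        raise ValueError("empty selection block")
    return _vote(range(1, 5), block, use_probabilities)


def decide_character(block: SelectionBlock, matrix: Optional[SpellerMatrix] = None,
                     use_probabilities: bool = False) -> str:
    """Speller character: winning row (codes 1-6) x winning column (7-12)."""
    matrix = matrix or SpellerMatrix()
    row = _vote(range(1, 7), block, use_probabilities)
    col = _vote(range(7, 13), block, use_probabilities)
    return matrix.char(row, col)


def blocks_from_session(
    schedule: StimulusSchedule,
    truth: GroundTruth,
    probs: np.ndarray,
    labels: np.ndarray,
) -> list[SelectionBlock]:
    """Split per-event detector outputs into per-selection blocks."""
    n_codes = PARADIGM_CODES[truth.paradigm]
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    per_sel = n_codes * truth.n_repetitions
    expected = per_sel * truth.n_selections
    if not (len(schedule) == len(probs) == len(labels) == expected):
        raise ValueError("schedule, outputs and truth are not aligned")
    blocks = []
    for s in range(truth.n_selections):
        sl = slice(s * per_sel, (s + 1) * per_sel)
        blocks.append(
            SelectionBlock(schedule.code[sl], probs[sl], labels[sl],
                           truth.n_repetitions, truth.paradigm)
        )
    return blocks


def _truth_answer(truth: GroundTruth, s: int, matrix: SpellerMatrix):
    if truth.paradigm == "four_choice":
        return int(truth.attended[s])
    row, col = truth.attended[s]
    return matrix.char(int(row), int(col))


def decide_session(blocks: Sequence[SelectionBlock], truth: GroundTruth,
                   matrix: Optional[SpellerMatrix] = None,
                   use_probabilities: bool = False) -> tuple[list, float]:
    """Decisions for every selection and the fraction that is correct."""
    matrix = matrix or SpellerMatrix()
    decisions, correct = [], 0
    for s, block in enumerate(blocks):
        if truth.paradigm == "four_choice":
            d = decide_direction(block, use_probabilities)
        else:
            d = decide_character(block, matrix, use_probabilities)
        decisions.append(d)
        correct += d == _truth_answer(truth, s, matrix)
    return decisions, correct / len(blocks) if blocks else 0.0


def accuracy_vs_repetitions(
    blocks: Sequence[SelectionBlock], truth: GroundTruth, n_rep_max: int,
    matrix: Optional[SpellerMatrix] = None, use_probabilities: bool = False,
) -> np.ndarray:
    """Selection accuracy when only the first r repetitions are used,
    for r = 1..n_rep_max; each r is decided from scratch."""
    if any(b.n_rep < n_rep_max for b in blocks):
        raise ValueError("n_rep_max exceeds the repetitions available in a block")
    out = np.empty(n_rep_max)
    for r in range(1, n_rep_max + 1):
        trunc = [b.truncate(r) for b in blocks]
        _, acc = decide_session(trunc, truth, matrix, use_probabilities)
        out[r - 1] = acc
    return out
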