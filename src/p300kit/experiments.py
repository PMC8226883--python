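"""End-to-end synthetic studies: session -> symbols -> detector -> decision.

These functions wire the full pipeline together under controlled
conditions and are what the verification suite and the example scripts
run.  Rebalancing (NearMiss-2 + oversampling) is applied to training
data only; evaluation sets are never resampled with duplication, so
holdout scores are leakage-free.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ConfusionCounts
from .decision import SpellerMatrix, accuracy_vs_repetitions, blocks_from_session
from .evaluation import MetricsReport, metrics
from .imbalance import ResampleConfig, rebalance
from .model import TrainConfig, build_detector, predict, train_autoencoder, train_classifier
from .preprocessing import preprocess_pipeline
from .synthetic import SessionSpec, generate_session


def balanced_trial_set(paradigm: str, n_total: int, snr: float, seed: int,
                       artifact_rate: float = 0.0):
    """A class-balanced symbol set of ``n_total`` distinct trials.

    Generates a session large enough to supply n_total/2 target trials,
    then subsamples the majority class without replacement — no trial is
    duplicated, so any split of the result is leakage-free.
    """
    n_half = n_total // 2
    n_codes = 4 if paradigm == "four_choice" else 12
    targets_per_sel = 1 if paradigm == "four_choice" else 2
    n_rep = 2
    n_sel = int(np.ceil(n_half / (targets_per_sel * n_rep)))
    spec = SessionSpec(paradigm=paradigm, n_repetitions=n_rep, n_selections=n_sel,
                       snr=snr, artifact_rate=artifact_rate, seed=seed)
    recording, schedule, _ = generate_session(spec)
    sts = preprocess_pipeline(recording, schedule)
    rng = np.random.default_rng(seed + 1)
    pos = np.flatnonzero(sts.labels)
    neg = np.flatnonzero(~sts.labels)
    pos = rng.choice(pos, size=n_half, replace=False)
    neg = rng.choice(neg, size=n_half, replace=False)
    idx = rng.permutation(np.concatenate([pos, neg]))
    return sts.symbols[idx], sts.labels[idx]


@dataclass
class SingleTrialResult:
    report: MetricsReport
    counts: ConfusionCounts
    n_train: int
    n_holdout: int


def single_trial_experiment(snr: float, n_trials: int = 2000, seed: int = 0,
                            holdout_fraction: float = 0.3,
                            tc: TrainConfig | None = None) -> SingleTrialResult:
    """Train the detector on a balanced 4-choice set and score a clean holdout.

    The holdout fraction is carved off before training; the detector never
    sees those trials in either phase.
    """
    X, y = balanced_trial_set("four_choice", n_trials, snr, seed)
    n_hold = int(round(holdout_fraction * len(y)))
    Xh, yh = X[:n_hold], y[:n_hold]
    Xt, yt = X[n_hold:], y[n_hold:]
    tc = tc or TrainConfig(seed=seed)
    detector = build_detector(seed=seed)
    train_autoencoder(detector, Xt, tc)
    train_classifier(detector, Xt, yt, tc)
    _, labels = predict(detector, Xh)
    counts = ConfusionCounts.from_labels(yh, labels)
    return SingleTrialResult(metrics(counts), counts, len(yt), len(yh))


def planted_channel_recovery(n_channels: int = 14, n_informative: int = 6,
                             stop_at: int = 10, snr: float = 1.5,
                             n_selections: int = 200, seed: int = 0) -> bool:
    """One recursive-elimination run on a montage where only the last
    ``n_informative`` channels carry the evoked response; True when all
    informative channels survive to the final ``stop_at``."""
    from .channel_selection import logistic_factory, recursive_elimination

    weights = np.zeros(n_channels)
    informative = list(range(n_channels - n_informative, n_channels))
    weights[informative] = 1.0
    spec = SessionSpec(paradigm="four_choice", n_channels=n_channels,
                       n_repetitions=2, n_selections=n_selections, snr=snr,
                       spatial_weights=weights, seed=seed)
    recording, schedule, _ = generate_session(spec)
    sts = preprocess_pipeline(recording, schedule)
    trace = recursive_elimination(sts.symbols, sts.labels, logistic_factory,
                                  stop_at=stop_at, seed=seed)
    return set(informative) <= set(trace.final_channels)


@dataclass
class SpellerResult:
    detector_report: MetricsReport
    character_accuracy: float
    accuracy_by_repetition: np.ndarray
    n_characters: int


def speller_recovery_experiment(snr: float = 3.0, n_train_selections: int = 10,
                                n_test_characters: int = 40, n_rep: int = 15,
                                seed: int = 0,
                                tc: TrainConfig | None = None) -> SpellerResult:
    """Full speller study: train on one session, spell characters in another.

    Training trials are rebalanced (NearMiss-2 then random oversampling);
    the test session is preprocessed with the training winsor thresholds
    and left untouched.  Character decisions accumulate the first r
    repetitions for r = 1..n_rep.
    """
    train_spec = SessionSpec(paradigm="speller6x6", n_repetitions=n_rep,
                             n_selections=n_train_selections, snr=snr, seed=seed)
    rec_tr, sched_tr, _ = generate_session(train_spec)
    sts_tr = preprocess_pipeline(rec_tr, sched_tr)
    Xb, yb, _ = rebalance(sts_tr.symbols, sts_tr.labels, ResampleConfig(seed=seed))

    tc = tc or TrainConfig(seed=seed)
    detector = build_detector(seed=seed)
    train_autoencoder(detector, Xb, tc)
    train_classifier(detector, Xb, yb, tc)

    test_spec = SessionSpec(paradigm="speller6x6", n_repetitions=n_rep,
                            n_selections=n_test_characters, snr=snr, seed=seed + 1)
    rec_te, sched_te, truth_te = generate_session(test_spec)
    sts_te = preprocess_pipeline(rec_te, sched_te, sts_tr.thresholds)
    probs, labels = predict(detector, sts_te)
    report = metrics(ConfusionCounts.from_labels(sts_te.labels, labels))

    blocks = blocks_from_session(sched_te, truth_te, probs, labels)
    acc_by_rep = accuracy_vs_repetitions(blocks, truth_te, n_rep, SpellerMatrix())
    return SpellerResult(report, float(acc_by_rep[-1]), acc_by_rep,
                         n_test_characters)
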