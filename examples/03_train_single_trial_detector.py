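"""Train the autoencoded CNN on a balanced synthetic set and score it.

Phase 1 fits the shared per-channel autoencoder (MSE, RMSprop) and
freezes it; phase 2 fits the convolutional head (binary cross-entropy,
Adam).  The holdout is carved off before training, so the F1 below is
leakage-free.  Takes around a minute on one core.
"""
from p300kit.experiments import single_trial_experiment

result = single_trial_experiment(snr=3.0, n_trials=2000, seed=0)
c = result.counts
print(f"trained on {result.n_train} balanced trials, "
      f"holdout of {result.n_holdout}")
print(f"holdout counts: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}")
r = result.report
print(f"precision {r.precision:.2f}%  recall {r.recall:.2f}%  "
      f"accuracy {r.accuracy:.2f}%  F1 {r.f1:.2f}%")
print("an F1 above 90% at snr=3 means single flashes are classified "
      "reliably without any repetition averaging")
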