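# Methods

This note documents the models and procedures implemented in p300kit,
the parameters that matter, the synthetic data the toolkit is validated
on, and the numerical and design choices made where the design was
genuinely open.

## Signal model and synthetic sessions

A session is a continuous multichannel recording (µV, canonically
240 Sa/s) plus a flash schedule. Flashes are spaced by the
inter-stimulus interval (ISI, default 0.175 s; flash duration 0.1 s) and
grouped into selections: 4 codes × n_rep flashes per 4-choice selection,
12 codes × n_rep per speller character epoch, with each repetition block
independently shuffled so the target occurrence probability per flash is
exactly 1/4 or 2/12. After each selection the generator inserts the same
pause the timing analytics assume (0.5 s and 2.5 s respectively), so
simulated sessions and the selection-time formulas T = 0.5 + 0.7·n_rep
and T = 2.5 + 2.1·n_rep describe the same protocol. The 4-choice ISI is
set to 0.175 s to stay consistent with that 0.7 s-per-block timing; the
value is configurable.

Target flashes add an ERP surrogate: a half-sine of width 0.3 s centred
0.35 s post-onset (peak inside the canonical 0.25–0.45 s P300 latency
band), scaled per channel by a spatial weight vector that defaults to
1.0 on the last three of six channels and 0.4 elsewhere, emulating
parietal dominance. Any smooth positive deflection in that window would
do; the half-sine makes the injected amplitude (and hence the
signal-to-noise ratio) exactly interpretable: `snr` is the template peak
on a full-weight channel divided by the noise standard deviation, and
`snr = 0` produces a null session.

Background noise is an order-2 autoregressive process (poles 0.9 and
0.8) band-limited to 0.1–20 Hz and rescaled to a per-channel standard
deviation `noise_sigma` (default 10 µV). The pole placement gives a
power spectrum falling roughly as 1/f² across 2–20 Hz, the standard
pink-noise surrogate for resting EEG. This matters beyond realism: the
symbolized representation of near-white in-band noise is essentially
full-rank, and no 8-dimensional bottleneck — not even an optimal linear
one — can reconstruct it without discarding the evoked-response
signature, whereas under 1/f-style noise the symbol sequences are
smooth and low-rank and the autoencoder preserves class information.
Artifacts (probability `artifact_rate` per trial) are 8σ Gaussian bumps
of 50 ms width on a random channel, exercising the winsorizing stage.

What the generator does **not** emulate: volume conduction and realistic
channel covariance (channels are independent), eye-blink morphology,
latency jitter of the evoked response, non-stationary noise, and
behavioural effects (fatigue, attention lapses). Passing tests therefore
demonstrate that the pipeline recovers a known planted signal under
controlled conditions, not performance on recorded EEG.

## Preprocessing

Stage order is fixed: epoch → baseline → winsorize → symbolize.

* **Epoch**: half-open window [onset + round(0.1·fs), onset +
  round(0.8·fs)), 168 samples at 240 Sa/s. 250 Sa/s input is reduced to
  240 Sa/s by polyphase resampling (24/25, mean-padded edges).
* **Baseline**: subtract the per-channel mean of the first 12 samples
  (50 ms) of the window.
* **Winsorize**: clip to the per-channel 1st/99th percentiles computed
  over all samples of the *training* trials only (linear interpolation
  between order statistics; the percentile method is otherwise
  unspecified, and this is numpy's default). Thresholds are serialized
  so test data reuse the training bounds. Winsorizing follows baseline
  correction, matching the listed stage order of the processing chain.
* **Symbolize**: onsets j ∈ {0, 3, 6, …} with j + 8 ≤ T − 1; the symbol
  is the count of the 8 following samples strictly greater than the
  amplitude at j (ties count 0). A 168-sample trial yields
  ⌊(168−8−1)/3⌋+1 = 54 symbols per channel. All indexing is 0-based
  with half-open windows. Symbols are invariant under any strictly
  increasing amplitude transform, which the property tests assert.

The optional zero-phase Butterworth band-pass (0.1–20 Hz, order 8) is
provided for unfiltered sources. Its 0.1 Hz edge implies an impulse
response of tens of seconds; the implementation extends the filtfilt
reflection padding to 3/lo seconds, and the tests evaluate band
behaviour away from record edges.

## Detector

Architecture (per-trial input: 54×6 symbols):

input standardizer → shared autoencoder per channel
(Dense 16 ReLU → Dense 8 ReLU → Dense 16 ReLU → Dense L_s linear)
→ concatenate (L_s, 6) → batch norm → Conv1D (16 filters, kernel 8,
stride 8, valid, ReLU) → flatten → batch norm → Dense 64 ReLU +
dropout 0.4 → Dense 64 ReLU + dropout 0.4 → Dense 1 sigmoid.

The convolution kernel covers 8 symbols ≈ 100 ms of signal and is
non-overlapping (stride = kernel), so the six (shapes profile) or seven
(counts profile) output steps are disjoint temporal summaries. The
input standardizer (per-channel mean/variance from the training set) is
the normalization stage "limited to training-set adaptation"; it has no
entry in the complexity ledger.

Two input-length profiles exist because the published architecture
description is internally inconsistent: every printed tensor shape
requires 54 symbols per channel, while every printed per-layer parameter
count requires 56. The **shapes** profile (L_s = 54, window
[0.1 s, 0.8 s]) is the working default; the **counts** profile
(L_s = 56, window extended to [0.1 s, 0.825 s] = 174 samples so the
symbolizer emits 56 symbols) is the parameter-accounting configuration
reproducing the totals 14,857 / 12,477 trainable / 2,380 frozen. The
totals only reconcile when the autoencoder is counted once (it is
genuinely shared across the six channel branches, not replicated) and
when the input standardizer is excluded. Related readings of the
source description adopted here: the temporal kernel is 8 wide with 16
filters (the only reading consistent with 784 = 8·6·16+16 parameters
and a (6,16) output at stride 8); dropout drops with probability 0.4;
decisions use a strict 0.5 threshold (probability exactly 0.5 → class
0).

**Training.** Phase 1 pools all single-channel symbol vectors of the
training split and fits the autoencoder (MSE, RMSprop lr 10⁻³, batch
32); weights are then frozen — the freeze is structural: phase 2
computes autoencoded features once and never backpropagates into the
autoencoder. Phase 2 fits the head (binary cross-entropy, Adam
lr 10⁻⁴, β₁ 0.9, β₂ 0.999, ε 10⁻⁸, no decay, batch 64) on a 70/30
train/validation split. Epoch budgets are not part of the published
recipe and are configuration: defaults 100 (autoencoder) and 200
(classifier) with early stopping on validation loss, patience 20, best
weights restored. All randomness (initialization, shuffling, dropout)
flows from explicit seeds; retraining with the same seed is
bit-reproducible.

**Complexity ledger.** Dense parameters in·out+out with MACC equal to
the parameter count; conv parameters kernel·C·filters+filters with MACC
steps·filters·(kernel·C+1); batch norm 4 parameters per feature (2
trainable) and 2 MACC per normalized element; activations 1 MACC per
unit. Some embedded-AI code generators report one extra accumulate per
conv filter; `vendor_macc_bias=True` reproduces that convention. The
ledger is verified in tests against the array sizes of an instantiated
network.

## Imbalance handling

Odd-ball training sets are 1:3 (4-choice) or 1:5 (speller) imbalanced.
`rebalance` applies NearMiss-2 — keep the majority samples whose mean
Euclidean distance to their k = 3 farthest minority samples (flattened
symbol vectors) is smallest, ties broken by input order — down to a 2:1
majority:minority ratio, then duplicates minority samples uniformly at
random (seeded) to exact parity. The intermediate 2:1 ratio is a design
choice balancing retained majority structure against duplication; both
knobs are exposed. Resampling operates on symbol vectors (the
representation the model consumes) and is applied to training data
only; evaluation sets are never oversampled, since duplicates crossing
a split boundary would leak and inflate holdout scores (measurably: a
null-signal experiment scores ~0.61 accuracy with leaking duplicates
versus ~0.51 without).

## Channel elimination

Greedy backward elimination: from the full montage, each round removes
the channel whose removal maximizes TP/(TP+FP+FN) (0 when the
denominator is 0) computed from a provisional classifier's validation
counts on a single seeded 70/30 holdout; ties remove the lowest index.
The provisional classifier is pluggable; the package ships a
standardized logistic regression (used by the planted-recovery
experiments — the selection stage only ranks channel subsets, and the
lightweight model keeps multi-seed replication cheap) and the
detector's own convolutional head without the autoencoder branch.
Cross-subject selection ranks channels by membership count in the
per-subject surviving sets, then by mean removal round (later = more
informative), then by index.

The planted-recovery experiment uses 14 channels of which the last 6
carry the template at snr 1.5 over 200-selection sessions. Equal-weight
informative channels are mutually redundant, so the marginal criterion
cost of removing one is small; the chosen session size makes that
margin resolvable against holdout noise, and recovery succeeds in at
least 9 of 10 seeded montages.

## Decisions and analytics

Selections are decided by maximum occurrence of positive single-trial
labels per code, with a documented tie-break chain: occurrence → summed
probability → lowest code (with no positive labels at all this reduces
to the summed-probability rule). A speller character is the
intersection of the independently decided row and column. An
alternative pure probability-accumulation mode is available
(`use_probabilities=True`); label counting is the default.
Accuracy-versus-repetitions recomputes each decision from scratch using
only the first r repetition blocks.

Metrics use the standard contingency formulas; 0/0 cells return 0 with
a warning. The ITR formula is the Wolpaw form with the analytic limits
P = 1, P = 0 and P = 1/N handled exactly (values within 10⁻¹² of the
chance cancellation are snapped to zero). Cross-subject aggregation
reports the arithmetic mean and (n−1)-denominator standard deviation;
a single report is flagged and its deviation reported as 0.

## Study conditions and problem sizes

The end-to-end verification experiments use: 2000 balanced distinct
trials (1000 targets, majority subsampled without replacement, 30 %
holdout carved off before training) for single-trial recovery at
snr = 3 and the chance-level check at snr = 0; a 10-selection,
15-repetition speller session (1800 trials, rebalanced) for training
and a 40-character session for character recovery, both at snr = 3 so
the per-trial detector clears F1 0.7 before aggregation; and the
planted-channel montages described above. These sizes keep every
experiment deterministic and fast while leaving comfortable margins
over the asserted thresholds.

## Known limitations

* The detector is validated on synthetic sessions only; no claim is
  made about recorded-EEG performance.
* The numpy network engine implements exactly the layers this
  architecture needs; it is not a general-purpose deep-learning
  framework (no GPU, no autodiff beyond the implemented layers).
* Recursive elimination retrains the provisional classifier once per
  candidate per round (O(C²) fits); very large montages would need a
  cheaper criterion or caching.
* The speller assumes one attended character per epoch and no dynamic
  stopping; adaptive repetition counts are out of scope.
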