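"""The autoencoded 1D-CNN single-trial P300 detector.

Architecture
------------
Symbol sequences of shape (L_s, 6 channels) enter a per-channel
standardizer (fit on training data only), then each channel slice passes
through ONE shared dense autoencoder (16-ReLU -> 8-ReLU -> 16-ReLU ->
L_s linear) whose role is to denoise the symbol sequence.  The six
reconstructions are re-concatenated to (L_s, 6) and fed to a sequential
head: batch norm -> 1D convolution (16 filters, kernel 8, stride 8, no
padding, ReLU) -> flatten -> batch norm -> two dense-64 ReLU layers with
dropout 0.4 -> dense-1 sigmoid giving the per-trial P300 probability.

Training is two-phase: the autoencoder is fit first (MSE, RMSprop,
minibatch 32) on pooled single-channel vectors and then frozen; the head
is fit with binary cross-entropy and Adam (lr 1e-4, batch 64) on a 70/30
train/validation split with early stopping on validation loss.

Profiles
--------
Two input-length profiles are provided.  ``shapes`` (L_s = 54, the
symbol count of a 168-sample trial) is the default working
configuration.  ``counts`` (L_s = 56, trial window extended to
[0.1 s, 0.825 s] = 174 samples) is the parameter-accounting
configuration whose ledger reproduces the published per-layer parameter
totals (autoencoder 2,144; grand total 14,857 with 12,477 trainable);
the two cannot be reconciled in a single input length.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nnet
from .preprocessing import SymbolizedTrialSet

PROFILES = {
    "shapes": {"symbols_per_channel": 54, "trial_window_end": 0.8},
    "counts": {"symbols_per_channel": 56, "trial_window_end": 0.825},
}


@dataclass
class NetworkConfig:
    """Hyperparameters of the detector architecture."""

    channels: int = 6
    symbols_per_channel: int = 54
    ae_units: tuple = (16, 8, 16)
    conv_filters: int = 16
    conv_kernel: int = 8
    conv_stride: int = 8
    dense_units: tuple = (64, 64, 1)
    dropout_rate: float = 0.4
    decision_threshold: float = 0.5
    trial_window_end: float = 0.8

    @classmethod
    def from_profile(cls, profile: str = "shapes", **overrides) -> "NetworkConfig":
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        return cls(**{**PROFILES[profile], **overrides})

    @property
    def conv_steps(self) -> int:
        steps = (self.symbols_per_channel - self.conv_kernel) // self.conv_stride + 1
        if steps < 1:
            raise ValueError(
                f"conv kernel {self.conv_kernel} exceeds input length "
                f"{self.symbols_per_channel}"
            )
        return steps

    @property
    def flatten_size(self) -> int:
        return self.conv_steps * self.conv_filters

    def validate(self) -> None:
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if len(self.ae_units) != 3:
            raise ValueError("ae_units must be (encoder, code, decoder)")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        _ = self.conv_steps  # raises when geometry is inconsistent


@dataclass
class TrainConfig:
    """Optimization settings for the two training phases."""

    ae_batch: int = 32
    ae_lr: float = 1e-3          # RMSprop default
    clf_batch: int = 64
    clf_lr: float = 1e-4         # Adam, no decay
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    validation_fraction: float = 0.30
    epochs_ae: int = 100
    epochs_clf: int = 200
    patience: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# complexity ledger


@dataclass
class LayerCost:
    name: str
    output_shape: tuple
    n_params: int
    n_trainable: int
    macc: int

    @property
    def n_frozen(self) -> int:
        return self.n_params - self.n_trainable


@dataclass
class ComplexityReport:
    layers: list[LayerCost] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    @property
    def trainable_params(self) -> int:
        return sum(l.n_trainable for l in self.layers)

    @property
    def frozen_params(self) -> int:
        return sum(l.n_frozen for l in self.layers)

    @property
    def total_macc(self) -> int:
        return sum(l.macc for l in self.layers)

    def to_rows(self) -> list[dict]:
        return [
            {
                "layer": l.name,
                "output_shape": "x".join(map(str, l.output_shape)),
                "params": l.n_params,
                "trainable": l.n_trainable,
                "macc": l.macc,
            }
            for l in self.layers
        ]


def count_parameters(config: NetworkConfig, vendor_macc_bias: bool = False) -> ComplexityReport:
    """Per-layer parameter and MACC ledger of the detector.

    Conventions: dense params = in*out + out and its MACC equals its
    parameter count; conv params = kernel*channels*filters + filters with
    MACC = output_steps*filters*(kernel*channels + 1); batch norm has
    4 parameters per feature (scale and shift trainable, moving mean and
    variance not) and MACC = 2 per normalized element; activations cost
    one MACC per unit.  The shared autoencoder is counted once and is
    entirely frozen in the assembled detector.  ``vendor_macc_bias`` adds
    one extra accumulate per conv filter, matching some embedded-AI code
    generators' accounting.
    """
    config.validate()
    L, C = config.symbols_per_channel, config.channels
    enc, code, dec = config.ae_units
    report = ComplexityReport()

    def dense_row(name, n_in, n_out, trainable=True, frozen_all=False):
        p = n_in * n_out + n_out
        report.layers.append(
            LayerCost(name, (n_out,), p, 0 if frozen_all else (p if trainable else 0), p)
        )

    def act_row(name, units):
        report.layers.append(LayerCost(name, (units,), 0, 0, units))

    # shared autoencoder (frozen after its own training phase)
    dense_row("ae_encoder_dense", L, enc, frozen_all=True)
    act_row("ae_encoder_relu", enc)
    dense_row("ae_code_dense", enc, code, frozen_all=True)
    act_row("ae_code_relu", code)
    dense_row("ae_decoder_dense", code, dec, frozen_all=True)
    act_row("ae_decoder_relu", dec)
    dense_row("ae_output_dense", dec, L, frozen_all=True)

    # sequential head
    report.layers.append(
        LayerCost("batchnorm_pre_conv", (L, C), 4 * C, 2 * C, 2 * L * C)
    )
    steps, F = config.conv_steps, config.conv_filters
    conv_p = config.conv_kernel * C * F + F
    conv_macc = steps * F * (config.conv_kernel * C + 1) + (F if vendor_macc_bias else 0)
    report.layers.append(LayerCost("conv1d", (steps, F), conv_p, conv_p, conv_macc))
    act_row("conv_relu", steps * F)
    report.layers.append(LayerCost("flatten", (config.flatten_size,), 0, 0, 0))
    flat = config.flatten_size
    report.layers.append(
        LayerCost("batchnorm_pre_dense", (flat,), 4 * flat, 2 * flat, 2 * flat)
    )
    d1, d2, d3 = config.dense_units
    dense_row("dense_1", flat, d1)
    act_row("dense_1_relu", d1)
    dense_row("dense_2", d1, d2)
    act_row("dense_2_relu", d2)
    dense_row("dense_out", d2, d3)
    act_row("sigmoid", d3)
    return report


def count_macc(config: NetworkConfig, vendor_macc_bias: bool = False) -> ComplexityReport:
    """Alias of :func:`count_parameters`; the ledger carries both columns."""
    return count_parameters(config, vendor_macc_bias=vendor_macc_bias)


# ---------------------------------------------------------------------------
# detector


class P300Detector:
    """Shared autoencoder + sequential CNN head with per-channel input scaler."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        L = config.symbols_per_channel
        enc, code, dec = config.ae_units
        self.ae = nnet.Sequential([
            nnet.Dense(L, enc, rng), nnet.ReLU(),
            nnet.Dense(enc, code, rng), nnet.ReLU(),
            nnet.Dense(code, dec, rng), nnet.ReLU(),
            nnet.Dense(dec, L, rng),
        ])
        d1, d2, d3 = config.dense_units
        self._dropouts = [
            nnet.Dropout(config.dropout_rate, rng),
            nnet.Dropout(config.dropout_rate, rng),
        ]
        self.head = nnet.Sequential([
            nnet.BatchNorm(config.channels),
            nnet.Conv1D(config.channels, config.conv_filters,
                        config.conv_kernel, config.conv_stride, rng),
            nnet.ReLU(),
            nnet.Flatten(),
            nnet.BatchNorm(config.flatten_size),
            nnet.Dense(config.flatten_size, d1, rng), nnet.ReLU(), self._dropouts[0],
            nnet.Dense(d1, d2, rng), nnet.ReLU(), self._dropouts[1],
            nnet.Dense(d2, d3, rng),
        ])
        self.scaler_mean: Optional[np.ndarray] = None
        self.scaler_std: Optional[np.ndarray] = None
        self.ae_frozen = False
        self.history: dict = {}

    # -- input handling ----------------------------------------------------

    def _as_array(self, symbols) -> np.ndarray:
        X = symbols.symbols if isinstance(symbols, SymbolizedTrialSet) else symbols
        X = np.asarray(X, dtype=float)
        expected = (self.config.symbols_per_channel, self.config.channels)
        if X.ndim != 3 or X.shape[1:] != expected:
            raise ValueError(
                f"symbols must have shape (n, {expected[0]}, {expected[1]}), got {X.shape}"
            )
        return X

    def fit_scaler(self, X: np.ndarray) -> None:
        self.scaler_mean = X.mean(axis=(0, 1))
        std = X.std(axis=(0, 1))
        std[std == 0] = 1.0
        self.scaler_std = std

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None:
            raise RuntimeError("input scaler not fitted; train the autoencoder first")
        return (X - self.scaler_mean) / self.scaler_std

    def channel_vectors(self, Xs: np.ndarray) -> np.ndarray:
        """Pool standardized trials into independent (L_s,) channel vectors."""
        N, L, C = Xs.shape
        return Xs.transpose(0, 2, 1).reshape(N * C, L)

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Standardize and pass every channel through the shared autoencoder."""
        Xs = self.standardize(self._as_array(X))
        N, L, C = Xs.shape
        rec = self.ae.forward(self.channel_vectors(Xs), train=False)
        return rec.reshape(N, C, L).transpose(0, 2, 1)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for d in self._dropouts:
            d.rng = rng


def build_detector(config: Optional[NetworkConfig] = None, seed: int = 0) -> P300Detector:
    return P300Detector(config or NetworkConfig(), seed=seed)


# ---------------------------------------------------------------------------
# training


def _split(n: int, fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(1, int(round(fraction * n)))
    return idx[n_val:], idx[:n_val]


def _epoch_minibatches(n: int, batch: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch):
        yield order[i: i + batch]


def train_autoencoder(detector: P300Detector, symbols, tc: Optional[TrainConfig] = None) -> dict:
    """Phase 1: fit the shared autoencoder on pooled channel vectors, then
    freeze it.  Returns the loss history (train/val MSE per epoch, plus the
    untrained validation MSE under key ``val_loss_initial``)."""
    tc = tc or TrainConfig()
    tc.validate()
    X = detector._as_array(symbols)
    detector.fit_scaler(X)
    V = detector.channel_vectors(detector.standardize(X))
    rng = np.random.default_rng(tc.seed)
    tr, va = _split(len(V), tc.validation_fraction, rng)
    opt = nnet.RMSprop(lr=tc.ae_lr)

    def val_mse() -> float:
        rec = detector.ae.forward(V[va], train=False)
        return float(np.mean((rec - V[va]) ** 2))

    history = {"loss": [], "val_loss": [], "val_loss_initial": val_mse()}
    best = (np.inf, detector.ae.get_weights())
    since_best = 0
    for _ in range(tc.epochs_ae):
        losses = []
        for mb in _epoch_minibatches(len(tr), tc.ae_batch, rng):
            xb = V[tr[mb]]
            rec = detector.ae.forward(xb, train=True)
            loss, grad = nnet.mse_loss(rec, xb)
            if not np.isfinite(loss):
                raise RuntimeError(f"autoencoder training diverged; history={history}")
            detector.ae.backward(grad)
            opt.step(detector.ae.params(), detector.ae.grads())
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        vl = val_mse()
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, detector.ae.get_weights())
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break
    detector.ae.set_weights(best[1])
    detector.ae_frozen = True
    detector.history["autoencoder"] = history
    return history


def train_classifier(detector: P300Detector, symbols, labels,
                     tc: Optional[TrainConfig] = None) -> dict:
    """Phase 2: fit the sequential head on autoencoded features with the
    autoencoder weights frozen.  30 % of the data is held out for
    validation-loss early stopping."""
    tc = tc or TrainConfig()
    tc.validate()
    if not detector.ae_frozen:
        raise RuntimeError("train the autoencoder before the classifier")
    y = np.asarray(labels).astype(float).ravel()
    if len(set(y.tolist())) < 2:
        raise ValueError("classifier training needs both target and non-target trials")
    E = detector.encode(symbols)  # AE frozen: features are fixed
    if len(E) != len(y):
        raise ValueError("labels length must match trial count")
    rng = np.random.default_rng(tc.seed + 1)
    detector.set_dropout_rng(rng)
    tr, va = _split(len(E), tc.validation_fraction, rng)
    opt = nnet.Adam(lr=tc.clf_lr, beta1=tc.adam_beta1, beta2=tc.adam_beta2,
                    eps=tc.adam_eps)

    def val_loss() -> float:
        logits = detector.head.forward(E[va], train=False)
        loss, _ = nnet.bce_with_logits(logits, y[va])
        return loss

    history = {"loss": [], "val_loss": []}
    best = (np.inf, [w.copy() for w in detector.head.state()])
    since_best = 0
    for _ in range(tc.epochs_clf):
        losses = []
        for mb in _epoch_minibatches(len(tr), tc.clf_batch, rng):
            xb, yb = E[tr[mb]], y[tr[mb]]
            logits = detector.head.forward(xb, train=True)
            loss, grad = nnet.bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(f"classifier training diverged; history={history}")
            detector.head.backward(grad)
            opt.step(detector.head.params(), detector.head.grads())
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        vl = val_loss()
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, [w.copy() for w in detector.head.state()])
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break
    for p, w in zip(detector.head.state(), best[1]):
        p[...] = w
    history["val_index"] = va
    detector.history["classifier"] = history
    return history


def predict(detector: P300Detector, symbols) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial P300 probability and binary label.

    The label is positive only when probability strictly exceeds the
    decision threshold (a probability of exactly 0.5 maps to 0); dropout
    is inactive, so repeated calls give identical outputs.
    """
    E = detector.encode(symbols)
    logits = detector.head.forward(E, train=False)
    probs = nnet.sigmoid(logits.ravel())
    return probs, probs > detector.config.decision_threshold
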