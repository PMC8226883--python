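"""Detector architecture, parameter/MACC ledger and two-phase training."""
import numpy as np
import pytest

from p300kit.model import (NetworkConfig, TrainConfig, build_detector,
                           count_parameters, predict, train_autoencoder,
                           train_classifier)


def _hash_weights(seq):
    return tuple(a.tobytes() for a in seq.params())


class TestConfig:
    def test_shapes_profile_geometry(self):
        cfg = NetworkConfig.from_profile("shapes")
        assert (cfg.symbols_per_channel, cfg.conv_steps, cfg.flatten_size) == (54, 6, 96)

    def test_counts_profile_geometry(self):
        cfg = NetworkConfig.from_profile("counts")
        assert (cfg.symbols_per_channel, cfg.conv_steps, cfg.flatten_size) == (56, 7, 112)

    def test_unknown_profile(self):
        with pytest.raises(ValueError, match="profile"):
            NetworkConfig.from_profile("huge")

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            NetworkConfig(symbols_per_channel=4, conv_kernel=8).validate()


class TestLedger:
    def test_counts_profile_autoencoder_rows(self):
        rep = count_parameters(NetworkConfig.from_profile("counts"))
        rows = {l.name: l.n_params for l in rep.layers}
        assert rows["ae_encoder_dense"] == 912
        assert rows["ae_code_dense"] == 136
        assert rows["ae_decoder_dense"] == 144
        assert rows["ae_output_dense"] == 952
        ae_total = sum(v for k, v in rows.items() if k.startswith("ae_"))
        assert ae_total == 2144

    def test_counts_profile_sequential_rows_and_totals(self):
        rep = count_parameters(NetworkConfig.from_profile("counts"))
        rows = {l.name: l.n_params for l in rep.layers}
        assert rows["batchnorm_pre_conv"] == 24
        assert rows["conv1d"] == 784
        assert rows["batchnorm_pre_dense"] == 448
        assert rows["dense_1"] == 7232
        assert rows["dense_2"] == 4160
        assert rows["dense_out"] == 65
        assert rep.total_params == 14857
        assert rep.trainable_params == 12477
        assert rep.frozen_params == 2380

    def test_shapes_profile_autoencoder(self):
        rep = count_parameters(NetworkConfig.from_profile("shapes"))
        rows = {l.name: l.n_params for l in rep.layers}
        # same counting rules at per-channel length 54
        assert rows["ae_encoder_dense"] == 880
        assert rows["ae_output_dense"] == 918
        ae_total = sum(v for k, v in rows.items() if k.startswith("ae_"))
        assert ae_total == 880 + 136 + 144 + 918

    def test_macc_convention(self):
        rep = count_parameters(NetworkConfig.from_profile("counts"))
        macc = {l.name: l.macc for l in rep.layers}
        assert macc["ae_encoder_dense"] == 912      # dense MACC = param count
        assert macc["ae_encoder_relu"] == 16        # activation MACC = units
        assert macc["batchnorm_pre_conv"] == 672    # 2 per normalized element
        assert macc["conv1d"] == 7 * 16 * (8 * 6 + 1)
        vendor = count_parameters(NetworkConfig.from_profile("counts"),
                                  vendor_macc_bias=True)
        vmacc = {l.name: l.macc for l in vendor.layers}
        assert vmacc["conv1d"] == macc["conv1d"] + 16

    def test_ledger_matches_instantiated_network(self):
        """Dual route: arithmetic ledger vs actual array sizes."""
        for profile in ("shapes", "counts"):
            cfg = NetworkConfig.from_profile(profile)
            det = build_detector(cfg)
            actual = sum(p.size for p in det.ae.params())
            actual += sum(p.size for p in det.head.params())
            # batch-norm moving statistics are parameters in the ledger but
            # not optimizer-visible arrays; add them explicitly
            from p300kit import nnet
            for layer in det.head.layers:
                if isinstance(layer, nnet.BatchNorm):
                    actual += layer.running_mean.size + layer.running_var.size
            assert count_parameters(cfg).total_params == actual

    def test_params_and_macc_increase_with_input_length(self):
        totals = [
            (count_parameters(NetworkConfig(symbols_per_channel=L)).total_params,
             count_parameters(NetworkConfig(symbols_per_channel=L)).total_macc)
            for L in (48, 54, 56, 64)
        ]
        assert all(a[0] < b[0] and a[1] < b[1] for a, b in zip(totals, totals[1:]))


@pytest.fixture(scope="module")
def toy_symbols():
    rng = np.random.default_rng(4)
    n = 400
    base = rng.integers(0, 9, size=(n, 54, 6)).astype(float)
    labels = np.arange(n) % 2 == 0
    # planted difference so the classes are separable
    base[labels, 20:30, 3:] += 3.0
    return np.clip(base, 0, 8), labels


class TestTraining:
    def test_forward_on_zeros_in_unit_interval(self):
        det = build_detector(seed=0)
        det.fit_scaler(np.zeros((4, 54, 6)) + 1.0)
        det.scaler_std = np.ones(6)
        probs, labels = predict(det, np.zeros((4, 54, 6)))
        assert np.all((probs >= 0) & (probs <= 1))

    def test_autoencoder_improves_on_untrained(self, toy_symbols):
        X, _ = toy_symbols
        det = build_detector(seed=1)
        h = train_autoencoder(det, X, TrainConfig(seed=1, epochs_ae=30))
        assert h["val_loss"][-1] < h["val_loss_initial"]
        assert det.ae_frozen

    def test_autoencoder_deterministic_given_seed(self, toy_symbols):
        X, _ = toy_symbols
        tc = TrainConfig(seed=5, epochs_ae=5)
        d1, d2 = build_detector(seed=2), build_detector(seed=2)
        train_autoencoder(d1, X, tc)
        train_autoencoder(d2, X, tc)
        assert _hash_weights(d1.ae) == _hash_weights(d2.ae)

    def test_classifier_requires_trained_autoencoder(self, toy_symbols):
        X, y = toy_symbols
        det = build_detector(seed=0)
        with pytest.raises(RuntimeError, match="autoencoder"):
            train_classifier(det, X, y)

    def test_classifier_rejects_single_class(self, toy_symbols):
        X, _ = toy_symbols
        det = build_detector(seed=0)
        train_autoencoder(det, X, TrainConfig(seed=0, epochs_ae=2))
        with pytest.raises(ValueError, match="both"):
            train_classifier(det, X, np.ones(len(X)))

    def test_freeze_contract_and_prediction_semantics(self, toy_symbols):
        X, y = toy_symbols
        det = build_detector(seed=3)
        tc = TrainConfig(seed=3, epochs_ae=15, epochs_clf=25)
        train_autoencoder(det, X, tc)
        before = _hash_weights(det.ae)
        train_classifier(det, X, y, tc)
        assert _hash_weights(det.ae) == before  # AE untouched by phase 2
        p1, l1 = predict(det, X[:50])
        p2, l2 = predict(det, X[:50])
        assert np.array_equal(p1, p2) and np.array_equal(l1, l2)  # no dropout
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert np.array_equal(l1, p1 > 0.5)  # strict: p == 0.5 maps to 0

    def test_shape_mismatch_rejected(self):
        det = build_detector(seed=0)
        with pytest.raises(ValueError, match="shape"):
            det._as_array(np.zeros((10, 54, 5)))
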