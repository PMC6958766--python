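import numpy as np
import pytest

import premirnet as pm
from premirnet import nn
from premirnet.exceptions import ValidationError
from premirnet.models import cnn_output_length, positive_scores

from helpers import numerical_gradients


class TestArchitectureArithmetic:
    def test_first_conv_parameter_count(self):
        clf = pm.build_cnn()
        # k=4 kernel, 12 channels, 16 filters: 4*12*16 weights + 16 biases
        assert clf.network.layers[0].n_params() == 4 * 12 * 16 + 16 == 784

    def test_cascade_output_length(self):
        # valid conv (L-k+1) then pool (L//2), three times, from 180
        assert cnn_output_length(pm.CNNSpec()) == 18

    def test_cnn_total_parameter_count(self):
        expected = (
            (4 * 12 * 16 + 16)
            + (5 * 16 * 32 + 32)
            + (6 * 32 * 64 + 64)
            + (18 * 64 * 32 + 32)
            + (32 * 2 + 2)
        )
        assert pm.build_cnn().n_params() == expected

    def test_first_lstm_parameter_count(self):
        clf = pm.build_rnn()
        # four gates, each W (12x128) + U (128x128) + b (128)
        assert clf.network.layers[0].n_params() == 4 * (128 * (12 + 128) + 128) == 72192

    def test_rnn_final_width_must_match_outputs(self):
        with pytest.raises(ValidationError):
            pm.RNNSpec(lstm_units=(8, 4))

    def test_non_decreasing_units_warn(self):
        with pytest.warns(UserWarning):
            pm.RNNSpec(lstm_units=(4, 8, 2))

    def test_length_collapse_is_detected(self):
        with pytest.raises(ValidationError):
            cnn_output_length(pm.CNNSpec(max_len=10))


class TestForwardPass:
    @pytest.mark.parametrize("builder", [pm.build_cnn, pm.build_rnn])
    def test_softmax_probability_pairs(self, builder):
        clf = builder()
        x = np.random.default_rng(0).random((5, 180, 12))
        probs = pm.predict(clf, x)
        assert probs.shape == (5, 2)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("builder", [pm.build_cnn, pm.build_rnn])
    def test_inference_determinism(self, builder):
        clf = builder()
        x = np.random.default_rng(1).random((3, 180, 12))
        np.testing.assert_array_equal(pm.predict(clf, x), pm.predict(clf, x))

    def test_empty_batch(self):
        assert pm.predict(pm.build_cnn(), []).shape == (0, 2)

    def test_shape_mismatch_rejected(self):
        clf = pm.build_cnn()
        with pytest.raises(ValidationError):
            pm.predict(clf, np.zeros((2, 90, 12)))

    def test_argmax_matches_threshold_labels(self, trained_cnn, corpus_encoded):
        clf, _ = trained_cnn
        mats, _ = corpus_encoded[2]
        probs = pm.predict(clf, mats)
        scores = positive_scores(clf, mats)
        non_tie = scores != 0.5
        np.testing.assert_array_equal(
            (probs.argmax(axis=1) == 1)[non_tie], (scores >= 0.5)[non_tie]
        )


class TestGradients:
    """Analytic backprop vs central-difference numerical gradients."""

    def _check(self, net, x, y, tol):
        loss_fn = nn.CrossEntropyLoss()
        loss_fn.forward(net.forward(x), y)
        net.backward(loss_fn.backward())
        analytic = [g.copy() for g in net.gradients()]
        numeric = numerical_gradients(net, loss_fn, x, y)
        for a, n in zip(analytic, numeric):
            scale = np.abs(n).max() + 1e-12
            assert np.abs(a - n).max() / scale < tol

    def test_conv_pool_dense_stack(self):
        rng = np.random.default_rng(0)
        net = nn.Sequential([
            nn.Conv1D(4, 3, 3), nn.ReLU(), nn.MaxPool1D(2), nn.Flatten(),
            nn.Dense(15, 4), nn.ReLU(), nn.Dense(4, 2), nn.Softmax(),
        ])
        net.initialize(1)
        x = rng.random((3, 12, 4))
        y = np.eye(2)[[0, 1, 0]]
        self._check(net, x, y, 1e-6)

    def test_stacked_lstm(self):
        rng = np.random.default_rng(2)
        net = nn.Sequential([
            nn.LSTM(4, 5, return_sequences=True),
            nn.LSTM(5, 2, return_sequences=False),
            nn.Softmax(),
        ])
        net.initialize(3)
        x = rng.random((3, 12, 4))
        y = np.eye(2)[[1, 0, 1]]
        self._check(net, x, y, 1e-5)


class TestPaddingBehavior:
    def test_pad_steps_drift_only_through_recurrence(self):
        """Zero-padded suffix steps feed nothing through the input weights:
        the state evolves exactly as the bias/recurrent drift predicts."""
        net = nn.Sequential([nn.LSTM(3, 4, return_sequences=True)])
        net.initialize(5)
        rng = np.random.default_rng(6)
        x = rng.random((2, 8, 3))
        x_padded = np.concatenate([x, np.zeros((2, 10, 3))], axis=1)
        hs = net.forward(x_padded)
        lstm = net.layers[0]
        Wx, Uh, b = lstm.params
        H = 4
        # replay the pad steps with the input contribution zeroed by hand
        i_s, f_s, g_s, o_s, c_s, hc_s, hprev_s, cprev_s = lstm._cache
        h = hs[:, 7, :].copy()
        c = c_s[7].copy()
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        for t in range(8, 18):
            z = b + h @ Uh  # no x @ Wx term: the input is all-zero padding
            i, f = sig(z[:, :H]), sig(z[:, H : 2 * H])
            g, o = np.tanh(z[:, 2 * H : 3 * H]), sig(z[:, 3 * H :])
            c = i * g + f * c
            h = o * np.tanh(c)
            np.testing.assert_allclose(hs[:, t, :], h, atol=1e-12)


class TestSaveLoad:
    def test_roundtrip_predictions_bit_identical(self, tmp_path, trained_cnn, corpus_encoded):
        clf, _ = trained_cnn
        mats, _ = corpus_encoded[2]
        before = pm.predict(clf, mats[:50])
        pm.save_model(clf, tmp_path / "m")
        loaded = pm.load_model(tmp_path / "m")
        np.testing.assert_array_equal(before, pm.predict(loaded, mats[:50]))

    def test_rnn_roundtrip(self, tmp_path):
        clf = pm.build_rnn()
        x = np.random.default_rng(0).random((4, 180, 12))
        before = pm.predict(clf, x)
        pm.save_model(clf, tmp_path / "m")
        loaded = pm.load_model(tmp_path / "m")
        np.testing.assert_array_equal(before, pm.predict(loaded, x))
        assert "no_peephole_lstm" in loaded.metadata["deviations"]

    def test_alphabet_drift_is_hard_error(self, tmp_path):
        pm.save_model(pm.build_cnn(), tmp_path / "m")
        wrong = tuple(reversed(pm.DEFAULT_ALPHABET.symbols))
        with pytest.raises(ValidationError, match="alphabet"):
            pm.load_model(tmp_path / "m", expect_alphabet=wrong)

    def test_max_len_drift_is_hard_error(self, tmp_path):
        pm.save_model(pm.build_cnn(), tmp_path / "m")
        with pytest.raises(ValidationError, match="max_len"):
            pm.load_model(tmp_path / "m", expect_max_len=90)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            pm.load_model(tmp_path / "nowhere")
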