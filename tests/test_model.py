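"""CNN+IndRNN classifier: recurrence semantics, gradients, training contracts."""

import numpy as np
import pytest

import mirlnc as m
from mirlnc import nn
from mirlnc.dataset import EncodedPairBatch
from mirlnc.model import ModelConfigError, build_network


def tiny_batch(n=24, width=64, seed=0):
    rng = np.random.default_rng(seed)
    tokens = rng.integers(1, 5, size=(n, width))
    labels = (np.arange(n) % 2).astype(np.int64)
    return EncodedPairBatch(tokens, np.full(n, width), labels, width)


def tiny_config(**kw):
    base = dict(embed_dim=4, conv_blocks=((4, 4, 2), (4, 4, 2)), indrnn_units=(4, 4),
                batch_size=8, epochs=2, dropout=0.0, dtype="float64", seed=0)
    base.update(kw)
    return m.ModelConfig(**base)


class TestIndRnnForward:
    def test_zero_recurrence_equals_feedforward(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 3, 4))
        W = rng.normal(size=(4, 6))
        b = rng.normal(size=6)
        out = nn.indrnn_forward(x, W, np.zeros(6), b)
        for t in range(5):
            np.testing.assert_allclose(out[t], np.maximum(x[t] @ W + b, 0))

    def test_pure_carry_identity_activation(self):
        x = np.zeros((7, 2, 3))
        W = np.zeros((3, 4))
        out = nn.indrnn_forward(x, W, np.ones(4), np.zeros(4),
                                activation=lambda z: z, h0=np.full((2, 4), 3.0))
        np.testing.assert_allclose(out[-1], 3.0)

    def test_geometric_decay_closed_form(self):
        x = np.zeros((10, 1, 2))
        W = np.zeros((2, 3))
        out = nn.indrnn_forward(x, W, np.full(3, 0.5), np.zeros(3),
                                activation=lambda z: z, h0=np.ones((1, 3)))
        for t in range(10):
            np.testing.assert_allclose(out[t], 2.0 ** -(t + 1))

    def test_vectorized_layer_matches_per_neuron_scalar_loop(self):
        """The batched IndRNN layer must equal an explicit per-neuron recurrence."""
        rng = np.random.default_rng(1)
        B, T, C, H = 3, 6, 5, 4
        x = rng.normal(size=(B, T, C))
        layer = nn.IndRNN(C, H, rng, use_bn=False)
        out = layer.forward(x, train=False)
        W, u, b = layer.params["W"], layer.params["u"], layer.params["b"]
        for bi in range(B):
            for n in range(H):
                h = 0.0
                for t in range(T):
                    a = float(x[bi, t] @ W[:, n]) + u[n] * h + b[n]
                    h = max(a, 0.0)
                    assert out[bi, t, n] == pytest.approx(h, rel=1e-12)

    def test_recurrent_gradient_bounded_by_clip(self):
        # with |u| <= 1 and identity-like propagation, d h_T / d h_0 = prod u <= 1
        u = np.random.default_rng(2).uniform(-1, 1, size=8)
        T = 12
        jac = u ** T
        assert np.all(np.abs(jac) <= 1.0)


class TestGradients:
    def test_numeric_gradient_check(self):
        """Analytic backprop of the full stack matches central differences."""
        batch = tiny_batch()
        model = m.CnnIndRnnModel(batch, tiny_config())
        net = model.network
        tokens, labels = batch.tokens, batch.labels

        def loss_fn():
            logits = net.forward(tokens, train=True)
            loss, _ = nn.bce_loss(nn.sigmoid(logits[:, 0]), labels)
            return loss

        # analytic grads (BN batch stats are deterministic given inputs)
        logits = net.forward(tokens, train=True)
        probs = nn.sigmoid(logits[:, 0])
        _, dlogit = nn.bce_loss(probs, labels)
        net.backward(dlogit[:, None])
        eps = 1e-6
        rng = np.random.default_rng(3)
        checked = 0
        for layer, name, p in net.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_fn()
                flat[idx] = orig - eps
                lm = loss_fn()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = g.reshape(-1)[idx]
                assert num == pytest.approx(ana, rel=2e-4, abs=2e-6), (name, idx)
                checked += 1
        assert checked >= 20


class TestBuildAndPredict:
    def test_probabilities_in_unit_interval(self):
        batch = tiny_batch()
        model = m.CnnIndRnnModel(batch, tiny_config())
        probs = model.predict_probs(batch.tokens)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_seeded_init_identical(self):
        batch = tiny_batch()
        a = m.CnnIndRnnModel(batch, tiny_config())
        b = m.CnnIndRnnModel(batch, tiny_config())
        for (l1, n1, p1), (l2, n2, p2) in zip(a.network.parameters(), b.network.parameters()):
            np.testing.assert_array_equal(p1, p2)

    def test_parameter_count_stable(self):
        batch = tiny_batch()
        n1 = m.CnnIndRnnModel(batch, tiny_config()).network.n_parameters()
        n2 = m.CnnIndRnnModel(batch, tiny_config(seed=9)).network.n_parameters()
        assert n1 == n2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ModelConfigError):
            tiny_config(dropout=1.0)
        with pytest.raises(ModelConfigError):
            tiny_config(conv_blocks=((4, 4, 2),))
        with pytest.raises(ModelConfigError):
            tiny_config(optimizer="adamw")

    def test_input_too_short_for_stack(self):
        with pytest.raises(ModelConfigError):
            build_network(tiny_config(), input_len=4)

    def test_predict_deterministic_dropout_off(self):
        batch = tiny_batch()
        model = m.CnnIndRnnModel(batch, tiny_config(dropout=0.5))
        res = model.fit(epochs=1)
        p1 = res.predict(batch.tokens)
        p2 = res.predict(batch.tokens)
        np.testing.assert_array_equal(p1, p2)

    def test_duplicate_rows_identical_probs(self):
        batch = tiny_batch()
        model = m.CnnIndRnnModel(batch, tiny_config())
        dup = np.vstack([batch.tokens[:1], batch.tokens[:1]])
        probs = model.predict_probs(dup)
        assert probs[0] == probs[1]


class TestTraining:
    def test_zero_epochs_leaves_model_unchanged(self):
        batch = tiny_batch()
        model = m.CnnIndRnnModel(batch, tiny_config())
        before = [p.copy() for _, _, p in model.network.parameters()]
        model.fit(epochs=0)
        after = [p for _, _, p in model.network.parameters()]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_same_seed_same_data_identical_loss(self):
        batch = tiny_batch()
        r1 = m.CnnIndRnnModel(batch, tiny_config(dropout=0.5)).fit(epochs=3)
        r2 = m.CnnIndRnnModel(batch, tiny_config(dropout=0.5)).fit(epochs=3)
        assert r1.history.loss.tolist() == r2.history.loss.tolist()

    def test_recurrent_weights_clipped_after_training(self):
        batch = tiny_batch()
        cfg = tiny_config(recurrent_clip=0.7, epochs=3, optimizer="adam", learning_rate=0.05)
        model = m.CnnIndRnnModel(batch, cfg)
        model.fit()
        for layer in model.network.layers:
            if isinstance(layer, nn.IndRNN):
                assert np.all(np.abs(layer.params["u"]) <= 0.7 + 1e-12)

    def test_learns_planted_signal(self):
        """A noiseless planted-site dataset is learnable to >= 0.95 train
        accuracy within 20 epochs."""
        cfg = m.SynthConfig(n_mirna=8, n_lncrna=120, n_positive=100, n_negative=100,
                            lncrna_len_range=(100, 200), site_mutation_rate=0.0, seed=3)
        recs, pairs, _ = m.make_dataset(cfg)
        seqmap = {r.id: r for r in recs}
        batch = m.encode_pairs(pairs, seqmap)
        mc = m.ModelConfig(embed_dim=16, conv_blocks=((16, 8, 4), (32, 8, 4)),
                           indrnn_units=(32, 32), optimizer="adam", learning_rate=0.01,
                           batch_size=32, epochs=20, seed=0, dtype="float32")
        res = m.CnnIndRnnModel(batch, mc).fit()
        assert res.history.train_accuracy.max() >= 0.95

    def test_summary_mentions_architecture(self):
        batch = tiny_batch()
        res = m.CnnIndRnnModel(batch, tiny_config()).fit(epochs=1)
        text = res.summary()
        assert "IndRNN" in text and "parameters" in text
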