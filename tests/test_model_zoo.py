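"""Architecture grammar, gradients, training behaviour and prediction."""

import numpy as np
import pytest

from zdnapred import _nn, model_zoo
from zdnapred.model_zoo import (
    BEST_CNN_SPEC,
    BEST_RNN_SPEC,
    ConvBlock,
    DenseBlock,
    ModelSpec,
    RecurrentBlock,
    TrainOptions,
    enumerate_grid,
    receptive_field,
)
from zdnapred.features import FeatureMatrix
from zdnapred.dataset import tile_and_select
from zdnapred.sparse_store import from_dense


class TestGrammar:
    def test_dense_must_be_last_and_unique(self):
        with pytest.raises(ValueError):
            ModelSpec((DenseBlock(), ConvBlock()))
        with pytest.raises(ValueError):
            ModelSpec((DenseBlock(), DenseBlock()))
        with pytest.raises(ValueError):
            ModelSpec((ConvBlock(),))

    def test_hybrid_order_enforced(self):
        ModelSpec((ConvBlock(), RecurrentBlock(), DenseBlock()))  # valid
        with pytest.raises(ValueError):
            ModelSpec((RecurrentBlock(), ConvBlock(), DenseBlock()))

    def test_kernel_constraints(self):
        with pytest.raises(ValueError):
            ConvBlock(kernel_size=4)  # even
        with pytest.raises(ValueError):
            ConvBlock(kernel_size=19)  # outside 1..17
        with pytest.raises(ValueError):
            ConvBlock(n_kernels=0)

    def test_reference_architectures_expressible(self):
        # best RNN: two bidirectional LSTMs + two dense layers with dropouts
        rec = BEST_RNN_SPEC.blocks[0]
        assert rec.n_layers == 2 and rec.bidirectional
        assert BEST_RNN_SPEC.blocks[1].n_layers == 2
        assert BEST_RNN_SPEC.blocks[1].dropout == 0.5
        # best CNN: 1 conv layer with 3 kernels + 1 dense layer
        conv = BEST_CNN_SPEC.blocks[0]
        assert conv.n_layers == 1 and conv.n_kernels == 3
        assert BEST_CNN_SPEC.blocks[1].n_layers == 1

    def test_spec_dict_roundtrip(self):
        for spec in (BEST_CNN_SPEC, BEST_RNN_SPEC):
            assert ModelSpec.from_dict(spec.to_dict()) == spec


class TestGrid:
    def test_cartesian_product_count(self):
        grid = {"cnn": {"conv_layers": [1, 2], "conv_kernels": [3, 5]}}
        assert len(enumerate_grid(grid)) == 4

    def test_deterministic_and_deduplicated(self):
        grid = {
            "cnn": {"conv_kernels": [3, 3, 5]},
            "rnn": {"hidden_sizes": [32], "bidirectional": [True]},
        }
        a = enumerate_grid(grid)
        assert a == enumerate_grid(grid)
        assert len(a) == len(set(a))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid({})


class TestReceptiveField:
    @pytest.mark.parametrize(
        "n_layers, kernel, expected",
        [(2, 5, 9), (1, 3, 3), (2, 17, 33), (1, 1, 1)],
    )
    def test_formula(self, n_layers, kernel, expected):
        spec = ModelSpec((ConvBlock(n_layers, 4, kernel), DenseBlock()))
        assert receptive_field(spec) == expected

    def test_recurrent_unbounded(self):
        with pytest.raises(ValueError, match="recurrent"):
            receptive_field(BEST_RNN_SPEC)


class TestGradients:
    """Analytic backward passes against central differences."""

    def _check(self, net, in_channels, length, rng):
        x = rng.normal(0.0, 1.0, (in_channels, length))
        y = rng.integers(0, 2, length)

        def loss_of():
            return _nn.cross_entropy(net.forward(x, train=False), y)[0]

        _, dlogits = _nn.cross_entropy(net.forward(x, train=False), y)
        net.zero_grad()
        dx = net.backward(dlogits)
        eps = 1e-6
        for p in net.params():
            for _ in range(3):
                idx = np.unravel_index(rng.integers(0, p.value.size), p.value.shape)
                old = p.value[idx]
                p.value[idx] = old + eps
                lp = loss_of()
                p.value[idx] = old - eps
                lm = loss_of()
                p.value[idx] = old
                assert abs((lp - lm) / (2 * eps) - p.grad[idx]) < 1e-6
        i, t = rng.integers(0, in_channels), rng.integers(0, length)
        old = x[i, t]
        x[i, t] = old + eps
        lp = loss_of()
        x[i, t] = old - eps
        lm = loss_of()
        x[i, t] = old
        assert abs((lp - lm) / (2 * eps) - dx[i, t]) < 1e-6

    def test_conv_dense_stack(self, rng):
        net = _nn.Sequential(
            [_nn.Conv1d(3, 4, 5, rng), _nn.ReLU(), _nn.Linear(4, 2, rng)]
        )
        self._check(net, 3, 11, rng)

    def test_bilstm_stack(self, rng):
        net = _nn.Sequential([_nn.LSTM(3, 4, rng, True), _nn.Linear(8, 2, rng)])
        self._check(net, 3, 9, rng)

    def test_unidirectional_lstm(self, rng):
        net = _nn.Sequential([_nn.LSTM(2, 3, rng, False), _nn.Linear(3, 2, rng)])
        self._check(net, 2, 7, rng)


def _separable_setup(length=4000, window=500):
    """One marker channel equal to the label track: linearly separable."""
    rng = np.random.default_rng(0)
    label = (rng.random(length) < 0.3).astype(float)
    # widen into short blocks so windows mix both classes
    fm = FeatureMatrix(
        "chr1",
        length,
        [("marker:m", from_dense(label)), ("noise", from_dense(rng.random(length).round(2)))],
    )
    store = {"chr1": fm}
    labels = {"chr1": from_dense(label)}
    ws = tile_and_select(labels, window, 3, seed=0)
    return store, labels, ws


class TestTraining:
    def test_separable_fixture_reaches_high_f1(self):
        store, labels, ws = _separable_setup()
        model = model_zoo.train(
            BEST_CNN_SPEC, ws, store, labels,
            opts=TrainOptions(epochs=120, learning_rate=1e-2, batch_size=4),
            seed=0,
        )
        from sklearn.metrics import f1_score

        probs = np.concatenate(
            [model.predict(store[w.chromosome], w.start, w.end) for w in ws.windows]
        )
        labs = np.concatenate(
            [labels[w.chromosome].slice(w.start, w.end) for w in ws.windows]
        )
        assert f1_score(labs, probs > 0.5) > 0.95

    def test_seed_determinism(self):
        store, labels, ws = _separable_setup(length=2000)
        opts = TrainOptions(epochs=5)
        a = model_zoo.train(BEST_CNN_SPEC, ws, store, labels, opts=opts, seed=3)
        b = model_zoo.train(BEST_CNN_SPEC, ws, store, labels, opts=opts, seed=3)
        assert a.training_log[-1]["loss"] == b.training_log[-1]["loss"]
        for pa, pb in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_loss_decreases_on_separable_fixture(self):
        store, labels, ws = _separable_setup(length=2000)
        model = model_zoo.train(
            BEST_CNN_SPEC, ws, store, labels, opts=TrainOptions(epochs=10), seed=0
        )
        losses = [e["loss"] for e in model.training_log]
        assert losses[-1] < losses[0]

    def test_empty_train_split_rejected(self):
        store, labels, ws = _separable_setup(length=2000)
        empty = ws.__class__(ws.windows, ws.window_length, ws.seed,
                             split={i: "test" for i in range(len(ws))})
        with pytest.raises(ValueError, match="empty train"):
            model_zoo.train(BEST_CNN_SPEC, empty, store, labels)

    def test_rnn_and_hybrid_train_smoke(self):
        store, labels, ws = _separable_setup(length=1200, window=200)
        for spec in (
            ModelSpec((RecurrentBlock(1, 8, True), DenseBlock())),
            ModelSpec((ConvBlock(1, 4, 3), RecurrentBlock(1, 8, False), DenseBlock(2, 8))),
        ):
            model = model_zoo.train(
                spec, ws, store, labels, opts=TrainOptions(epochs=2), seed=0
            )
            probs = model.predict_window(store["chr1"].dense(0, 200))
            assert probs.shape == (200,)
            assert probs.min() >= 0.0 and probs.max() <= 1.0


class TestPredict:
    def test_chunked_equals_single_pass(self, recovery_model, default_fixture):
        fm = default_fixture["store"]["chr1"]
        whole = model_zoo.predict(recovery_model, fm, 0, 30_000, chunk=200_000)
        chunked = model_zoo.predict(recovery_model, fm, 0, 30_000, chunk=7_000)
        np.testing.assert_array_equal(whole, chunked)

    def test_probability_bounds_and_two_class_normalization(self, recovery_model, default_fixture):
        fm = default_fixture["store"]["chr1"]
        both = recovery_model.predict_window(fm.dense(0, 2000), both_classes=True)
        np.testing.assert_allclose(both.sum(axis=0), 1.0, atol=1e-12)
        assert both.min() >= 0.0

    def test_all_zero_input_constant_output(self, recovery_model):
        x = np.zeros((len(recovery_model.channel_names), 300))
        probs = recovery_model.predict_window(x)
        assert np.ptp(probs[10:-10]) < 1e-12  # away from padding edges

    def test_channel_mismatch_rejected(self, recovery_model):
        fm = FeatureMatrix("chr1", 10, [("other", from_dense(np.ones(10)))])
        with pytest.raises(ValueError, match="channels"):
            model_zoo.predict(recovery_model, fm, 0, 10)


def test_checkpoint_roundtrip(tmp_path, recovery_model, default_fixture):
    path = tmp_path / "model.npz"
    model_zoo.save_model(recovery_model, path)
    loaded = model_zoo.load_model(path)
    assert loaded.spec == recovery_model.spec
    assert loaded.channel_names == recovery_model.channel_names
    fm = default_fixture["store"]["chr2"]
    np.testing.assert_array_equal(
        loaded.predict(fm, 0, 3000), recovery_model.predict(fm, 0, 3000)
    )
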