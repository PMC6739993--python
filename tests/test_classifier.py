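"""Segment classifiers: architecture, gradients, training, mask aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ucpwi import nn
from ucpwi.classifier import (
    BubbleMask,
    TrainConfig,
    UNetConfig,
    build_cnn,
    build_model,
    build_rnn,
    build_unet,
    count_parameters,
    load_checkpoint,
    predict_mask,
    save_checkpoint,
    train,
)
from ucpwi.rf_sim import ChannelData, ProbeGeometry, make_training_corpus


class TestArchitecture:
    def test_unet_parameter_checksum(self):
        """The default channel plan reproduces the 607,112-parameter total."""
        assert count_parameters(build_unet()) == 607_112

    def test_layer_inventory(self):
        m = build_unet()
        n_conv = sum(1 for layer in m._layers if isinstance(layer, nn.Conv1D))
        assert n_conv == 14
        assert len(m.pools) == 3 and len(m.ups) == 3 and len(m.drops) == 4
        assert isinstance(m.head, nn.Dense)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(base_filters=(32, 64))
        with pytest.raises(ValueError):
            UNetConfig(dropout_rate=1.5)

    def test_same_seed_identical_weights(self):
        a, b = build_unet(seed=3), build_unet(seed=3)
        assert all(np.array_equal(p.value, q.value) for p, q in zip(a.params(), b.params()))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_model("transformer")

    @pytest.mark.parametrize("builder", [build_unet, build_cnn, build_rnn])
    def test_batched_softmax_simplex(self, builder):
        model = builder(seed=0)
        x = np.random.default_rng(0).normal(size=(7, 60)).astype(np.float32)
        p = model.predict_proba(x)
        assert p.shape == (7, 2)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_softmax_simplex_property(self, seed):
        logits = np.random.default_rng(seed).normal(scale=30, size=(5, 2))
        p = nn.softmax(logits)
        assert np.all((p >= 0) & (p <= 1))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestGradients:
    """Backward passes checked against double-precision finite differences."""

    def _directional_check(self, model, x, y, h=1e-6, tol=1e-6):
        _, d = nn.cross_entropy(model.forward(x, training=False), y)
        for p in model.params():
            p.grad[...] = 0
        model.backward(d)
        rng = np.random.default_rng(9)
        dirs = [rng.normal(size=p.value.shape) for p in model.params()]
        # perturb weights only: zero-initialised biases sit exactly on ReLU
        # kinks where one-sided finite differences are expected to disagree
        for p, u in zip(model.params(), dirs):
            if p.value.ndim == 1:
                u[...] = 0
        gdot = sum(float(np.vdot(p.grad, u)) for p, u in zip(model.params(), dirs))
        for p, u in zip(model.params(), dirs):
            p.value += h * u
        lp = nn.cross_entropy(model.forward(x, training=False), y)[0]
        for p, u in zip(model.params(), dirs):
            p.value -= 2 * h * u
        lm = nn.cross_entropy(model.forward(x, training=False), y)[0]
        num = (lp - lm) / (2 * h)
        assert abs(num - gdot) / (abs(num) + abs(gdot)) < tol

    @pytest.mark.parametrize("kind", ["unet", "cnn", "rnn"])
    def test_backprop_matches_finite_differences(self, kind, monkeypatch):
        monkeypatch.setattr(nn, "F32", np.float64)
        if kind == "unet":
            cfg = UNetConfig(
                base_filters=(2, 3, 4), bottleneck_filters=5, up_filters=(4, 3, 2),
                dropout_rate=0.0,
            )
            model = build_unet(cfg, seed=3)
        else:
            model = build_model(kind, seed=3)
            model.drop.rate = 0.0
        x = np.random.default_rng(5).normal(size=(4, 60))
        y = np.array([0, 1, 1, 0])
        self._directional_check(model, x, y)

    def test_adam_decreases_loss_on_quadratic(self):
        p = nn.Param(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            p.grad[...] = 2 * p.value
            opt.step()
        assert np.all(np.abs(p.value) < 0.1)


class TestTraining:
    def test_single_batch_overfit(self, training_corpus):
        """200 epochs on 100 segments drive training accuracy to ~1."""
        small = training_corpus.train.take(np.arange(100))
        small.subset = np.zeros(100, dtype=np.int8)
        ds = type(training_corpus)(
            segments=np.concatenate([small.segments, small.segments]),
            labels=np.concatenate([small.labels, small.labels]),
            provenance=np.concatenate([small.provenance, small.provenance]),
            background_frac=np.concatenate([small.background_frac] * 2),
            subset=np.concatenate([np.zeros(100, dtype=np.int8), np.ones(100, dtype=np.int8)]),
        )
        model = build_unet(seed=1)
        model, history = train(model, ds, TrainConfig(epochs=200, lr=1e-3, seed=1))
        assert history["train_acc"][-1] >= 0.99

    def test_shuffled_labels_give_chance_accuracy(self, training_corpus):
        """Labels shuffled against segments: held-out accuracy ~ 0.5."""
        rng = np.random.default_rng(0)
        tr_idx = rng.choice(np.flatnonzero(training_corpus.subset == 0), 2000, replace=False)
        # balanced 50/50 test set so any degenerate predictor scores 0.5
        te_pool = np.flatnonzero(training_corpus.subset == 1)
        te_b = te_pool[training_corpus.labels[te_pool] == 1][:500]
        te_t = te_pool[training_corpus.labels[te_pool] == 0][:500]
        idx = np.concatenate([tr_idx, te_b, te_t])
        ds = training_corpus.take(idx)
        ds.subset = np.concatenate([np.zeros(2000, dtype=np.int8), np.ones(1000, dtype=np.int8)])
        ds.labels = ds.labels.copy()
        ds.labels[:2000] = rng.permutation(ds.labels[:2000])
        if len(np.unique(ds.labels[:2000])) < 2:  # pragma: no cover
            pytest.skip("degenerate shuffle")
        model = build_unet(seed=2)
        model, history = train(model, ds, TrainConfig.fast(epochs=3, seed=2))
        assert history["final_test_acc"] == pytest.approx(0.5, abs=0.05)

    def test_degenerate_dataset_rejected(self, training_corpus):
        ds = training_corpus.take(np.flatnonzero(training_corpus.labels == 1)[:200])
        ds.subset = np.concatenate([np.zeros(150, dtype=np.int8), np.ones(50, dtype=np.int8)])
        with pytest.raises(ValueError, match="degenerate"):
            train(build_unet(seed=0), ds, TrainConfig.fast(epochs=1))

    def test_fast_profile_capped(self):
        with pytest.raises(ValueError):
            TrainConfig.fast(epochs=25)


class _ConstantModel:
    """Stub emitting a constant bubble probability."""

    trained = True

    def __init__(self, p1):
        self.p1 = p1

    def predict_proba(self, segments, batch_size=1024):
        out = np.full((len(segments), 2), 1 - self.p1)
        out[:, 1] = self.p1
        return out


class TestPredictMask:
    @pytest.fixture
    def frame(self):
        g = ProbeGeometry(n_elements=4)
        rf = np.random.default_rng(0).normal(size=(300, 4)).astype(np.float32)
        return ChannelData(rf=rf, geometry=g, f_transmit=4e6)

    def test_constant_one_gives_all_ones(self, frame):
        mask = predict_mask(_ConstantModel(1.0), frame, require_trained=False)
        assert np.all(mask.mask == 1)
        assert np.allclose(mask.prob, 1.0)

    def test_mask_matches_threshold(self, frame):
        mask = predict_mask(_ConstantModel(0.4), frame, require_trained=False)
        assert np.all(mask.mask == 0)

    def test_single_segment_line_constant_over_span(self):
        g = ProbeGeometry(n_elements=2)
        rf = np.random.default_rng(1).normal(size=(60, 2)).astype(np.float32)
        frame = ChannelData(rf=rf, geometry=g, f_transmit=4e6)
        mask = predict_mask(_ConstantModel(0.9), frame, require_trained=False)
        assert np.allclose(mask.prob, 0.9)

    def test_untrained_model_flagged(self, frame):
        model = build_unet(seed=0)
        with pytest.raises(ValueError, match="trained"):
            predict_mask(model, frame)

    def test_aggregation_permutation_invariant(self, frame):
        """Mean aggregation does not depend on segment visit order."""

        class _SeededModel(_ConstantModel):
            def __init__(self):
                self.rng = np.random.default_rng(3)

            def predict_proba(self, segments, batch_size=1024):
                # deterministic per-segment score derived from content
                s = np.abs(segments).sum(axis=1)
                p1 = (np.sin(s) + 1) / 2
                return np.column_stack([1 - p1, p1])

        m = _SeededModel()
        a = predict_mask(m, frame, require_trained=False)
        b = predict_mask(m, frame, require_trained=False)
        assert np.array_equal(a.prob, b.prob)

    def test_mask_shape_contract(self):
        with pytest.raises(ValueError):
            BubbleMask(mask=np.zeros((3, 3)), prob=np.zeros((4, 4)))


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        model = build_unet(seed=4)
        model.trained = True
        path = tmp_path / "model.npz"
        save_checkpoint(model, str(path))
        loaded = load_checkpoint(str(path))
        x = np.random.default_rng(0).normal(size=(3, 60)).astype(np.float32)
        assert np.allclose(model.predict_proba(x), loaded.predict_proba(x))
        assert loaded.count_parameters() == 607_112
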