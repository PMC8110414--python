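"""Architecture contracts: shapes, softmax, residual identity,
deterministic initialization and backprop correctness."""

import numpy as np
import pytest

from ecgresnet.model import (
    Conv1d,
    MaxPool1d,
    Model,
    ModelSpec,
    ReLU,
    ResidualBlock,
    Sequential,
    build_model,
    softmax,
)

TINY = ModelSpec(
    input_length=32,
    initial_filters=2,
    initial_kernel=5,
    initial_stride=1,
    residual_kernel=3,
    n_improved_stages=1,
    filter_schedule=(4,),
    dropout_rate=0.0,
)


class TestSoftmax:
    def test_uniform_logits(self):
        np.testing.assert_allclose(softmax(np.zeros((1, 5))), np.full((1, 5), 0.2))

    def test_shift_invariance(self, rng):
        lg = rng.standard_normal((3, 5))
        np.testing.assert_allclose(softmax(lg), softmax(lg + 123.4), atol=1e-12)

    def test_log_ratio_logits(self):
        lg = np.log([[1.0, 2.0, 3.0, 4.0, 10.0]])
        np.testing.assert_allclose(
            softmax(lg), [[0.05, 0.10, 0.15, 0.20, 0.50]], atol=1e-12
        )


class TestBuildModel:
    def test_forward_shape_and_normalization_default_spec(self, rng):
        m = build_model(ModelSpec(), seed=0)
        p = m.forward(rng.standard_normal((4, 1080)))
        assert p.shape == (4, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert ((p > 0) & (p <= 1)).all()

    def test_same_seed_same_weights(self):
        a = build_model(TINY, seed=42)
        b = build_model(TINY, seed=42)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_different_seed_different_weights(self):
        a = build_model(TINY, seed=1)
        b = build_model(TINY, seed=2)
        assert any(
            not np.array_equal(pa.value, pb.value)
            for pa, pb in zip(a.parameters(), b.parameters())
        )

    def test_parameter_count_stable(self):
        n = build_model(ModelSpec(), seed=0).n_parameters()
        assert n == build_model(ModelSpec(), seed=5).n_parameters()
        assert n > 0

    def test_eval_forward_deterministic_despite_dropout(self, rng):
        spec = ModelSpec(
            input_length=32, initial_filters=2, initial_kernel=5,
            initial_stride=1, residual_kernel=3, n_improved_stages=1,
            filter_schedule=(4,), dropout_rate=0.5,
        )
        m = build_model(spec, seed=0)
        X = rng.standard_normal((3, 32))
        np.testing.assert_array_equal(m.forward(X), m.forward(X))

    def test_inconsistent_schedule_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(n_improved_stages=3, filter_schedule=(12, 24))
        with pytest.raises(ValueError):
            ModelSpec(filter_schedule=(12, 12, 24, 24, 48, 24, 96))

    def test_wrong_input_length_rejected(self, rng):
        m = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            m.forward(rng.standard_normal((2, 33)))

    def test_state_round_trip(self, rng):
        m = build_model(TINY, seed=0)
        X = rng.standard_normal((2, 32))
        before = m.forward(X)
        state = m.state()
        for p in m.parameters():
            p.value += 1.0
        m.load_state(state)
        np.testing.assert_array_equal(m.forward(X), before)


class TestResidualBlock:
    def test_zeroed_branch_identity(self, rng):
        branch = Sequential([
            Conv1d(3, 3, 3, rng=rng, name="c1"), ReLU(),
            Conv1d(3, 3, 3, rng=rng, name="c2"),
        ])
        for p in branch.params():
            p.value[...] = 0.0
        block = ResidualBlock(branch, shortcut=None)
        x = np.random.default_rng(0).standard_normal((2, 3, 16))
        np.testing.assert_array_equal(block.forward(x, training=False), x)

    def test_projection_changes_channels(self, rng):
        branch = Sequential([
            Conv1d(12, 24, 3, stride=2, rng=rng, name="c1"), ReLU(),
            Conv1d(24, 24, 3, rng=rng, name="c2"),
        ])
        block = ResidualBlock(branch, Conv1d(12, 24, 1, stride=2, rng=rng, name="p"))
        x = np.random.default_rng(0).standard_normal((2, 12, 16))
        y = block.forward(x, training=False)
        assert y.shape == (2, 24, 8)

    def test_shape_mismatch_without_projection_rejected(self, rng):
        branch = Sequential([Conv1d(3, 6, 3, rng=rng, name="c")])
        block = ResidualBlock(branch, shortcut=None)
        with pytest.raises(ValueError, match="projection"):
            block.forward(np.zeros((1, 3, 8)), training=False)

    def test_single_tap_convolution_arithmetic(self):
        # length-8 single-channel input, 1-tap kernels set by hand:
        # branch doubles then triples -> 6x; identity shortcut adds x
        rng = np.random.default_rng(0)
        c1 = Conv1d(1, 1, 1, rng=rng, name="c1")
        c2 = Conv1d(1, 1, 1, rng=rng, name="c2")
        c1.w.value[...] = 2.0
        c2.w.value[...] = 3.0
        c1.b.value[...] = 0.0
        c2.b.value[...] = 0.0
        block = ResidualBlock(Sequential([c1, ReLU(), c2]), shortcut=None)
        x = np.arange(1.0, 9.0)[None, None, :]
        np.testing.assert_allclose(block.forward(x, training=False), 7.0 * x)


class TestMaxPoolShortcut:
    def test_same_length_stride_one(self):
        pool = MaxPool1d(3, stride=1)
        x = np.random.default_rng(0).standard_normal((2, 4, 20))
        assert pool.forward(x, training=False).shape == x.shape

    def test_region_maximum(self):
        pool = MaxPool1d(3, stride=3)
        x = np.array([[[1.0, 5.0, 2.0, -1.0, 0.0, -2.0]]])
        np.testing.assert_array_equal(
            pool.forward(x, training=False), [[[5.0, 0.0]]]
        )


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        m = build_model(TINY, seed=3)
        rng = np.random.default_rng(1)
        # move biases off zero: at exact-zero biases some ReLU inputs sit
        # exactly on the kink and two-sided differences are ill-defined
        for p in m.parameters():
            if p.name.endswith(".b") or p.name.endswith(".beta"):
                p.value[...] = 0.1 * rng.standard_normal(p.value.shape)
        X = rng.standard_normal((4, 32))
        y = np.eye(5)[rng.integers(0, 5, 4)]

        def objective():
            p = softmax(m.forward_logits(X, training=True))
            return -np.mean(np.sum(y * np.log(np.clip(p, 1e-12, 1)), axis=1))

        m.zero_grad()
        p = softmax(m.forward_logits(X, training=True))
        m.backward((p - y) / len(X))
        for prm in m.parameters():
            flat = prm.value.reshape(-1)
            gflat = prm.grad.reshape(-1)
            idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + 1e-6
                up = objective()
                flat[i] = orig - 1e-6
                dn = objective()
                flat[i] = orig
                numeric = (up - dn) / 2e-6
                assert gflat[i] == pytest.approx(numeric, rel=1e-4, abs=1e-7), prm.name
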