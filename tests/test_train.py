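import numpy as np
import pytest

from lcnet.dataio import ImageRecord, Label
from lcnet.layers import Param
from lcnet.train import (
    CLASS_ORDER,
    TrainConfig,
    TrainHistory,
    class_weights,
    sgdm_step,
    train,
    weighted_cross_entropy,
)


class TestClassWeights:
    def test_balanced_unit_weights(self):
        w = class_weights({Label.MEL: 692, Label.BEN: 692})
        np.testing.assert_allclose(w, [1.0, 1.0])

    def test_inverse_frequency(self):
        w = class_weights({Label.MEL: 100, Label.BEN: 300})
        np.testing.assert_allclose(w, [2.0, 400 / 600], rtol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights({Label.MEL: 10})

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights({Label.MEL: 0, Label.BEN: 5})


class TestWeightedCrossEntropy:
    def test_perfect_predictions_near_zero(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        t = p.copy()
        assert weighted_cross_entropy(p, t, np.ones(2)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction(self):
        loss = weighted_cross_entropy(
            np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]), np.ones(2)
        )
        assert loss == pytest.approx(np.log(2), abs=1e-10)

    def test_linear_in_weights(self, rng):
        p = rng.dirichlet(np.ones(2), size=6)
        t = np.eye(2)[rng.integers(0, 2, 6)]
        w = rng.uniform(0.5, 2.0, 2)
        assert weighted_cross_entropy(p, t, 2 * w) == pytest.approx(
            2 * weighted_cross_entropy(p, t, w), rel=1e-12
        )

    def test_matches_per_sample_oracle(self, rng):
        """Vectorized loss equals an explicit per-sample double sum."""
        n, k = 13, 2
        p = rng.dirichlet(np.ones(k), size=n)
        t = np.eye(k)[rng.integers(0, k, n)]
        w = rng.uniform(0.2, 3.0, k)
        oracle = 0.0
        for i in range(n):
            for j in range(k):
                oracle -= w[j] * t[i, j] * np.log(max(p[i, j], 1e-12))
        oracle /= n
        assert weighted_cross_entropy(p, t, w) == pytest.approx(oracle, abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            weighted_cross_entropy(np.ones((2, 2)), np.ones((3, 2)), np.ones(2))


class TestSgdmStep:
    def test_decay_only(self):
        cfg = TrainConfig()
        theta, v = sgdm_step(np.array([1.0]), np.array([0.0]), np.array([0.0]), cfg)
        assert theta[0] == pytest.approx(1.0 - cfg.learning_rate * cfg.weight_decay, rel=1e-12)

    def test_reduces_to_plain_sgd(self):
        cfg = TrainConfig(momentum=0.0, weight_decay=0.0)
        theta, _ = sgdm_step(np.array([2.0]), np.array([0.5]), np.array([0.0]), cfg)
        assert theta[0] == pytest.approx(2.0 - 0.001 * 0.5, rel=1e-12)

    def test_two_step_hand_iteration(self):
        cfg = TrainConfig(weight_decay=0.0)  # lr 0.001, momentum 0.99
        theta = np.array([1.0])
        v = np.array([0.0])
        g = np.array([0.5])
        theta, v = sgdm_step(theta, g, v, cfg)
        assert theta[0] == pytest.approx(0.9995, abs=1e-10)
        theta, v = sgdm_step(theta, g, v, cfg)
        assert v[0] == pytest.approx(-0.000995, abs=1e-10)
        assert theta[0] == pytest.approx(0.998505, abs=1e-10)

    def test_nonfinite_gradient_aborts(self):
        with pytest.raises(FloatingPointError):
            sgdm_step(np.array([1.0]), np.array([np.nan]), np.array([0.0]), TrainConfig())

    def test_velocity_accumulates_direction(self):
        cfg = TrainConfig(weight_decay=0.0)
        theta, v = np.array([0.0]), np.array([0.0])
        g = np.array([1.0])
        steps = []
        for _ in range(5):
            prev = theta.copy()
            theta, v = sgdm_step(theta, g, v, cfg)
            steps.append(prev[0] - theta[0])
        assert all(b > a for a, b in zip(steps, steps[1:]))  # momentum accelerates


class _FrozenModel:
    """Stub with constant outputs: exercises the epoch loop mechanics."""

    def __init__(self):
        self._p = Param(np.zeros(1, dtype=np.float32))

    def forward_logits(self, x, training=False):
        return np.zeros((x.shape[0], 2), dtype=np.float32)

    def forward(self, x, training=False):
        return np.full((x.shape[0], 2), 0.5, dtype=np.float32)

    def backward(self, grad):
        return grad

    def params(self):
        return [("p", self._p)]

    def zero_grad(self):
        self._p.grad[...] = 0

    def state_dict(self):
        return {"p": self._p.value.copy()}

    def load_state_dict(self, state):
        self._p.value = state["p"].copy()


def _records(n_mel, n_ben, seed=0, size=128, prefix=""):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_mel):
        px = rng.integers(0, 60, size=(size, size, 3), dtype=np.uint8)
        recs.append(ImageRecord(f"{prefix}m{i}", px, Label.MEL))
    for i in range(n_ben):
        px = rng.integers(180, 256, size=(size, size, 3), dtype=np.uint8)
        recs.append(ImageRecord(f"{prefix}b{i}", px, Label.BEN))
    return recs


class TestTrainLoop:
    def test_patience_one_frozen_model_stops_at_epoch_two(self):
        cfg = TrainConfig(max_epochs=50, early_stop_patience=1, augment=False)
        model = _FrozenModel()
        _, hist = train(model, _records(4, 4, size=8), _records(2, 2, seed=1, size=8, prefix="v_"), cfg)
        assert hist.stopped_epoch == 2
        assert hist.best_epoch == 1

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train(_FrozenModel(), [], _records(1, 1, size=8), TrainConfig())

    def test_train_val_overlap_rejected(self):
        recs = _records(2, 2, size=8)
        with pytest.raises(ValueError, match="overlap"):
            train(_FrozenModel(), recs, recs, TrainConfig())

    def test_history_invariants_frozen(self):
        cfg = TrainConfig(max_epochs=4, early_stop_patience=10, augment=False)
        _, hist = train(_FrozenModel(), _records(3, 3, size=8), _records(1, 1, seed=1, size=8, prefix="v_"), cfg)
        assert hist.stopped_epoch <= cfg.max_epochs
        assert hist.best_epoch <= hist.stopped_epoch
        assert len(hist.train_loss) == len(hist.val_loss) == hist.stopped_epoch

    def test_same_seed_identical_history(self):
        """End-to-end determinism of the full epoch loop on the real network."""
        from lcnet.network import build_config, build_network

        tr, va = _records(5, 5), _records(2, 2, seed=1, prefix="v_")
        cfg = TrainConfig(max_epochs=2, augment=True, seed=3)
        histories = []
        for _ in range(2):
            model = build_network(build_config(), seed=3)
            _, h = train(model, tr, va, cfg)
            histories.append(h)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].val_loss == histories[1].val_loss
        assert histories[0].val_accuracy == histories[1].val_accuracy

    def test_memorization_loss_decreases(self):
        """Train loss falls monotonically over 5 epochs on 10 samples."""
        from lcnet.network import build_config, build_network

        model = build_network(build_config(), seed=0)
        cfg = TrainConfig(max_epochs=5, augment=False, seed=0)
        _, hist = train(model, _records(5, 5), _records(2, 2, seed=1, prefix="v_"), cfg)
        assert all(a > b for a, b in zip(hist.train_loss, hist.train_loss[1:]))
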