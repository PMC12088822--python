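"""Energy-model oracles by exact enumeration, CD statistics, fine-tuning."""

import numpy as np
import pytest

from hdbncaen import hdbn
from hdbncaen.hdbn import (
    HDBNModel, RBMParams, TrainConfig, cd_update, conditionals, energy,
    exact_log_likelihood, exact_partition, extract_features, finetune,
    joint_probability, loss_and_grads, model_expectations, predict_proba,
    pretrain_stack, train_rbm,
)


def _rand_params(n_v, n_h, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    return RBMParams(scale * rng.standard_normal((n_v, n_h)),
                     scale * rng.standard_normal(n_v),
                     scale * rng.standard_normal(n_h))


class TestEnergy:
    def test_zero_params_zero_energy(self):
        p = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert energy(np.ones(3), np.ones(2), p) == 0.0

    def test_single_unit_value(self):
        p = RBMParams(np.array([[1.0]]), np.zeros(1), np.zeros(1))
        assert energy(np.array([1.0]), np.array([1.0]), p) == -1.0

    def test_zero_visible_reduces_to_hidden_bias(self):
        p = _rand_params(3, 2, 0)
        h = np.array([1.0, 1.0])
        assert energy(np.zeros(3), h, p) == pytest.approx(-p.c.sum())

    def test_dimension_mismatch(self):
        p = _rand_params(3, 2, 1)
        with pytest.raises(ValueError):
            energy(np.zeros(2), np.zeros(2), p)


class TestConditionals:
    def test_zero_params_half_probability(self):
        p = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        probs = conditionals(np.ones(3), p, "hidden_given_visible")
        assert np.allclose(probs, 0.5)

    def test_large_bias_saturates(self):
        p = RBMParams(np.zeros((1, 1)), np.zeros(1), np.array([30.0]))
        assert conditionals(np.zeros(1), p, "hidden_given_visible")[0] > 1 - 1e-9

    def test_probabilities_in_unit_interval(self):
        p = _rand_params(4, 3, 2, scale=3.0)
        for d, s in (("hidden_given_visible", np.ones(4)),
                     ("visible_given_hidden", np.ones(3))):
            probs = conditionals(s, p, d)
            assert ((probs >= 0) & (probs <= 1)).all()


class TestPartition:
    def test_zero_params_counts_states(self):
        p = RBMParams(np.zeros((2, 1)), np.zeros(2), np.zeros(1))
        assert exact_partition(p) == pytest.approx(8.0)

    def test_log2_weight_hand_enumeration(self):
        p = RBMParams(np.array([[np.log(2.0)]]), np.zeros(1), np.zeros(1))
        assert exact_partition(p) == pytest.approx(5.0)
        assert joint_probability(np.array([1.0]), np.array([1.0]), p) \
            == pytest.approx(0.4)

    def test_zero_params_uniform_joint(self):
        p = RBMParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1))
        for v in (0.0, 1.0):
            for h in (0.0, 1.0):
                assert joint_probability(np.array([v]), np.array([h]), p) \
                    == pytest.approx(0.25)

    def test_enumeration_guard(self):
        p = RBMParams(np.zeros((15, 6)), np.zeros(15), np.zeros(6))
        with pytest.raises(ValueError):
            exact_partition(p)

    @pytest.mark.parametrize("seed", range(20))
    def test_joint_normalizes_on_random_models(self, seed):
        p = _rand_params(3, 2, seed, scale=1.5)
        total = sum(
            joint_probability(np.array(v, dtype=float), np.array(h, dtype=float), p)
            for v in np.ndindex(2, 2, 2) for h in np.ndindex(2, 2))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestContrastiveDivergence:
    def test_zero_learning_rate_no_change(self):
        p = _rand_params(3, 2, 3)
        rng = np.random.default_rng(0)
        batch = (rng.random((8, 3)) < 0.5).astype(float)
        out = cd_update(p, batch, 1, 0.0, seed=0)
        assert np.array_equal(out.W, p.W)

    def test_expected_update_on_unit_rbm(self):
        # zero-init 1x1 RBM, all-ones batch: E[ΔW] = η(0.5 − 0.25)
        vals = []
        for seed in range(10_000):
            p = RBMParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1))
            vals.append(cd_update(p, np.ones((1, 1)), 1, 1.0, seed).W[0, 0])
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(mean - 0.25) < 3 * se

    def test_long_chain_negative_stats_match_enumeration(self):
        # stationary Gibbs statistics vs exact model moments (oracle)
        p = _rand_params(3, 2, 4, scale=0.8)
        Evh, Ev, Eh = model_expectations(p)
        rng = np.random.default_rng(5)
        starts = (rng.random((4000, 3)) < 0.5).astype(float)
        from hdbncaen.hdbn import _cd_stats
        _, (nW, nb, nc) = _cd_stats(p, starts, 300, rng)
        assert np.abs(nW - Evh).max() < 0.04
        assert np.abs(nb - Ev).max() < 0.04
        assert np.abs(nc - Eh).max() < 0.04

    def test_cd1_training_increases_exact_log_likelihood(self):
        rng = np.random.default_rng(6)
        V = (rng.random((8, 4)) < rng.random(4)).astype(float)
        cfg = TrainConfig(learning_rate=0.05, lr_decay=1.0, epochs=200,
                          batch_size=8, dropout=0.0, seed=6)
        init = RBMParams(np.random.default_rng(1).standard_normal((4, 3)) / 2,
                         np.zeros(4), np.zeros(3))
        trained, _ = train_rbm(V, 3, cfg)
        assert exact_log_likelihood(trained, V) > exact_log_likelihood(init, V)

    def test_exact_gradient_ascent_increases_log_likelihood(self):
        # enumeration-based ML gradient: sign-convention regression test
        rng = np.random.default_rng(7)
        V = (rng.random((6, 3)) < 0.5).astype(float)
        p = _rand_params(3, 2, 8, scale=0.3)
        lls = [exact_log_likelihood(p, V)]
        for _ in range(50):
            Evh, Ev, Eh = model_expectations(p)
            ph = conditionals(V, p, "hidden_given_visible")
            p = RBMParams(p.W + 0.1 * (V.T @ ph / len(V) - Evh),
                          p.b + 0.1 * (V.mean(0) - Ev),
                          p.c + 0.1 * (ph.mean(0) - Eh))
            lls.append(exact_log_likelihood(p, V))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_empty_batch_rejected(self):
        p = _rand_params(2, 2, 9)
        with pytest.raises(ValueError):
            cd_update(p, np.zeros((0, 2)), 1, 0.1, seed=0)


class TestPretrain:
    def test_single_layer_shape(self):
        rng = np.random.default_rng(10)
        X = rng.random((50, 6))
        stack = pretrain_stack(X, [6], TrainConfig(epochs=2, dropout=0.0))
        assert len(stack) == 1 and stack[0].W.shape == (6, 6)

    def test_reconstruction_error_decreases(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            proto = (rng.random((4, 8)) < 0.5).astype(float)
            X = proto[rng.integers(0, 4, 200)]
            X = np.clip(X + 0.05 * rng.standard_normal(X.shape), 0, 1)
            cfg = TrainConfig(learning_rate=0.1, lr_decay=1.0, epochs=30,
                              batch_size=32, dropout=0.0, seed=seed)
            _, hist = train_rbm(X, 6, cfg)
            wins += hist[-1] < hist[0]
        assert wins >= 9

    def test_seed_determinism(self):
        rng = np.random.default_rng(11)
        X = rng.random((40, 5))
        cfg = TrainConfig(epochs=3, dropout=0.0, seed=42)
        a = pretrain_stack(X, [4, 3], cfg)
        b = pretrain_stack(X, [4, 3], cfg)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.W, pb.W)

    def test_invalid_layer_size(self):
        with pytest.raises(ValueError):
            pretrain_stack(np.zeros((5, 3)), [0], TrainConfig())


class TestFinetune:
    def _data(self, seed, n=300, sep=4.0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 4)) + (y - 0.5)[:, None] * sep
        X = (X - X.min()) / (X.max() - X.min())
        return X, y

    def test_huge_l2_shrinks_head(self):
        X, y = self._data(0)
        # plain SGD with η < 1/λ: the L2 term contracts weights geometrically
        cfg = TrainConfig(learning_rate=2.5e-7, lr_decay=1.0, epochs=30,
                          l2=1e6, dropout=0.0, seed=0)
        stack = pretrain_stack(X, [8], TrainConfig(epochs=2, dropout=0.0, seed=0))
        model = finetune(stack, X, y, cfg)
        assert np.linalg.norm(model.head_W) < 1e-2

    def test_separable_data_high_training_accuracy(self):
        wins = 0
        for seed in range(10):
            X, y = self._data(seed)
            cfg = TrainConfig(learning_rate=0.01, optimizer="adam", epochs=50,
                              lr_decay=1.0, dropout=0.0, seed=seed)
            stack = pretrain_stack(X, [8], TrainConfig(epochs=3, dropout=0.0, seed=seed))
            model = finetune(stack, X, y, cfg)
            acc = (predict_proba(model, X).argmax(1) == y).mean()
            wins += acc >= 0.95
        assert wins >= 9

    def test_gradients_match_finite_differences(self, gradcheck):
        rng = np.random.default_rng(12)
        X = rng.random((3, 5))
        y = np.array([0, 1, 1])
        model = HDBNModel(
            [rng.standard_normal((5, 4)) / 2, rng.standard_normal((4, 3)) / 2],
            [0.1 * rng.standard_normal(4), 0.1 * rng.standard_normal(3)],
            rng.standard_normal((3, 2)) / 2, np.zeros(2), [4, 3])
        params = [g for pair in zip(model.weights, model.biases) for g in pair]
        params += [model.head_W, model.head_b]
        err = gradcheck(lambda: loss_and_grads(model, X, y, 0.01), params)
        assert err < 1e-5

    def test_extract_features_contract(self):
        X, y = self._data(1, n=50)
        stack = pretrain_stack(X, [6, 3], TrainConfig(epochs=2, dropout=0.0))
        model = finetune(stack, X, y, TrainConfig(epochs=2, dropout=0.0))
        F = extract_features(model, X)
        assert F.shape == (50, 3)
        assert ((F > 0) & (F < 1)).all()
        assert np.array_equal(F, extract_features(model, X))
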