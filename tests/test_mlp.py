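"""MLP classifier: shapes, gradient correctness, class weighting, training."""

import numpy as np
import pytest

import fedcog as fc
from fedcog.exceptions import ConfigError, DataError
from fedcog.mlp import learning_rate_at


def unflatten(vec, template):
    layers, i = [], 0
    for W, b in template.layers:
        layers.append(
            (vec[i : i + W.size].reshape(W.shape), vec[i + W.size : i + W.size + b.size])
        )
        i += W.size + b.size
    return fc.ModelParams(tuple(layers))


class TestInitAndForward:
    def test_default_architecture_parameter_count(self):
        # 176->20->20->1: (176*20+20) + (20*20+20) + (20*1+1)
        params = fc.init_params((176, 20, 20, 1), seed=0)
        assert params.n_params == 176 * 20 + 20 + 20 * 20 + 20 + 20 * 1 + 1 == 3981
        assert params.layer_sizes == (176, 20, 20, 1)

    def test_init_is_seeded_and_glorot_bounded(self):
        a = fc.init_params((10, 4, 1), seed=7)
        b = fc.init_params((10, 4, 1), seed=7)
        np.testing.assert_array_equal(a.flatten(), b.flatten())
        W0 = a.layers[0][0]
        assert np.abs(W0).max() <= np.sqrt(6 / (10 + 4))
        assert np.all(a.layers[0][1] == 0)

    def test_minimal_network_and_bad_sizes(self):
        p = fc.init_params((1, 1), seed=0)
        assert p.layers[0][0].shape == (1, 1) and p.layers[0][1][0] == 0.0
        with pytest.raises(ConfigError):
            fc.init_params((4, 0, 1), seed=0)
        with pytest.raises(ConfigError):
            fc.init_params((4,), seed=0)

    def test_zero_params_output_half(self):
        p = fc.init_params((3, 2, 1), seed=0).map(np.zeros_like)
        probs = fc.forward(p, np.random.default_rng(0).standard_normal((7, 3)))
        np.testing.assert_allclose(probs, 0.5)

    def test_probabilities_bounded_and_dim_checked(self, toy_params):
        X = np.random.default_rng(1).standard_normal((25, 6)) * 3
        probs = fc.forward(toy_params, X)
        assert probs.shape == (25,)
        assert np.all((probs > 0) & (probs < 1))
        with pytest.raises(DataError):
            fc.forward(toy_params, np.zeros((4, 5)))

    def test_params_json_round_trip(self, toy_params):
        clone = fc.ModelParams.from_json(toy_params.to_json())
        np.testing.assert_array_equal(clone.flatten(), toy_params.flatten())


class TestClassWeights:
    def test_balanced_labels_give_unit_weights(self):
        w = fc.class_weights(np.array([0, 1] * 10))
        assert (w.weight_cu, w.weight_ci) == (1.0, 1.0)

    def test_imbalanced_formula(self):
        # N=100 with 90 CI / 10 CU: w_c = N / (2 N_c)
        w = fc.class_weights(np.array([1] * 90 + [0] * 10))
        assert w.weight_ci == pytest.approx(100 / 180)
        assert w.weight_cu == pytest.approx(5.0)

    def test_single_class_is_an_error(self):
        with pytest.raises(DataError, match="one class"):
            fc.class_weights(np.ones(20))


class TestWeightedBCE:
    def test_perfect_predictions_vanish(self):
        labels = np.array([0, 1, 1])
        assert fc.weighted_bce(labels.astype(float), labels) == pytest.approx(0.0, abs=1e-10)

    def test_uninformative_half_is_ln2(self):
        loss = fc.weighted_bce(np.full(9, 0.5), np.array([0, 1] * 4 + [0]))
        assert loss == pytest.approx(np.log(2))

    def test_hand_worked_weighted_batch(self):
        # labels (1,0), p=(0.8,0.3), weights (ci=2, cu=0.5):
        # mean of 2*(-ln 0.8) and 0.5*(-ln 0.7)
        w = fc.ClassWeights(weight_cu=0.5, weight_ci=2.0)
        loss = fc.weighted_bce(np.array([0.8, 0.3]), np.array([1, 0]), w)
        expected = (2 * -np.log(0.8) + 0.5 * -np.log(0.7)) / 2
        assert loss == pytest.approx(expected, abs=1e-4)
        assert loss == pytest.approx(0.3123, abs=1e-4)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            fc.weighted_bce(np.array([0.5]), np.array([1, 0]))


class TestGradient:
    @staticmethod
    def kink_free_batch(params, sizes, start_seed=0, n=5):
        """A batch whose hidden pre-activations stay clear of the ReLU kink,
        where the finite-difference oracle is ill-defined."""
        for seed in range(start_seed, start_seed + 50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((n, sizes[0]))
            a, ok = X, True
            for i, (W, b) in enumerate(params.layers[:-1]):
                z = a @ W + b
                ok = ok and np.abs(z).min() > 1e-3
                a = np.maximum(z, 0)
            if ok:
                return X
        raise AssertionError("no kink-free batch found")

    @pytest.mark.parametrize("sizes", [(6, 4, 1), (6, 4, 3, 1), (2, 1)])
    def test_analytic_gradient_matches_central_differences(self, sizes):
        """Backprop vs finite differences (h=1e-5), every layer, 5-sample batch."""
        params = fc.init_params(sizes, seed=1)
        X = self.kink_free_batch(params, sizes)
        y = np.array([1, 0, 1, 1, 0])
        w = fc.class_weights(y)
        _, grad = fc.loss_and_grad(params, X, y, w)
        flat_g = grad.flatten()
        flat_p = params.flatten()
        h = 1e-5
        for j in range(flat_p.size):
            e = np.zeros_like(flat_p)
            e[j] = h
            lp, _ = fc.loss_and_grad(unflatten(flat_p + e, params), X, y, w)
            lm, _ = fc.loss_and_grad(unflatten(flat_p - e, params), X, y, w)
            fd = (lp - lm) / (2 * h)
            denom = max(abs(fd), abs(flat_g[j]), 1e-8)
            assert abs(fd - flat_g[j]) / denom < 1e-4


class TestTraining:
    def test_zero_epochs_is_identity(self, toy_params, small_table):
        out, losses = fc.train_local(
            toy_params, small_table, fc.TrainingConfig(epochs=0, seed=0)
        )
        np.testing.assert_array_equal(out.flatten(), toy_params.flatten())
        assert losses == []

    def test_descent_on_separable_toy_data(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-2, 0.3, (10, 2)), rng.normal(2, 0.3, (10, 2))])
        table = fc.FeatureTable(
            features=X,
            labels=np.array([0] * 10 + [1] * 10),
            sample_ids=np.array([f"t{i}" for i in range(20)], dtype=object),
        )
        params = fc.init_params((2, 4, 1), seed=1)
        _, losses = fc.train_local(params, table, fc.TrainingConfig(epochs=30, seed=2))
        assert losses[-1] < losses[0]
        assert all(np.isfinite(losses))

    def test_training_is_seeded(self, small_table):
        p0 = fc.init_params((6, 4, 1), seed=0)
        cfg = fc.TrainingConfig(epochs=5, seed=9)
        a, _ = fc.train_local(p0, small_table, cfg)
        b, _ = fc.train_local(p0, small_table, cfg)
        np.testing.assert_array_equal(a.flatten(), b.flatten())

    def test_lr_schedule_is_strictly_decreasing_exponential(self):
        cfg = fc.TrainingConfig()
        lrs = [learning_rate_at(cfg, e) for e in range(150)]
        assert lrs[0] == 0.01
        assert lrs[1] == pytest.approx(0.0095)
        assert all(a > b for a, b in zip(lrs, lrs[1:]))
        assert lrs[-1] == pytest.approx(0.01 * 0.95**149)

    def test_validation_holdout_shrinks_the_training_stream(self, toy_params, small_table):
        cfg_full = fc.TrainingConfig(epochs=5, seed=9)
        cfg_val = fc.TrainingConfig(epochs=5, seed=9, validation_fraction=0.5)
        full, losses_full = fc.train_local(toy_params, small_table, cfg_full)
        held, losses_val = fc.train_local(toy_params, small_table, cfg_val)
        assert all(np.isfinite(losses_val))
        # different data stream -> different trajectory
        assert not np.array_equal(full.flatten(), held.flatten())

    def test_single_class_training_errors(self, toy_params):
        table = fc.FeatureTable(
            features=np.zeros((5, 6)),
            labels=np.ones(5, dtype=int),
            sample_ids=np.array([f"x{i}" for i in range(5)], dtype=object),
        )
        with pytest.raises(DataError):
            fc.train_local(toy_params, table, fc.TrainingConfig(epochs=1, seed=0))

    def test_trained_model_beats_085_auc_on_strong_signal(self):
        """With effect size 1.5 on 10 features (Bayes AUC ~ 1.0) and 2,000
        samples, the default training recipe clears AUC 0.85 on held-out data."""
        table = fc.generate_cohort(
            fc.GeneratorConfig(n_samples=2000, effect_size=1.5, n_informative=10, seed=21)
        )
        train, test = fc.train_test_split(table, seed=1)
        scaler = fc.Standardizer.fit(train.features)
        params = fc.init_params(seed=0)
        params, _ = fc.train_local(
            params, scaler.transform_table(train), fc.TrainingConfig(seed=2)
        )
        probs = fc.forward(params, scaler.transform(test.features))
        assert fc.auc_score(probs, test.labels) > 0.85


class TestStandardizer:
    def test_train_columns_become_zero_mean_unit_variance(self, cohort_2239):
        train, test = fc.train_test_split(cohort_2239, seed=3)
        scaler = fc.Standardizer.fit(train.features)
        Z = scaler.transform(train.features)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)
        # test data uses the train statistics, so it is close but not exact
        Zt = scaler.transform(test.features)
        assert 0.05 < np.abs(Zt.mean(axis=0)).max() < 0.5

    def test_constant_feature_does_not_blow_up(self):
        X = np.zeros((10, 2))
        X[:, 1] = np.arange(10)
        Z = fc.Standardizer.fit(X).transform(X)
        assert np.isfinite(Z).all()
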