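"""The NumPy biLSTM classifier: architecture, gradients, training contract."""

import numpy as np
import pytest

import epievents as ep
from epievents.baseline_detector import CLASS_ORDER, EventLabel
from epievents.lstm_classifier import (EventClassifier, EventClassifierResults,
                                       LstmConfig, _Network,
                                       lstm_parameter_count, run_experiment)

from conftest import prototype_features


def _separable(n_per_class=100, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    X = rng.random((4 * n_per_class, 3, 8)) * 0.1
    y = np.repeat(np.arange(4), n_per_class)
    for k in range(4):
        X[y == k, 1, k] += (k + 1) * scale
    return X, y


class TestArchitecture:
    @pytest.mark.parametrize("hu,bi,layers", [(200, True, 1), (20, True, 1),
                                              (50, False, 1), (16, False, 2),
                                              (16, True, 2)])
    def test_parameter_count_matches_closed_form(self, hu, bi, layers):
        cfg = LstmConfig(hidden_units=hu, bidirectional=bi, layers=layers,
                         n_iterations=0)
        net = _Network(cfg)
        assert net.n_params() == lstm_parameter_count(hu, 8, bi, layers)

    def test_default_bilstm_200_formula(self):
        # 2 directions x 4 gates x (HU*(8+HU) + HU) + FC over 2*HU
        hu = 200
        expected = 2 * 4 * (hu * (8 + hu) + hu) + (2 * hu * 4 + 4)
        assert lstm_parameter_count(hu) == expected

    def test_untrained_model_outputs_probabilities(self, rng):
        net = _Network(LstmConfig(hidden_units=10, n_iterations=0))
        probs = net.forward(rng.standard_normal((7, 3, 8)))
        assert probs.shape == (7, 4)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-12)

    def test_two_layer_dropout_structure(self):
        net = _Network(LstmConfig(hidden_units=8, layers=2, dropout_p=0.2))
        assert len(net.layers) == 2
        assert net.layers[0].return_sequences and not net.layers[1].return_sequences

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LstmConfig(layers=3)
        with pytest.raises(ValueError):
            LstmConfig(dropout_p=1.0)
        with pytest.raises(ValueError):
            LstmConfig(hidden_units=0)


class TestGradients:
    @pytest.mark.parametrize("bi,layers,dropout", [(True, 1, 0.0),
                                                   (False, 2, 0.0)])
    def test_backprop_matches_numerical_gradient(self, bi, layers, dropout):
        rng = np.random.default_rng(2)
        net = _Network(LstmConfig(hidden_units=4, bidirectional=bi,
                                  layers=layers, dropout_p=dropout, seed=3))
        X = rng.standard_normal((6, 3, 8))
        Y = np.eye(4)[rng.integers(0, 4, 6)]
        probs = net.forward(X)
        grads = net.backward(probs, Y)

        def loss():
            p = net.forward(X)
            return -np.mean(np.log(np.sum(p * Y, axis=1)))

        eps = 1e-6
        for p, g in zip(net.params, grads):
            flat_idx = rng.integers(0, p.size, size=min(4, p.size))
            for fi in flat_idx:
                ix = np.unravel_index(fi, p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                lp = loss()
                p[ix] = orig - eps
                lm = loss()
                p[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[ix]) < 1e-5 * max(1.0, abs(num))


class TestTraining:
    def test_separable_set_reaches_full_accuracy(self):
        X, y = _separable()
        cfg = LstmConfig(hidden_units=20, n_iterations=200, seed=0)
        res = EventClassifier.from_arrays(X, y, cfg).fit()
        assert (res.predict(X) == y).mean() == 1.0
        assert res.loss_history[-1] < res.loss_history[0]

    def test_zero_iterations_leaves_model_at_init(self, rng):
        X, y = _separable(20)
        cfg = LstmConfig(hidden_units=6, n_iterations=0, seed=5)
        res = EventClassifier.from_arrays(X, y, cfg).fit()
        fresh = _Network(LstmConfig(hidden_units=6, n_iterations=0, seed=5))
        for a, b in zip(res._net.params, fresh.params):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_predictions(self):
        X, y = _separable(30)
        cfg = LstmConfig(hidden_units=8, n_iterations=50, seed=11)
        m = EventClassifier.from_arrays(X, y, cfg)
        p1 = m.fit().predict_proba(X)
        p2 = m.fit().predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_accuracy_nondecreasing_in_iterations(self):
        """Accuracy plateaus with training length on the separable set (no
        overfitting collapse over 50 -> 200 -> 1000 steps)."""
        X, y = _separable(50, scale=2.0)
        Xt, yt = _separable(50, seed=99, scale=2.0)
        accs = []
        for ni in (50, 200, 1000):
            acc = []
            for seed in range(3):
                cfg = LstmConfig(hidden_units=10, n_iterations=ni, seed=seed)
                res = EventClassifier.from_arrays(X, y, cfg).fit()
                acc.append((res.predict(Xt) == yt).mean())
            accs.append(np.mean(acc))
        assert accs[1] >= accs[0] - 0.02
        assert accs[2] >= accs[1] - 0.02

    def test_label_shuffle_gives_chance_accuracy(self):
        """With labels randomly permuted the network cannot beat the 25%
        4-class chance level on held-out data."""
        X, y = _separable(40)
        Xt, yt = _separable(40, seed=7)
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y_shuf = rng.permutation(y)
            cfg = LstmConfig(hidden_units=8, n_iterations=150, seed=seed)
            res = EventClassifier.from_arrays(X, y_shuf, cfg).fit()
            accs.append((res.predict(Xt) == yt).mean())
        assert abs(np.mean(accs) - 0.25) < 0.05

    def test_single_class_training_set_rejected(self):
        X = np.random.default_rng(0).random((50, 3, 8))
        y = np.zeros(50, dtype=int)
        with pytest.raises(ValueError, match="single class"):
            EventClassifier.from_arrays(X, y, LstmConfig(n_iterations=10))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            EventClassifier.from_arrays(np.empty((0, 3, 8)), np.empty(0),
                                        LstmConfig())


class TestPrediction:
    def test_exact_tie_breaks_toward_first_class(self):
        X, y = _separable(20)
        cfg = LstmConfig(hidden_units=5, n_iterations=0, seed=0)
        res = EventClassifier.from_arrays(X, y, cfg).fit()
        res._net.Wfc[...] = 0.0
        res._net.bfc[...] = 0.0
        pred = res.predict(X[:10])
        assert np.all(pred == 0)  # spike, the first class in the fixed order
        assert ep.CLASS_ORDER[0] is EventLabel.SPIKE

    def test_batch_equals_per_event_prediction(self):
        X, y = _separable(20)
        cfg = LstmConfig(hidden_units=6, n_iterations=30, seed=2)
        res = EventClassifier.from_arrays(X, y, cfg).fit()
        batch = res.predict(X[:8])
        single = np.array([res.predict(X[i]) for i in range(8)]).ravel()
        np.testing.assert_array_equal(batch, single)

    def test_shape_mismatch_rejected(self):
        X, y = _separable(20)
        res = EventClassifier.from_arrays(
            X, y, LstmConfig(hidden_units=4, n_iterations=0)).fit()
        with pytest.raises(ValueError, match="shaped"):
            res.predict(np.zeros((5, 2, 8)))

    def test_checkpoint_roundtrip(self, tmp_path):
        X, y = _separable(30)
        cfg = LstmConfig(hidden_units=6, n_iterations=40, seed=4)
        res = EventClassifier.from_arrays(X, y, cfg).fit()
        path = tmp_path / "model.npz"
        res.save(path)
        back = EventClassifierResults.load(path)
        np.testing.assert_array_equal(res.predict_proba(X),
                                      back.predict_proba(X))
        assert back.manifest == res.manifest


class TestRunExperiment:
    def _gt(self, n_subjects, n=30):
        by_subj = prototype_features(n, n_subjects, seed=1)
        return ep.assemble_ground_truth(by_subj, n_per_class=n, seed=0)

    def _cfg(self):
        return LstmConfig(hidden_units=6, n_iterations=40, seed=0)

    def test_within_subject_structure(self):
        gt = self._gt(1)
        out = run_experiment("within_subject", gt,
                             ep.SplitSpec(10, 10, 2, seed=0), self._cfg())
        assert list(out) == ["P0"]
        assert out["P0"].n_randomizations == 2

    def test_between_subjects_grid(self):
        gt = self._gt(3)
        out = run_experiment("between_subjects", gt,
                             ep.SplitSpec(10, 10, 1, seed=0), self._cfg())
        assert len(out) == 9
        assert ("P0", "P2") in out and ("P2", "P2") in out

    def test_global_and_cross_site(self):
        gt = self._gt(3)
        holdout = ep.assemble_ground_truth(prototype_features(20, 2, seed=9),
                                           n_per_class=20, seed=0)
        # rename holdout subjects to avoid collision
        holdout.cells = {(f"H{k[0]}", k[1]): v for k, v in holdout.cells.items()}
        out = run_experiment("cross_site", gt, ep.SplitSpec(10, 10, 1, seed=0),
                             self._cfg(), holdout_gt=holdout)
        assert set(out) == {"P0", "P1", "P2", "HP0", "HP1"}

    def test_cross_site_requires_holdout(self):
        with pytest.raises(ValueError, match="held-out"):
            run_experiment("cross_site", self._gt(1),
                           ep.SplitSpec(5, 5, 1), self._cfg())

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="scenario"):
            run_experiment("bogus", self._gt(1), ep.SplitSpec(5, 5, 1),
                           self._cfg())
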