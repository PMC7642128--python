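"""Classifier contracts: gradient correctness, seeded determinism, fold
arithmetic, leakage guards, and learnability on separable synthetic data."""

import dataclasses

import numpy as np
import pytest

from mieeg import classify as clf
from mieeg import synthgen, wavelet_bands
from mieeg.classify import (
    ClassifierConfig, CNNParams, LSTMParams, TrainParams, cross_validate,
    compare_archs, compare_training_regimes, evaluate, load_model,
    make_folds, save_model, train,
)
from mieeg.classify._nn import LSTMClassifier, ShallowCNN, fit
from mieeg.core import EpochSet
from tests.conftest import make_epochs

FAST_TRAIN = TrainParams(batch_size=8, max_epochs=8, early_stop_patience=4,
                         min_epochs=4, learning_rate=3e-3)


def fast_config(arch="cnn", seed=0, **train_kw):
    tp = dataclasses.replace(FAST_TRAIN, **train_kw) if train_kw else FAST_TRAIN
    return ClassifierConfig(
        arch=arch,
        cnn=CNNParams(temporal_kernel=11, n_temporal_filters=4,
                      n_spatial_filters=6, pool_factor=4),
        lstm=LSTMParams(hidden_units=12, n_layers=1, time_pool=5),
        train=tp, seed=seed,
    )


def finite_difference_check(model, x, y, n_probes=6, eps=1e-6):
    _, grads = model.loss_and_grads(x, y)
    rng = np.random.default_rng(0)
    worst = 0.0
    for key, g in grads.items():
        for _ in range(n_probes):
            idx = tuple(rng.integers(0, s) for s in g.shape)
            p = model.params[key]
            orig = p[idx]
            p[idx] = orig + eps
            l1, _ = model.loss_and_grads(x, y)
            p[idx] = orig - eps
            l2, _ = model.loss_and_grads(x, y)
            p[idx] = orig
            num = (l1 - l2) / (2 * eps)
            worst = max(worst, abs(num - g[idx]) / max(1e-8, abs(num) + abs(g[idx])))
    return worst


class TestGradients:
    def test_cnn_backprop_matches_finite_differences(self, rng):
        x = rng.normal(size=(6, 5, 40))
        y = rng.integers(0, 2, 6)
        net = ShallowCNN(5, 40, temporal_kernel=7, n_temporal_filters=3,
                         n_spatial_filters=4, pool_factor=3, rng=rng,
                         dtype=np.float64)
        assert finite_difference_check(net, x, y) < 1e-6

    def test_lstm_backprop_matches_finite_differences(self, rng):
        x = rng.normal(size=(6, 12, 5))
        y = rng.integers(0, 2, 6)
        net = LSTMClassifier(5, hidden_units=8, n_layers=2, rng=rng,
                             dtype=np.float64)
        assert finite_difference_check(net, x, y) < 1e-4


class TestFolds:
    def test_stratified_fold_arithmetic(self):
        es = make_epochs(n_trials=280, n_channels=2, n_samples=30)
        folds = make_folds(es, 5, seed=0)
        y = np.array([l == "right" for l in es.labels])
        for tr, te in folds:
            assert len(te) == 56
            assert np.sum(y[te]) == 28  # 28 per class
            assert len(np.intersect1d(tr, te)) == 0

    def test_same_seed_same_assignment(self):
        es = make_epochs(n_trials=60, n_channels=2, n_samples=30)
        a = make_folds(es, 5, seed=3)
        b = make_folds(es, 5, seed=3)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tea, teb)

    def test_k_exceeding_class_count(self):
        es = make_epochs(n_trials=8, n_channels=2, n_samples=30)
        with pytest.raises(ValueError, match="class count"):
            make_folds(es, 5, seed=0)


class TestTrainContracts:
    def test_deterministic_given_seed(self):
        es = make_epochs(n_trials=40, n_channels=4, n_samples=120, seed=5)
        m1 = train(es, fast_config(seed=11))
        m2 = train(es, fast_config(seed=11))
        assert m1.history.train_loss == m2.history.train_loss
        assert m1.history.val_loss == m2.history.val_loss
        for k in m1.net.params:
            np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])

    def test_single_class_rejected(self):
        es = make_epochs(n_trials=40, n_channels=4, n_samples=120)
        one = EpochSet(
            data=es.data, labels=np.array(["left"] * 40, dtype=object),
            fs=es.fs, channel_names=es.channel_names, cue_index=es.cue_index,
        )
        with pytest.raises(ValueError, match="single class"):
            train(one, fast_config())

    def test_too_few_trials_rejected(self):
        es = make_epochs(n_trials=10, n_channels=4, n_samples=120)
        with pytest.raises(ValueError, match="20 trials"):
            train(es, fast_config())

    def test_permuted_labels_give_chance(self):
        """White-noise data with random labels: validation accuracy must sit
        inside the binomial 95% interval around 0.5."""
        es = make_epochs(n_trials=80, n_channels=4, n_samples=120, seed=6)
        m = train(es, fast_config(seed=2))
        n_val = 16
        ci = 1.96 * np.sqrt(0.25 / n_val)
        assert abs(np.mean(m.history.val_accuracy) - 0.5) <= 2 * ci

    def test_no_leakage_from_test_labels(self):
        """Evaluating with shuffled test labels must not change predictions."""
        es = make_epochs(n_trials=40, n_channels=4, n_samples=120, seed=7)
        test = make_epochs(n_trials=20, n_channels=4, n_samples=120, seed=8)
        m = train(es, fast_config(seed=3))
        pred1 = m.predict(test)
        shuffled = EpochSet(
            data=test.data, labels=test.labels[::-1].copy(), fs=test.fs,
            channel_names=test.channel_names, cue_index=test.cue_index,
        )
        pred2 = m.predict(shuffled)
        assert list(pred1) == list(pred2)


class TestEvaluate:
    def test_single_class_test_set_recall(self):
        es = make_epochs(n_trials=40, n_channels=4, n_samples=120, seed=9)
        m = train(es, fast_config(seed=4))
        test = make_epochs(n_trials=20, n_channels=4, n_samples=120, seed=10)
        only_left = EpochSet(
            data=test.data, labels=np.array(["left"] * 20, dtype=object),
            fs=test.fs, channel_names=test.channel_names, cue_index=test.cue_index,
        )
        acc, conf = evaluate(m, only_left)
        assert conf[1].sum() == 0
        assert acc == pytest.approx(conf[0, 0] / conf[0].sum())

    def test_shape_mismatch_rejected(self):
        es = make_epochs(n_trials=40, n_channels=4, n_samples=120)
        m = train(es, fast_config())
        other = make_epochs(n_trials=10, n_channels=4, n_samples=100)
        with pytest.raises(ValueError, match="length"):
            evaluate(m, other)


class TestLearnability:
    def test_cnn_separates_synthetic_erd(self):
        """Strong injected ERD at moderate noise must be learnable."""
        cfg = synthgen.GeneratorConfig(
            preset="custom", n_channels=16, n_trials_per_class=40,
            erd_depth=0.6, snr_db=5.0, seed=17)
        pre = wavelet_bands.preprocess_epochs(synthgen.generate_session(cfg))
        config = fast_config(seed=1, max_epochs=40, min_epochs=25,
                             early_stop_patience=8)
        folds = make_folds(pre, 4, config.seed)
        tr, te = folds[0]
        from mieeg.classify import _subset

        m = train(_subset(pre, tr), config)
        acc, _ = evaluate(m, _subset(pre, te))
        assert acc >= 0.85

    def test_lstm_learns_temporal_structure(self, rng):
        """The LSTM baseline is a working learner on genuinely temporal
        signals (class-dependent drift)."""
        B, T, D = 160, 40, 6
        X = rng.normal(size=(B, T, D)).astype(np.float32)
        y = rng.integers(0, 2, B)
        X[y == 1, :, 0] += np.linspace(0, 1.5, T, dtype=np.float32)
        net = LSTMClassifier(D, hidden_units=16, rng=rng)
        fit(net, X[:120], y[:120], X[120:], y[120:], batch_size=16,
            max_epochs=50, patience=10, min_epochs=20, learning_rate=3e-3,
            rng=rng)
        acc = np.mean(net.forward(X[120:]).argmax(1) == y[120:])
        assert acc >= 0.85


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def tiny_separable(self):
        cfg = synthgen.GeneratorConfig(
            preset="custom", n_channels=8, n_trials_per_class=20,
            erd_depth=0.6, snr_db=8.0, seed=19)
        return wavelet_bands.preprocess_epochs(synthgen.generate_session(cfg))

    def test_report_shape(self, tiny_separable):
        rep = cross_validate(tiny_separable, 4, fast_config(seed=6))
        assert len(rep.fold_accuracies) == 4
        assert 0.0 <= rep.mean_accuracy <= 1.0
        assert all(c.sum() == 10 for c in rep.confusions)

    def test_compare_archs_shares_folds_and_is_deterministic(self, tiny_separable):
        cfgs = [fast_config("cnn", seed=6), fast_config("lstm", seed=6)]
        a = compare_archs(tiny_separable, cfgs, k=4)
        b = compare_archs(tiny_separable, cfgs, k=4)
        assert a["reports"]["cnn"].fold_accuracies == b["reports"]["cnn"].fold_accuracies
        assert a["paired_fold_differences"] == b["paired_fold_differences"]
        diffs = a["paired_fold_differences"]["cnn-lstm"]
        assert len(diffs) == 4

    def test_training_regimes_reports_both(self):
        sessions = []
        for seed in (23, 24):
            cfg = synthgen.GeneratorConfig(
                preset="custom", n_channels=8, n_trials_per_class=22,
                erd_depth=0.6, snr_db=8.0, seed=seed)
            sessions.append(
                wavelet_bands.preprocess_epochs(synthgen.generate_session(cfg)))
        out = compare_training_regimes(sessions, fast_config(seed=7), k=2)
        assert len(out["per_subject"]) == 2
        assert out["pooled"].k == 2
        assert 0.0 <= out["per_subject_mean"] <= 1.0


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        es = make_epochs(n_trials=40, n_channels=4, n_samples=120, seed=11)
        m = train(es, fast_config(seed=8))
        save_model(m, tmp_path / "model")
        back = load_model(tmp_path / "model")
        test = make_epochs(n_trials=12, n_channels=4, n_samples=120, seed=12)
        np.testing.assert_allclose(
            m.predict_proba(test), back.predict_proba(test), atol=1e-6)
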