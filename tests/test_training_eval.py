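import numpy as np
import pytest

from triplanar.architectures import reference_config, build_model, transform_batch
from triplanar.training_eval import (
    CrossvalResult,
    FoldSplit,
    TrainConfig,
    crossval,
    evaluate,
    fold_arrays,
    lr_at_epoch,
    metrics_from_predictions,
    pca_svm_baseline,
    predict_proba,
    split_subjectwise,
    train,
)


class TestSubjectwiseSplit:
    def test_10_subjects_5_folds(self):
        subjects = [f"s{i}" for i in range(10)]
        folds = split_subjectwise(subjects, k=5, seed=3)
        assert len(folds) == 5
        test_sets = [set(f.test_subjects) for f in folds]
        assert all(len(t) == 2 for t in test_sets)
        assert set().union(*test_sets) == set(subjects)
        for a in range(5):
            for b in range(a + 1, 5):
                assert not test_sets[a] & test_sets[b]

    def test_partitions_disjoint_and_exhaustive(self):
        subjects = [f"s{i}" for i in range(23)]
        for fold in split_subjectwise(subjects, k=5, seed=0):
            tr, va, te = map(set, (fold.train_subjects, fold.val_subjects, fold.test_subjects))
            assert not (tr & va or tr & te or va & te)
            assert tr | va | te == set(subjects)
            assert len(va) == max(1, round(0.1 * (len(subjects) - len(te))))

    def test_deterministic_given_seed(self):
        subjects = [f"s{i}" for i in range(12)]
        a = split_subjectwise(subjects, k=4, seed=9)
        b = split_subjectwise(subjects, k=4, seed=9)
        assert [(f.train_subjects, f.val_subjects, f.test_subjects) for f in a] == [
            (f.train_subjects, f.val_subjects, f.test_subjects) for f in b
        ]

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            split_subjectwise(["a", "b"], k=5)

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError, match="two partitions"):
            FoldSplit(0, ["a"], ["a"], ["b"])


class TestLRSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(0, 0.0025), (49, 0.0025), (50, 0.00125), (100, 0.000625), (149, 0.000625)],
    )
    def test_halving_every_50(self, epoch, expected):
        assert lr_at_epoch(epoch) == pytest.approx(expected)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(-1)


class _StubModel:
    """Minimal model-interface stub emitting a scripted loss stream."""

    def __init__(self, mode):
        self.mode = mode  # "constant" or "improving"
        self.calls = 0

    def forward(self, x, training=False):
        n = x.shape[0]
        probs = np.full((n, 5), 0.2)
        if self.mode == "improving" and training:
            self.calls += 1
            probs = np.full((n, 5), 1e-3)
            probs[:, 0] = 1 - 4e-3
            probs = probs ** (self.calls / (self.calls + 50.0))
            probs /= probs.sum(axis=1, keepdims=True)
        return probs

    def backward(self, dout):
        return dout

    def param_arrays(self):
        return []

    def grads(self):
        return {}

    def state_dict(self):
        return {}

    def load_state_dict(self, state):
        pass


def _toy_data(n=8):
    X = np.zeros((n, 2), dtype=np.float32)
    y = np.zeros(n, dtype=int)
    return (X, y), (X[:2], y[:2])


class TestEarlyStopping:
    def test_constant_loss_stops_after_patience(self):
        """First epoch sets the running minimum; 6 flat epochs then stop."""
        tr, va = _toy_data()
        _, history = train(_StubModel("constant"), tr, va, TrainConfig(max_epochs=100, seed=0))
        assert len(history) == 1 + 6

    def test_decreasing_loss_never_stops_early(self):
        tr, va = _toy_data()
        _, history = train(_StubModel("improving"), tr, va,
                           TrainConfig(max_epochs=30, batch_size=8, seed=0))
        assert len(history) == 30
        losses = [h["train_loss"] for h in history]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_lr_schedule_recorded_matches_closed_form(self):
        tr, va = _toy_data()
        _, history = train(_StubModel("constant"), tr, va,
                           TrainConfig(max_epochs=10, halve_every=3, base_lr=0.1, seed=0))
        for h in history:
            assert h["lr"] == pytest.approx(0.1 * 0.5 ** (h["epoch"] // 3))


class TestTrainOnRealModel:
    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(0)
        cfg = reference_config("mv2d", (10, 12, 11))
        n = 40
        vols = rng.standard_normal((n, 10, 12, 11)).astype(np.float32)
        y = rng.integers(0, 5, size=n)
        vols[np.arange(n), 0, 0, 0] += 10.0 * y  # make the task learnable
        X = transform_batch(cfg, vols)
        model = build_model(cfg, np.random.default_rng(1))
        tcfg = TrainConfig(max_epochs=12, batch_size=8, seed=4)
        model, history = train(model, (X[:30], y[:30]), (X[30:], y[30:]), tcfg)
        return model, history, (X[30:], y[30:])

    def test_checkpoint_has_best_validation_accuracy(self, trained):
        model, history, val = trained
        best = max(h["val_accuracy"] for h in history)
        probs = predict_proba(model, val[0])
        assert float(np.mean(probs.argmax(1) == val[1])) == pytest.approx(best)

    def test_training_is_deterministic_given_seed(self, trained):
        _, history, _ = trained
        rng = np.random.default_rng(0)
        cfg = reference_config("mv2d", (10, 12, 11))
        n = 40
        vols = rng.standard_normal((n, 10, 12, 11)).astype(np.float32)
        y = rng.integers(0, 5, size=n)
        vols[np.arange(n), 0, 0, 0] += 10.0 * y
        X = transform_batch(cfg, vols)
        model = build_model(cfg, np.random.default_rng(1))
        _, history2 = train(model, (X[:30], y[:30]), (X[30:], y[30:]),
                            TrainConfig(max_epochs=12, batch_size=8, seed=4))
        assert [h["train_loss"] for h in history] == [h["train_loss"] for h in history2]


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 4] * 3)
        rep = metrics_from_predictions(y, y)
        assert rep.accuracy == rep.precision == rep.f1 == 1.0
        assert np.trace(rep.confusion) == 15

    def test_hand_computed_two_class_confusion(self):
        # confusion [[3,1],[1,3]]: accuracy .75, macro precision .75, macro F1 .75
        y_true = np.array([0] * 4 + [1] * 4)
        y_pred = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        rep = metrics_from_predictions(y_true, y_pred, n_classes=2)
        np.testing.assert_array_equal(rep.confusion, [[3, 1], [1, 3]])
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(0.75)

    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        y = np.repeat(np.arange(5), 200)
        pred = rng.integers(0, 5, size=y.size)
        rep = metrics_from_predictions(y, pred)
        assert abs(rep.accuracy - 0.2) < 0.05

    def test_confusion_rows_sum_to_class_counts(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 5, 100)
        pred = rng.integers(0, 5, 100)
        rep = metrics_from_predictions(y, pred)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), np.bincount(y, minlength=5))
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / 100)

    def test_empty_test_set_rejected(self):
        model = _StubModel("constant")
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, (np.zeros((0, 2)), np.zeros(0, dtype=int)))


class TestPCASVM:
    def test_linearly_separable_classes_are_perfect(self, rng):
        n_per, d = 20, 30
        X, y = [], []
        for c in range(5):
            pts = rng.standard_normal((n_per, d)) + 20.0 * np.eye(d)[c]
            X.append(pts)
            y.append(np.full(n_per, c))
        X, y = np.vstack(X), np.concatenate(y)
        rep = pca_svm_baseline((X, y), (X, y), n_components=10)
        assert rep.accuracy == 1.0

    def test_oversized_n_components_clamped_with_warning(self, rng):
        X = rng.standard_normal((12, 40))
        y = np.arange(12) % 5
        with pytest.warns(UserWarning, match="clamping"):
            rep = pca_svm_baseline((X, y), (X, y), n_components=500)
        assert 0.0 <= rep.accuracy <= 1.0


class TestCrossval:
    def test_tiny_regime_shapes_and_determinism(self, tiny_samples):
        tcfg = TrainConfig(max_epochs=2, seed=0)
        res = crossval("mv2d", tiny_samples, k=3, seed=5, train_config=tcfg)
        assert isinstance(res, CrossvalResult)
        assert len(res.reports) == 3
        m, s = res.mean_std("accuracy")
        assert np.isfinite(m) and np.isfinite(s)
        res2 = crossval("mv2d", tiny_samples, k=3, seed=5, train_config=tcfg)
        assert [f.test_subjects for f in res.splits] == [f.test_subjects for f in res2.splits]
        assert [r.accuracy for r in res.reports] == [r.accuracy for r in res2.reports]

    def test_pca_svm_runs_under_crossval(self, tiny_samples):
        res = crossval("pca_svm", tiny_samples, k=3, seed=5)
        assert len(res.reports) == 3

    def test_summary_formats_mean_and_std(self, tiny_samples):
        res = crossval("pca_svm", tiny_samples, k=3, seed=5)
        assert "±" in res.summary() and "accuracy" in res.summary()


class TestNormalizationLeakage:
    def _perturb_test_subjects(self, samples, split):
        out = []
        test = set(split.test_subjects)
        for s in samples:
            v = s.volume * 1000.0 if s.subject_id in test else s.volume
            out.append(type(s)(v, s.label, s.subject_id))
        return out

    def test_train_only_stats_ignore_test_samples(self, tiny_samples):
        split = split_subjectwise([s.subject_id for s in tiny_samples], k=3, seed=2)[0]
        clean = fold_arrays(tiny_samples, split, norm="train_only")
        dirty = fold_arrays(self._perturb_test_subjects(tiny_samples, split), split,
                            norm="train_only")
        np.testing.assert_array_equal(clean["train"][0], dirty["train"][0])
        np.testing.assert_array_equal(clean["val"][0], dirty["val"][0])
        assert not np.array_equal(clean["test"][0], dirty["test"][0])

    def test_all_samples_stats_do_leak(self, tiny_samples):
        """The historical mode lets test voxels move the statistics."""
        split = split_subjectwise([s.subject_id for s in tiny_samples], k=3, seed=2)[0]
        clean = fold_arrays(tiny_samples, split, norm="all_samples")
        dirty = fold_arrays(self._perturb_test_subjects(tiny_samples, split), split,
                            norm="all_samples")
        assert not np.array_equal(clean["train"][0], dirty["train"][0])
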