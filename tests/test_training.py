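"""Splits, metrics, training protocol and aggregation."""

import numpy as np
import pytest

import demfusion as dm
import demfusion.nn as nn
from demfusion.training import (Sample, TrainConfig, aggregate_runs,
                                drop_missing_mmse, evaluate_classification,
                                evaluate_regression, split_dataset,
                                train_model)


class FakeSubject:
    def __init__(self, i, label, mmse):
        self.id = f"S{i}"
        self.label = label
        self.mmse = mmse


class TestSplit:
    def test_exact_fractions_100(self):
        train, val = split_dataset(list(range(100)), seed=0)
        assert len(train) == 65 and len(val) == 35
        assert sorted(train + val) == list(range(100))

    def test_round_half_up_108(self):
        # 108 * 0.65 = 70.2 -> 70 train / 38 validation
        train, val = split_dataset(list(range(108)), seed=0)
        assert len(train) == 70 and len(val) == 38

    def test_same_seed_same_split(self):
        a = split_dataset(list(range(30)), seed=5)
        b = split_dataset(list(range(30)), seed=5)
        assert a == b

    def test_stratified_split_balances_classes(self):
        labels = [0] * 50 + [1] * 50
        train, val = split_dataset(list(range(100)), seed=3, stratify=labels)
        train_pos = sum(1 for i in train if labels[i])
        assert len(train) == 65
        assert train_pos in (32, 33)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            split_dataset([1])


class TestDropMissingMmse:
    def test_regression_drops_missing(self):
        subs = [FakeSubject(i, 0, 25) for i in range(107)] + [FakeSubject(107, 0, None)]
        assert len(drop_missing_mmse(subs, "regression")) == 107

    def test_no_missing_is_identity(self):
        subs = [FakeSubject(i, 0, 25) for i in range(10)]
        assert drop_missing_mmse(subs, "regression") == subs

    def test_classification_keeps_all(self):
        subs = [FakeSubject(i, 0, 25) for i in range(107)] + [FakeSubject(107, 0, None)]
        assert len(drop_missing_mmse(subs, "classification")) == 108


class TestClassificationMetrics:
    def test_hand_computed_confusion_example(self):
        m = evaluate_classification([1, 0, 0, 0], [1, 1, 0, 0])
        assert m.precision == 100.0
        assert m.recall == 50.0
        assert abs(m.f1 - 66.67) < 0.01
        assert m.accuracy == 75.0
        assert m.specificity == 100.0

    def test_perfect_predictions(self):
        m = evaluate_classification([1, 0, 1], [1, 0, 1])
        assert all(v == 100.0 for v in m.as_dict().values())

    def test_all_negative_predictor(self):
        with pytest.warns(RuntimeWarning):
            m = evaluate_classification([0, 0, 0, 0], [1, 1, 0, 0])
        assert m.recall == 0.0
        assert m.specificity == 100.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            evaluate_classification([], [])

    def test_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            true = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            tp = int(np.sum((pred == 1) & (true == 1)))
            tn = int(np.sum((pred == 0) & (true == 0)))
            fp = int(np.sum((pred == 1) & (true == 0)))
            fn = int(np.sum((pred == 0) & (true == 1)))
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = evaluate_classification(pred, true)
            tol = 1e-10
            assert abs(m.accuracy - 100.0 * (tp + tn) / n) < tol
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert abs(m.precision - 100.0 * prec) < tol
            assert abs(m.recall - 100.0 * rec) < tol
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert abs(m.f1 - 100.0 * f1) < tol
            spec = tn / (tn + fp) if tn + fp else 0.0
            assert abs(m.specificity - 100.0 * spec) < tol


class TestRegressionMetric:
    def test_perfect_is_zero(self):
        assert evaluate_regression([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic_sqrt2(self):
        assert abs(evaluate_regression([28, 20], [30, 20]) - np.sqrt(2)) < 1e-9

    def test_constant_shift_law(self, rng):
        t = rng.normal(size=10)
        assert abs(evaluate_regression(t + 3.0, t) - 3.0) < 1e-9


class TestAggregation:
    def test_identical_runs(self):
        out = aggregate_runs([{"accuracy": 80.0}] * 5)
        assert out["accuracy"] == (80.0, 0.0)

    def test_hand_arithmetic_population_std(self):
        out = aggregate_runs([{"m": 80.0}, {"m": 90.0}])
        assert out["m"] == (85.0, 5.0)

    def test_single_run(self):
        assert aggregate_runs([{"m": 3.0}]) == {"m": (3.0, 0.0)}


class TestProtocol:
    def test_early_stopping_halts_after_exactly_six_bad_epochs(self):
        stopper = nn.EarlyStopping(patience=6)
        assert not stopper.step(1.0)
        flags = [stopper.step(1.0 + 0.01 * i) for i in range(1, 8)]
        assert flags[:5] == [False] * 5
        assert flags[5] is True  # halts at exactly the 6th non-improving epoch

    def test_plateau_decays_lr_to_1e6_after_three_bad_epochs(self):
        opt = nn.Adam([nn.Parameter(np.zeros(1))], lr=1e-5)
        sched = nn.ReduceLROnPlateau(opt, factor=0.1, patience=3)
        sched.step(1.0)
        assert not sched.step(1.0)
        assert not sched.step(1.0)
        assert sched.step(1.0)  # third consecutive bad epoch
        assert np.isclose(opt.lr, 1e-6)

    def test_improvement_resets_counters(self):
        stopper = nn.EarlyStopping(patience=3)
        stopper.step(1.0)
        stopper.step(1.1)
        stopper.step(1.1)
        assert not stopper.step(0.9)  # improvement
        assert stopper.bad_epochs == 0


class _ConstantModel(nn.Module):
    """Stub with one parameter whose output never depends on the data."""

    def __init__(self, value=0.0):
        super().__init__()
        self.w = nn.Parameter(np.array([value]))
        self.out = nn.Linear(1, 1, np.random.default_rng(0))

    def __call__(self, token_ids, pad_mask, image, acoustic=None):
        return (self.w * 0.0 + self.w.data[0]).reshape(1, 1)


def _fake_samples(n):
    return [Sample(f"s{i}", np.zeros(2, dtype=np.int64), np.ones(2, bool),
                   np.zeros((1, 1, 1)), np.zeros(1), i % 2, float(20 + i % 5))
            for i in range(n)]


class TestTrainModel:
    def test_flat_validation_loss_halts_at_early_stopping_patience(self):
        data = _fake_samples(8)
        cfg = TrainConfig(task="regression", max_epochs=50,
                          early_stopping_patience=6, batch_size=4, seed=0)
        model = _ConstantModel(22.0)
        _, hist = train_model(model, data, data, cfg)
        # epoch 1 improves over inf; then 6 flat epochs trigger the stop
        assert hist.n_epochs == 7

    def test_learning_rate_trajectory_under_plateau(self):
        data = _fake_samples(8)
        cfg = TrainConfig(task="regression", learning_rate=1e-5, max_epochs=9,
                          early_stopping_patience=50, batch_size=4, seed=0)
        model = _ConstantModel(22.0)
        _, hist = train_model(model, data, data, cfg)
        assert np.isclose(hist.lr[0], 1e-5)
        # plateau of 3 epochs after the first -> decayed to 1e-6
        assert any(np.isclose(lr, 1e-6) for lr in hist.lr)

    def test_checkpoint_roundtrip(self, tmp_path):
        from demfusion.training import load_checkpoint, save_checkpoint
        model = _ConstantModel(1.0)
        model.out.weight.data[:] = 3.25
        save_checkpoint(tmp_path / "ck.npz", model, task="ad", seed=9)
        clone = _ConstantModel(0.0)
        meta = load_checkpoint(tmp_path / "ck.npz", clone)
        assert str(meta["task"]) == "ad" and int(meta["seed"]) == 9
        for (k1, v1), (k2, v2) in zip(sorted(model.state_dict().items()),
                                      sorted(clone.state_dict().items())):
            assert k1 == k2 and np.array_equal(v1, v2)

    def test_nonfinite_loss_aborts(self):
        data = _fake_samples(4)
        cfg = TrainConfig(task="regression", max_epochs=3, batch_size=4, seed=0)
        model = _ConstantModel(np.inf)
        with pytest.raises(FloatingPointError):
            train_model(model, data, data, cfg)
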