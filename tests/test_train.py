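"""Training protocol, schedule, metrics and cross-validation."""

import numpy as np
import pytest

from trilightnet import (
    ModelConfig,
    TrainConfig,
    auroc,
    compute_metrics,
    confusion_from_predictions,
    cosine_lr,
    gen_cohort,
    make_cv_folds,
    run_cv,
)
from trilightnet.metrics import ConfusionCounts
from trilightnet.synthetic import cohort_to_dataset
from trilightnet.train import train_one_fold

rng = np.random.default_rng(2025)


class TestCosineSchedule:
    def test_endpoints_and_midpoint(self):
        assert cosine_lr(0, 1e-4, 50) == 1e-4
        assert abs(cosine_lr(25, 1e-4, 50) - 5e-5) < 1e-18
        assert cosine_lr(50, 1e-4, 50) == 1e-4  # restarts at T_max

    def test_quarter_period(self):
        expected = 1e-4 * (1 + np.cos(np.pi * 0.25)) / 2
        assert abs(cosine_lr(25, 1e-4, 100) - expected) < 1e-18

    def test_bad_tmax(self):
        with pytest.raises(ValueError):
            cosine_lr(1, 1e-4, 0)


class TestConfusion:
    def test_perfect_predictor(self):
        y = np.array([1] * 30 + [0] * 73)
        c = confusion_from_predictions(y.astype(float), y)
        assert (c.tp, c.tn, c.fp, c.fn) == (30, 73, 0, 0)

    def test_all_negative_predictor(self):
        y = np.array([1] * 30 + [0] * 73)
        c = confusion_from_predictions(np.zeros(103), y)
        assert (c.tp, c.fn, c.tn, c.fp) == (0, 30, 73, 0)

    def test_random_case_against_loop_oracle(self):
        p = rng.uniform(0, 1, 200)
        y = rng.integers(0, 2, 200)
        c = confusion_from_predictions(p, y, threshold=0.4)
        tp = sum(1 for pi, yi in zip(p, y) if pi >= 0.4 and yi == 1)
        fp = sum(1 for pi, yi in zip(p, y) if pi >= 0.4 and yi == 0)
        fn = sum(1 for pi, yi in zip(p, y) if pi < 0.4 and yi == 1)
        tn = sum(1 for pi, yi in zip(p, y) if pi < 0.4 and yi == 0)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_from_predictions(np.zeros(3), np.zeros(4, dtype=int))


class TestMetrics:
    def test_perfect_classifier_balanced_accuracy(self):
        r = compute_metrics(ConfusionCounts(tp=30, tn=73, fp=0, fn=0))
        assert r.balanced_accuracy == 1.0

    def test_all_majority_predictor(self):
        r = compute_metrics(ConfusionCounts(tp=0, tn=73, fp=0, fn=30))
        assert r.balanced_accuracy == 0.5

    def test_hand_worked_value(self):
        """(TP,FN,TN,FP) = (15,15,36,37) -> (0.5 + 36/73)/2 = 0.49658."""
        r = compute_metrics(ConfusionCounts(tp=15, fn=15, tn=36, fp=37))
        assert abs(r.balanced_accuracy - 0.49658) < 5e-6

    def test_auroc_worked_example(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == 0.75

    def test_auroc_matches_pair_counting(self):
        """Midrank Mann-Whitney vs brute-force concordant-pair count,
        including ties, on many small instances."""
        for trial in range(60):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
            pairs = 0.0
            total = 0
            for i in range(n):
                for j in range(n):
                    if y[i] == 1 and y[j] == 0:
                        total += 1
                        pairs += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
            assert abs(auroc(y, s) - pairs / total) < 1e-12

    def test_balanced_accuracy_identity_random_tables(self):
        """balanced accuracy == (sensitivity + specificity)/2 whenever
        both are defined."""
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 50, 4))
            r = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            assert np.isclose(r.balanced_accuracy, 0.5 * (r.sensitivity + r.specificity))

    def test_empty_class_reports_nan_with_warning(self):
        with pytest.warns(UserWarning):
            r = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(r.sensitivity)


def _tiny_dataset(n_per_class=8, seed=0):
    cohort = gen_cohort(n_per_class, n_per_class, seed=seed)
    return cohort_to_dataset(cohort, [r.subject_id for _, _, r in cohort.subjects])


class TestTraining:
    def test_loss_decreases_majority_of_seeds(self):
        """5 epochs on 16 synthetic subjects: training loss drops from
        epoch 1 to 5 for at least 2 of 3 seeds."""
        wins = 0
        data = _tiny_dataset(8, seed=1)
        for seed in (0, 1, 2):
            cfg = TrainConfig(epochs=5, batch_size=8, lr=1e-3, seed=seed)
            _, hist = train_one_fold(
                data, np.arange(12), np.arange(12, 16), ModelConfig(), cfg
            )
            wins += hist["train_loss"][-1] < hist["train_loss"][0]
        assert wins >= 2

    def test_zero_patience_stops_after_first_plateau(self):
        data = _tiny_dataset(4, seed=2)
        cfg = TrainConfig(epochs=50, batch_size=8, lr=1e-3, patience=0, seed=0)
        _, hist = train_one_fold(data, np.arange(6), np.arange(6, 8), ModelConfig(), cfg)
        vals = hist["val_loss"]
        # every epoch except the last improved on the best so far
        for i in range(1, len(vals) - 1):
            assert vals[i] < min(vals[:i])
        assert len(vals) < 50

    def test_training_is_deterministic(self):
        data = _tiny_dataset(4, seed=3)
        cfg = TrainConfig(epochs=2, batch_size=4, lr=1e-3, seed=5)
        m1, h1 = train_one_fold(data, np.arange(6), np.arange(6, 8), ModelConfig(), cfg)
        m2, h2 = train_one_fold(data, np.arange(6), np.arange(6, 8), ModelConfig(), cfg)
        assert h1["train_loss"] == h2["train_loss"]
        s1, s2 = m1.state_dict(), m2.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    def test_early_stop_returns_best_validation_params(self):
        data = _tiny_dataset(6, seed=4)
        cfg = TrainConfig(epochs=6, batch_size=8, lr=3e-3, patience=2, seed=1)
        model, hist = train_one_fold(
            data, np.arange(8), np.arange(8, 12), ModelConfig(), cfg
        )
        from trilightnet.train import _dataset_loss

        final_val = _dataset_loss(model, data, np.arange(8, 12), cfg)
        assert final_val <= min(hist["val_loss"]) + 1e-6

    def test_overlapping_indices_rejected(self):
        data = _tiny_dataset(2, seed=5)
        with pytest.raises(ValueError):
            train_one_fold(data, np.arange(3), np.arange(2, 4), ModelConfig(), TrainConfig())


class TestCrossValidation:
    def test_two_fold_smoke(self):
        """k=2 on 40 synthetic subjects: both folds report every metric
        and a seeded rerun reproduces them exactly."""
        cohort = gen_cohort(20, 20, seed=6)
        data = cohort_to_dataset(cohort, [r.subject_id for _, _, r in cohort.subjects])
        folds = make_cv_folds(cohort.labels(), k=2, seed=0)
        cfg = TrainConfig(epochs=2, batch_size=8, lr=1e-3, seed=3)
        res = run_cv(data, folds, ModelConfig(), cfg)
        assert len(res.fold_reports) == 2
        for rep in res.fold_reports:
            assert np.isfinite(rep.balanced_accuracy)
            assert np.isfinite(rep.auroc)
        # mean +- sd equals direct recomputation
        vals = [r.balanced_accuracy for r in res.fold_reports]
        mean, sd = res.summary["balanced_accuracy"]
        assert np.isclose(mean, np.mean(vals)) and np.isclose(sd, np.std(vals))
        res2 = run_cv(data, folds, ModelConfig(), cfg)
        assert [r.balanced_accuracy for r in res2.fold_reports] == vals
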