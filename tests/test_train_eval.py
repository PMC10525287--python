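"""Batch-size formula, stratified folds and confusion-metric arithmetic."""

import numpy as np
import pytest

from remwave.train_eval import (
    CVReport,
    FoldResult,
    TrainingConfig,
    aggregate,
    compute_stream_metrics,
    cross_validate,
    derive_batch_size,
    evaluate_fold,
    stratified_folds,
    train_fold,
)


class TestBatchSize:
    @pytest.mark.parametrize("R,V,C,expected", [
        (100, 0.1, 10, 10),
        (1, 0.1, 10, 1),
        (761, 0.1, 9, 77),   # int(76.1 + 1)
        (379, 0.1, 10, 35),
    ])
    def test_formula(self, R, V, C, expected):
        assert derive_batch_size(R, V, C) == expected

    def test_zero_records_rejected(self):
        with pytest.raises(ValueError):
            derive_batch_size(0, 0.1, 10)

    def test_config_resolution(self):
        cfg = TrainingConfig(cv_folds=10, validation_split=0.1)
        assert cfg.resolved_batch_size(100) == 10
        assert TrainingConfig(batch_size=64).resolved_batch_size(100) == 64


class TestStratifiedFolds:
    def test_exact_divisibility_keeps_ratio(self):
        y = np.array(["REM"] * 20 + ["NonREM"] * 80)
        folds = stratified_folds(y, 10, seed=0)
        for _, te in folds:
            assert np.sum(y[te] == "REM") == 2

    def test_partition(self):
        y = np.array(["REM"] * 15 + ["NonREM"] * 50)
        folds = stratified_folds(y, 5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(65))
        for tr, te in folds:
            assert set(tr).isdisjoint(te)

    def test_same_seed_same_folds(self):
        y = np.array(["REM"] * 10 + ["NonREM"] * 30)
        a = stratified_folds(y, 4, seed=9)
        b = stratified_folds(y, 4, seed=9)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(["REM"] * 10, 2, seed=0)

    def test_folds_exceeding_minority_rejected(self):
        y = ["REM"] * 3 + ["NonREM"] * 50
        with pytest.raises(ValueError):
            stratified_folds(y, 5, seed=0)


class TestFoldMetrics:
    def test_printed_fold_metrics_recovered(self):
        """Confusion counts from a 10-fold CV run reproduce their metrics."""
        good = FoldResult(tp=228, fp=11, fn=54, tn=1989)
        assert round(good.accuracy, 3) == 0.972
        assert round(good.specificity, 3) == 0.995
        assert round(good.recall, 3) == 0.809
        assert round(good.precision, 3) == 0.954
        assert round(good.f1, 3) == 0.875

        bad = FoldResult(tp=7, fp=17, fn=275, tn=1983)
        assert round(bad.precision, 3) == 0.292
        assert round(bad.recall, 3) == 0.025
        assert round(bad.f1, 3) == 0.046

    def test_perfect_predictor(self):
        f = FoldResult(tp=10, fp=0, fn=0, tn=40)
        assert f.accuracy == f.precision == f.recall == f.f1 == 1.0

    def test_zero_denominators_return_zero(self):
        f = FoldResult(tp=0, fp=0, fn=5, tn=45)
        assert f.precision == 0.0 and f.recall == 0.0 and f.f1 == 0.0

    def test_counts_sum_to_fold_size(self):
        f = FoldResult(tp=3, fp=4, fn=5, tn=8)
        assert f.n == 20

    def test_metric_identities_recomputed(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 100, 4)
            if tp + fp + fn + tn == 0:
                continue
            f = FoldResult(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))
            assert f.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))
            if tn + fp:
                assert f.specificity == pytest.approx(tn / (tn + fp))
            if tp + fn:
                assert f.recall == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert f.precision == pytest.approx(tp / (tp + fp))
            if f.precision + f.recall:
                assert f.f1 == pytest.approx(
                    2 * f.precision * f.recall / (f.precision + f.recall)
                )


class TestAggregate:
    # per-fold metric columns of a published-style 10-fold run
    ACCS = [0.872, 0.972, 0.976, 0.947, 0.971, 0.994, 0.995, 0.998, 0.999, 0.909]
    F1S = [0.046, 0.875, 0.892, 0.785, 0.865, 0.975, 0.981, 0.993, 0.996, 0.488]

    def test_unweighted_mean_of_columns(self):
        assert np.mean(self.ACCS) == pytest.approx(0.9633, abs=5e-5)
        assert np.mean(self.F1S) == pytest.approx(0.7896, abs=5e-5)

    def test_single_fold_average_is_that_fold(self):
        f = FoldResult(tp=5, fp=1, fn=2, tn=12)
        rep = aggregate([f])
        assert rep.averages["accuracy"] == f.accuracy
        assert rep.averages["f1"] == f.f1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_report_round_trip(self, tmp_path):
        rep = aggregate([FoldResult(2, 1, 1, 6), FoldResult(3, 0, 0, 7)])
        p = tmp_path / "rep.json"
        rep.save(p)
        import json

        d = json.loads(p.read_text())
        assert len(d["folds"]) == 2
        assert d["averages"]["accuracy"] == rep.averages["accuracy"]


class _ThresholdModel:
    """Deterministic stand-in classifier: REM iff mean(sample) > 0."""

    positive_class_ = "REM"
    history_ = None

    def predict(self, X):
        return np.where(np.asarray(X).mean(axis=1) > 0, "REM", "NonREM")


class TestEvaluateFold:
    def test_counts_from_threshold_model(self):
        X = np.vstack([np.ones((4, 3)), -np.ones((6, 3))])
        y = np.array(["REM"] * 3 + ["NonREM"] * 7)  # one REM labelled low
        f = evaluate_fold(_ThresholdModel(), (X, y))
        assert (f.tp, f.fp, f.fn, f.tn) == (3, 1, 0, 6)

    def test_stream_metrics_auc_matches_pairwise_ranking(self):
        """AUC equals the brute-force pairwise ranking probability."""
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 120)
        y[:3] = [0, 1, 0]
        s = rng.normal(size=120) + y * 0.8
        m = compute_stream_metrics(y, s)
        pos = s[y == 1]
        neg = s[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert m["auc_roc"] == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestTrainFold:
    def test_max_epochs_one_gives_one_history_row(self, small_dataset):
        from remwave.models import BandCNNClassifier

        X, y = small_dataset
        cfg = TrainingConfig(cv_folds=3, max_epochs=1, seed=0)
        model = BandCNNClassifier(random_state=0, kernel_size=10)
        fitted, hist = train_fold(model, (X, y), cfg)
        assert len(hist) == 1

    def test_constant_labels_rejected(self, small_dataset):
        from remwave.models import BandCNNClassifier

        X, _ = small_dataset
        cfg = TrainingConfig(cv_folds=3, max_epochs=1)
        with pytest.raises(ValueError):
            train_fold(BandCNNClassifier(), (X, ["NonREM"] * len(X)), cfg)

    def test_cross_validate_reproducible(self, small_dataset):
        from remwave.models import BandCNNClassifier

        X, y = small_dataset
        cfg = TrainingConfig(cv_folds=3, max_epochs=2, seed=4)
        model = BandCNNClassifier(random_state=4, kernel_size=10, dense_layers=(16,))
        r1 = cross_validate(model, X, y, cfg)
        r2 = cross_validate(model, X, y, cfg)
        for a, b in zip(r1.folds, r2.folds):
            assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)
        assert sum(f.n for f in r1.folds) == len(y)
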