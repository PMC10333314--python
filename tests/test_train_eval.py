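"""Class weights, aggregation, metrics, clinical bins, baselines, CV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxdep.dataio import make_folds
from voxdep.train_eval import (
    NoInformationBaseline,
    TrainConfig,
    aggregate_detection,
    aggregate_severity,
    clinical_bin,
    clinical_bin_matrix,
    compute_class_weights,
    compute_metrics,
    run_cross_validation,
    train_model,
)


def brute_force_metrics(y_true, y_pred):
    """Independent confusion-matrix oracle: explicit counting loops."""
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 1 and p == 0:
            fn += 1
        else:
            tn += 1

    def f1(tp_, fp_, fn_):
        prec = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        rec = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        return 2 * prec * rec / (prec + rec) if prec + rec else 0.0

    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return f1(tp, fp, fn), f1(tn, fn, fp), (sens + spec) / 2.0


class TestClassWeights:
    def test_inverse_frequency_70_30(self):
        labels = [0] * 70 + [1] * 30
        w = compute_class_weights(labels)
        # raw weights 100/140 and 100/60, normalised to mean 1
        raw = np.array([100 / 140, 100 / 60])
        assert w == pytest.approx(raw / raw.mean())
        assert w[1] / w[0] == pytest.approx(7 / 3)

    def test_balanced_classes_unit_weights(self):
        assert compute_class_weights([0, 1] * 10) == pytest.approx([1.0, 1.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights([0, 0, 0])


class TestAggregation:
    @pytest.mark.parametrize("decisions,expected", [
        ([1, 1, 0], 1),
        ([1, 0], 1),      # tie resolves to depressed
        ([0, 0, 0, 1], 0),
        ([0], 0),
    ])
    def test_majority_vote(self, decisions, expected):
        assert aggregate_detection(decisions) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_detection([])
        with pytest.raises(ValueError):
            aggregate_severity([])

    def test_severity_mean_and_clipping(self):
        assert aggregate_severity([4, 6, 8]) == pytest.approx(6.0)
        assert aggregate_severity([30.0], scale="PHQ8") == 24.0
        assert aggregate_severity([7.5]) == 7.5


class TestMetrics:
    def test_hand_computed_example(self):
        m = compute_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert m.f1_depressed == pytest.approx(2 / 3, abs=1e-9)
        assert m.f1_healthy == pytest.approx(0.8)
        assert m.balanced_accuracy == pytest.approx(0.75)

    def test_perfect_predictions(self):
        m = compute_metrics([1, 0, 1], [1, 0, 1])
        assert (m.f1_depressed, m.f1_healthy, m.balanced_accuracy) == (1, 1, 1)

    def test_rmse(self):
        m = compute_metrics(score_true=[5, 9], score_pred=[5, 7])
        assert m.rmse == pytest.approx(np.sqrt(2.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 0], [1])

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=50))
    def test_matches_brute_force_oracle(self, pairs):
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        m = compute_metrics(y_true, y_pred)
        f1d, f1h, bac = brute_force_metrics(y_true, y_pred)
        assert m.f1_depressed == pytest.approx(f1d, abs=1e-12)
        assert m.f1_healthy == pytest.approx(f1h, abs=1e-12)
        assert m.balanced_accuracy == pytest.approx(bac, abs=1e-12)


class TestClinicalBins:
    @pytest.mark.parametrize("score,name", [
        (0, "None"), (8, "None"), (8.4, "None"), (9, "Mild"), (12, "Mild"),
        (13, "Moderate"), (16, "Moderate"), (17, "Severe"), (24, "Severe"),
    ])
    def test_bin_edges(self, score, name):
        assert clinical_bin(score) == name

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            clinical_bin(25)

    def test_matrix_row_sums_are_true_counts(self, rng):
        true = rng.uniform(0, 24, size=40)
        pred_a = rng.uniform(0, 24, size=40)
        pred_b = np.full(40, 5.0)
        m_a = clinical_bin_matrix(true, pred_a)
        m_b = clinical_bin_matrix(true, pred_b)
        # row sums depend on the truths only, not on the predictor
        assert np.array_equal(m_a.row_sums(), m_b.row_sums())
        assert m_a.counts.sum() == 40


class TestNoInformationBaseline:
    def test_constant_mean_prediction(self):
        b = NoInformationBaseline().fit(train_scores=[2, 4, 6])
        assert np.all(b.predict_score(5) == 4.0)

    def test_majority_class_prediction(self):
        b = NoInformationBaseline().fit(train_labels=[0, 0, 0, 1])
        assert np.all(b.predict_label(3) == 0)

    def test_rmse_equals_test_std_when_means_match(self, rng):
        test = rng.normal(10, 3, size=500)
        b = NoInformationBaseline().fit(train_scores=[10.0])
        m = compute_metrics(score_true=test, score_pred=b.predict_score(500))
        assert m.rmse == pytest.approx(
            np.sqrt(np.mean((test - 10.0) ** 2)), rel=1e-12)


class TestTraining:
    def test_linear_severity_signal_learned(self, rng):
        # noise-free linear target: training MSE (evaluation mode, final
        # model) must fall below 1% of the initial target variance
        X = rng.standard_normal((240, 8, 6)).astype(np.float32)
        y = 12 + 4 * X[:, :, 0].mean(axis=1)
        reg = train_model("mkcnn", "severity", X, y,
                         TrainConfig(epochs=50, batch_size=16, seed=0))
        mse = float(np.mean((reg.predict(X) - y) ** 2))
        assert mse < 0.01 * np.var(y)

    def test_shuffled_labels_give_chance_heldout(self, small_cohort, rng):
        from voxdep.features import build_context_windows, stack_windows

        wins = [w for r in small_cohort.recordings
                for w in build_context_windows(
                    small_cohort.embeddings[r.recording_id], 8, 2,
                    r.recording_id, label=r.label)]
        X = stack_windows(wins)
        y = rng.permutation(np.array([w.label for w in wins]))
        half = len(X) // 2
        clf = train_model("dnn", "detect", X[:half], y[:half],
                         TrainConfig(epochs=10, batch_size=32, seed=1),
                         pool=True)
        m = compute_metrics(y[half:], clf.predict(X[half:]))
        assert 0.3 < m.balanced_accuracy < 0.7

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((40, 8, 6)).astype(np.float32)
        y = (X[:, :, 0].mean(axis=1) > 0).astype(int)
        cfg = TrainConfig(epochs=3, batch_size=16, seed=4)
        a = train_model("lstm", "detect", X, y, cfg)
        b = train_model("lstm", "detect", X, y, cfg)
        assert a.loss_curve_ == b.loss_curve_


class TestCrossValidation:
    def test_speaker_disjoint_pipeline_recovers_signal(self, small_cohort):
        folds = make_folds(small_cohort.recordings, k=5, seed=0)
        cfg = TrainConfig(epochs=15, batch_size=16, context=8, stride=1, seed=0)
        res = run_cross_validation(small_cohort.recordings,
                                   small_cohort.embeddings, folds,
                                   family="mkcnn", task="detect", config=cfg)
        assert res.pooled.balanced_accuracy >= 0.75
        assert len(res.per_fold) == 5
        assert res.pooled.n == len(small_cohort.recordings)

    def test_severity_task_reports_rmse_and_bins(self, small_cohort):
        folds = make_folds(small_cohort.recordings, k=5, seed=0)
        cfg = TrainConfig(epochs=8, batch_size=16, context=8, stride=2, seed=0)
        res = run_cross_validation(small_cohort.recordings,
                                   small_cohort.embeddings, folds,
                                   family="dnn", task="severity", config=cfg,
                                   pool=True)
        assert res.pooled.rmse is not None and res.pooled.rmse >= 0
        assert res.bin_matrix is not None
        assert res.bin_matrix.counts.sum() == len(small_cohort.recordings)
        assert res.baseline.rmse >= res.pooled.rmse * 0  # defined

    def test_no_test_fold_leakage_into_training(self, small_cohort):
        """Perturbing held-out features must not change the fitted fold model."""
        from voxdep.features import FeatureScaler, build_context_windows, stack_windows
        from voxdep.models import WindowClassifier

        folds = make_folds(small_cohort.recordings, k=5, seed=0)
        train_ids = folds.train_recordings(0)
        test_ids = folds.test_recordings(0)
        feats = dict(small_cohort.embeddings)
        by_id = {r.recording_id: r for r in small_cohort.recordings}

        def fit_fold(features):
            scaler = FeatureScaler().fit(
                np.concatenate([features[r] for r in train_ids]))
            wins = [w for r in train_ids for w in build_context_windows(
                scaler.transform(features[r]), 8, 2, r,
                label=by_id[r].label)]
            X = stack_windows(wins)
            y = np.array([w.label for w in wins])
            return WindowClassifier(family="dnn", pool=True, epochs=3,
                                    batch_size=16, random_state=0).fit(X, y)

        ref = fit_fold(feats)
        feats_perturbed = dict(feats)
        for rid in test_ids:
            feats_perturbed[rid] = feats[rid] + 100.0
        alt = fit_fold(feats_perturbed)
        for p, q in zip(ref.network_.params(), alt.network_.params()):
            assert np.array_equal(p.value, q.value)
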