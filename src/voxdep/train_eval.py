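"""Training, cross-validated evaluation and clinical reporting.

Evaluation follows the recording-level protocol: networks are trained and
scored on context windows, but the reported metrics are computed per
recording after aggregation — majority vote over window decisions for
detection (ties resolved towards "depressed": in screening a false negative
is the costlier error), and the mean of window scores (clipped to the
severity scale) for severity estimation.

Cross-validation is 5-fold, speaker-disjoint and label-stratified.  Within
each fold the feature scaler, the class weights and the model are fitted on
the training folds only.  Detection quality is summarised by per-class F1
(depressed and healthy) and balanced accuracy; severity by RMSE.  A
no-information baseline (constant majority class / constant training-mean
score) is evaluated on the same splits, and severity predictions can be
binned into the four clinical PHQ-8 groups (None <= 8, Mild 9-12,
Moderate 13-16, Severe 17-24) to build confusion matrices over clinical
levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score

from .dataio import DEPRESSION_THRESHOLD, SCALE_RANGES, FoldAssignment, RecordingRecord
from .features import FeatureScaler, build_context_windows, stack_windows
from .models import WindowClassifier, WindowRegressor

CLINICAL_BINS = ("None", "Mild", "Moderate", "Severe")
#: upper edge (inclusive) of each clinical PHQ-8 bin
_BIN_UPPER = (8, 12, 16, 24)


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the training recipe)."""

    learning_rate: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.99
    epochs: int = 50
    batch_size: int = 128
    context: int = 16
    stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class MetricsReport:
    """Recording-level performance summary."""

    f1_depressed: float | None = None
    f1_healthy: float | None = None
    balanced_accuracy: float | None = None
    rmse: float | None = None
    confusion: dict = field(default_factory=dict)
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "f1_depressed": self.f1_depressed,
            "f1_healthy": self.f1_healthy,
            "balanced_accuracy": self.balanced_accuracy,
            "rmse": self.rmse,
            "n": self.n,
        }


@dataclass
class ClinicalBinMatrix:
    """4x4 counts over clinical severity groups (rows true, cols predicted)."""

    counts: np.ndarray
    bins: tuple = CLINICAL_BINS

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def compute_class_weights(labels) -> np.ndarray:
    """Inverse-frequency class weights, normalised to mean 1.

    weight_c is proportional to total / (2 * count_c); both classes must be
    present in the training labels.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if (counts == 0).any():
        raise ValueError("both classes must be present to compute class weights")
    raw = counts.sum() / (2.0 * counts)
    return raw / raw.mean()


def aggregate_detection(decisions) -> int:
    """Majority vote over window decisions; ties resolve to depressed (1)."""
    decisions = np.asarray(decisions, dtype=int)
    if decisions.size == 0:
        raise ValueError("no decisions to aggregate")
    ones = int(decisions.sum())
    return int(ones >= decisions.size - ones)


def aggregate_severity(scores, scale: str = "PHQ8") -> float:
    """Mean of window scores, clipped to the severity-scale range."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to aggregate")
    lo, hi = SCALE_RANGES[scale]
    return float(np.clip(scores.mean(), lo, hi))


def compute_metrics(y_true=None, y_pred=None,
                    score_true=None, score_pred=None) -> MetricsReport:
    """Per-class F1, balanced accuracy and/or severity RMSE.

    Balanced accuracy is the mean of sensitivity (depressed recall) and
    specificity (healthy recall).
    """
    report = MetricsReport()
    if y_true is not None:
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction/truth length mismatch")
        report.f1_depressed = float(f1_score(y_true, y_pred, pos_label=1,
                                             zero_division=0))
        report.f1_healthy = float(f1_score(y_true, y_pred, pos_label=0,
                                           zero_division=0))
        cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
        tn, fp, fn, tp = cm.ravel()
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        report.balanced_accuracy = float((sens + spec) / 2.0)
        report.confusion = {"tn": int(tn), "fp": int(fp),
                            "fn": int(fn), "tp": int(tp)}
        report.n = int(y_true.size)
    if score_true is not None:
        score_true = np.asarray(score_true, dtype=float)
        score_pred = np.asarray(score_pred, dtype=float)
        if score_true.shape != score_pred.shape:
            raise ValueError("prediction/truth length mismatch")
        report.rmse = float(np.sqrt(np.mean((score_true - score_pred) ** 2)))
        report.n = int(score_true.size)
    return report


def clinical_bin(score: float) -> str:
    """Clinical PHQ-8 group of a (possibly continuous) severity score.

    Predicted regression scores are rounded to the nearest integer (numpy
    half-to-even) before binning.
    """
    lo, hi = SCALE_RANGES["PHQ8"]
    if not lo <= score <= hi:
        raise ValueError(f"PHQ-8 score {score} outside [{lo}, {hi}]")
    rounded = int(np.rint(score))
    for name, upper in zip(CLINICAL_BINS, _BIN_UPPER):
        if rounded <= upper:
            return name
    raise AssertionError("unreachable")


def clinical_bin_matrix(true_scores, pred_scores) -> ClinicalBinMatrix:
    """4x4 confusion matrix over clinical PHQ-8 groups."""
    idx = {name: i for i, name in enumerate(CLINICAL_BINS)}
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(true_scores, pred_scores, strict=True):
        counts[idx[clinical_bin(t)], idx[clinical_bin(p)]] += 1
    return ClinicalBinMatrix(counts=counts)


class NoInformationBaseline:
    """Constant predictor: majority class for detection, mean for severity."""

    def fit(self, train_labels=None, train_scores=None) -> "NoInformationBaseline":
        if train_labels is None and train_scores is None:
            raise ValueError("baseline needs training labels and/or scores")
        if train_labels is not None:
            labels = np.asarray(train_labels, dtype=int)
            ones = int(labels.sum())
            self.majority_label_ = int(ones > labels.size - ones)
        if train_scores is not None:
            self.mean_score_ = float(np.mean(train_scores))
        return self

    def predict_label(self, n: int) -> np.ndarray:
        return np.full(n, self.majority_label_, dtype=int)

    def predict_score(self, n: int) -> np.ndarray:
        return np.full(n, self.mean_score_, dtype=float)


def train_model(family: str, task: str, X, y, config: TrainConfig | None = None,
                **kwargs):
    """Fit one network on pre-built windows; thin wrapper over the estimators.

    Returns the fitted estimator; its ``loss_curve_`` holds the per-epoch
    training loss.
    """
    config = config or TrainConfig()
    cls = WindowClassifier if task == "detect" else WindowRegressor
    est = cls(family=family, epochs=config.epochs, batch_size=config.batch_size,
              learning_rate=config.learning_rate, beta1=config.beta1,
              beta2=config.beta2, random_state=config.seed, **kwargs)
    return est.fit(X, y)


@dataclass
class CVResult:
    """Outcome of a speaker-disjoint cross-validation run."""

    task: str
    pooled: MetricsReport
    per_fold: list
    baseline: MetricsReport
    bin_matrix: ClinicalBinMatrix | None = None
    baseline_bin_matrix: ClinicalBinMatrix | None = None
    predictions: dict = field(default_factory=dict)
    baseline_predictions: dict = field(default_factory=dict)


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence(entropy=(int(seed), int(fold)))
               .generate_state(1)[0] % (2 ** 31))


def run_cross_validation(
    records: list[RecordingRecord],
    features: dict,
    folds: FoldAssignment,
    family: str = "lstm",
    task: str = "detect",
    config: TrainConfig | None = None,
    split_at: int | None = None,
    ensemble: int = 1,
    **estimator_kwargs,
) -> CVResult:
    """Speaker-disjoint k-fold evaluation of one network family.

    ``features`` maps recording_id to an (n_segments, L) matrix (for the
    fusion families, the two streams concatenated along the feature axis
    with ``split_at`` marking the boundary).  Per fold: a feature scaler and
    (for detection) class weights are fitted on training-fold data only, the
    model is trained on training windows, and held-out recordings are scored
    through window aggregation.  Pooled metrics concatenate all held-out
    predictions; per-fold metrics are also reported.
    """
    config = config or TrainConfig()
    by_id = {r.recording_id: r for r in records}
    scale = records[0].scale

    pred_labels: dict = {}
    pred_scores: dict = {}
    base_labels: dict = {}
    base_scores: dict = {}
    per_fold = []

    for fold in range(folds.k):
        train_ids = [r for r in folds.train_recordings(fold) if r in by_id]
        test_ids = [r for r in folds.test_recordings(fold) if r in by_id]
        if not train_ids or not test_ids:
            raise ValueError(f"fold {fold} has an empty train or test side")
        train_recs = [by_id[r] for r in train_ids]
        test_recs = [by_id[r] for r in test_ids]
        if task == "detect" and len({r.label for r in train_recs}) < 2:
            raise ValueError(f"fold {fold} training side has a single class")

        scaler = FeatureScaler().fit(
            np.concatenate([features[r] for r in train_ids], axis=0))

        def windows_of(rec):
            segs = scaler.transform(features[rec.recording_id])
            return build_context_windows(
                segs, config.context, config.stride, rec.recording_id,
                label=rec.label, severity=rec.severity_score)

        train_windows = [w for rec in train_recs for w in windows_of(rec)]
        X = stack_windows(train_windows)
        if task == "detect":
            y = np.array([w.label for w in train_windows])
        else:
            y = np.array([w.severity for w in train_windows])

        est_cls = WindowClassifier if task == "detect" else WindowRegressor
        members = []
        for m in range(ensemble):
            est = est_cls(family=family, split_at=split_at,
                          epochs=config.epochs, batch_size=config.batch_size,
                          learning_rate=config.learning_rate, beta1=config.beta1,
                          beta2=config.beta2,
                          random_state=_fold_seed(config.seed, fold * 1000 + m),
                          **estimator_kwargs)
            members.append(est.fit(X, y))

        baseline = NoInformationBaseline().fit(
            train_labels=[r.label for r in train_recs],
            train_scores=[r.severity_score for r in train_recs])

        fold_truth_l, fold_pred_l = [], []
        fold_truth_s, fold_pred_s = [], []
        for rec in test_recs:
            wins = windows_of(rec)
            Xw = stack_windows(wins)
            if task == "detect":
                # ensemble members vote through averaged window posteriors
                proba = np.mean([m.predict_proba(Xw) for m in members], axis=0)
                out = proba.argmax(axis=1)
            else:
                out = np.mean([m.predict(Xw) for m in members], axis=0)
            if task == "detect":
                pred = aggregate_detection(out)
                pred_labels[rec.recording_id] = pred
                base_labels[rec.recording_id] = int(baseline.predict_label(1)[0])
                fold_truth_l.append(rec.label)
                fold_pred_l.append(pred)
            else:
                pred = aggregate_severity(out, scale)
                pred_scores[rec.recording_id] = pred
                base_scores[rec.recording_id] = float(baseline.predict_score(1)[0])
                fold_truth_s.append(rec.severity_score)
                fold_pred_s.append(pred)
        if task == "detect":
            per_fold.append(compute_metrics(fold_truth_l, fold_pred_l))
        else:
            per_fold.append(compute_metrics(score_true=fold_truth_s,
                                            score_pred=fold_pred_s))

    ids = sorted(pred_labels) if task == "detect" else sorted(pred_scores)
    if task == "detect":
        truth = [by_id[r].label for r in ids]
        pooled = compute_metrics(truth, [pred_labels[r] for r in ids])
        baseline_report = compute_metrics(truth, [base_labels[r] for r in ids])
        bin_matrix = baseline_bin_matrix = None
    else:
        truth = [by_id[r].severity_score for r in ids]
        pooled = compute_metrics(score_true=truth,
                                 score_pred=[pred_scores[r] for r in ids])
        baseline_report = compute_metrics(
            score_true=truth, score_pred=[base_scores[r] for r in ids])
        bin_matrix = baseline_bin_matrix = None
        if scale == "PHQ8":
            bin_matrix = clinical_bin_matrix(truth, [pred_scores[r] for r in ids])
            baseline_bin_matrix = clinical_bin_matrix(
                truth, [base_scores[r] for r in ids])

    return CVResult(
        task=task, pooled=pooled, per_fold=per_fold, baseline=baseline_report,
        bin_matrix=bin_matrix, baseline_bin_matrix=baseline_bin_matrix,
        predictions=pred_labels if task == "detect" else pred_scores,
        baseline_predictions=base_labels if task == "detect" else base_scores,
    )
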