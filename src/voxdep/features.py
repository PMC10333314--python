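"""Per-segment feature assembly: summary statistics, scaling, context windows.

Segment-level inputs come in three flavours: speaker-identity embeddings
(x-vector 512-d, ECAPA-TDNN 256-d, d-vector 192-d, or synthetic), 384-d
OpenSMILE-style vectors, and frame-level COVAREP matrices which are reduced
to 6 higher-order statistics per coefficient (74 coefficients -> 444 dims).

Models consume *context windows*: C contiguous segments of one recording
stacked into a C x L matrix, labelled with the recording's label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: canonical embedding dimensions per extractor kind
EMBEDDING_DIMS = {"xvector": 512, "ecapa": 256, "dvector": 192}

#: statistic order of covarep_statistics (stat-major)
COVAREP_STATS = ("mean", "max", "min", "std", "skew", "kurtosis")


def covarep_statistics(frames: np.ndarray) -> np.ndarray:
    """Higher-order statistics of a T x d frame matrix, stat-major order.

    Returns a length 6*d vector: all means, then maxima, minima, population
    standard deviations, skews and Fisher (excess) kurtoses.  Zero-variance
    columns yield skew = 0 and kurtosis = 0 by convention.  With the 74
    standard COVAREP coefficients this reproduces the 444-dim descriptor.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[0] < 1:
        raise ValueError("frames must be a non-empty T x d matrix")
    std = frames.std(axis=0, ddof=0)
    degenerate = std == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = sps.skew(frames, axis=0, bias=True)
        kurt = sps.kurtosis(frames, axis=0, fisher=True, bias=True)
    skew = np.where(degenerate, 0.0, skew)
    kurt = np.where(degenerate, 0.0, kurt)
    return np.concatenate([
        frames.mean(axis=0),
        frames.max(axis=0),
        frames.min(axis=0),
        std,
        skew,
        kurt,
    ])


class FeatureScaler:
    """Per-dimension z-scoring with train-set statistics and a 1e-8 std floor.

    Fitted on training-fold features only; validation/test matrices are
    transformed with the training parameters, never refitted.
    """

    STD_FLOOR = 1e-8

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training matrix must be non-empty and 2-D")
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.maximum(X.std(axis=0, ddof=0), self.STD_FLOOR)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean_.shape[0]:
            raise ValueError(
                f"dimension mismatch: fitted {self.mean_.shape[0]}, got {X.shape[-1]}"
            )
        return (X - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def normalize_features(train: np.ndarray, *apply_to: np.ndarray):
    """Z-score ``train`` and transform the other matrices with its statistics.

    Returns ``(train_z, *apply_to_z, scaler)``.
    """
    scaler = FeatureScaler().fit(train)
    out = [scaler.transform(train)] + [scaler.transform(m) for m in apply_to]
    return (*out, scaler)


@dataclass
class ContextWindow:
    """C contiguous segments of one recording, with the inherited label."""

    matrix: np.ndarray
    recording_id: str
    window_index: int
    label: int | None = None
    severity: float | None = None
    padded: bool = False


def build_context_windows(
    features: np.ndarray,
    context: int,
    stride: int = 1,
    recording_id: str = "",
    label: int | None = None,
    severity: float | None = None,
) -> list[ContextWindow]:
    """Sliding C-segment windows over one recording's feature matrix.

    Windows start every ``stride`` segments.  A recording with fewer than
    ``context`` segments yields a single window padded cyclically (rows
    repeat from the top) and flagged ``padded=True``.
    """
    if context < 1:
        raise ValueError("context must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    windows = []
    if n < context:
        rows = features[np.arange(context) % n]
        windows.append(ContextWindow(rows, recording_id, 0, label, severity, True))
        return windows
    for w, start in enumerate(range(0, n - context + 1, stride)):
        windows.append(ContextWindow(
            features[start:start + context], recording_id, w, label, severity,
        ))
    return windows


def window_count(n_segments: int, context: int, stride: int = 1) -> int:
    """Number of windows a recording yields (always at least one)."""
    if n_segments < context:
        return 1
    return (n_segments - context) // stride + 1


def stack_windows(windows) -> np.ndarray:
    """Stack a list of ContextWindow into an (n, C, L) array."""
    return np.stack([w.matrix for w in windows])
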