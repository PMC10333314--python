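"""Longitudinal analysis: does a change in depression severity move a
speaker's embedding?

For speakers recorded at several visits, each recording is summarised by the
length-normalised mean of its segment embeddings.  Genuine verification
trials pair two visits of the same speaker and carry the absolute severity
difference between the visits; impostor trials pair recordings of different
speakers.  Two curves are reported against binned severity change: the mean
cosine similarity of genuine trials, and the verification equal error rate
(EER) of each bin's genuine trials against a shared impostor set (shared so
that only the genuine population varies across bins).

A speaker-classification probe (multinomial logistic regression on segment
embeddings, 25 train / 15 test segments per speaker) quantifies how much
speaker identity the embeddings retain, again as an EER in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
import logging

import numpy as np
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)


@dataclass
class TrialPair:
    """One verification trial between two recordings."""

    speaker_id: str
    recording_a: str
    recording_b: str
    delta_severity: float
    similarity: float
    genuine: bool


@dataclass
class DeltaCurve:
    """A per-bin summary (mean +/- sd, or EER) against severity change."""

    bin_edges: np.ndarray      # len B+1
    values: np.ndarray         # len B, NaN where the bin is unoccupied
    stds: np.ndarray
    counts: np.ndarray

    def occupied(self) -> np.ndarray:
        return ~np.isnan(self.values)


def cosine_similarity(a, b) -> float:
    """Inner product over the norm product, clipped to [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def recording_embedding(segment_embeddings, pooling: str = "mean") -> np.ndarray:
    """Length-normalised mean (or median) of a recording's segment embeddings."""
    mat = np.asarray(segment_embeddings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ValueError("need a non-empty n x L matrix of segment embeddings")
    pooled = np.median(mat, axis=0) if pooling == "median" else mat.mean(axis=0)
    norm = np.linalg.norm(pooled)
    if norm == 0:
        raise ValueError("pooled embedding has zero norm")
    return pooled / norm


def build_trials(cohort, impostor_ratio: float = 10.0, seed: int = 0,
                 pooling: str = "mean") -> list[TrialPair]:
    """Genuine and impostor verification trials from a longitudinal cohort.

    Genuine trials are all within-speaker visit pairs; impostor trials are
    cross-speaker recording pairs subsampled to ``impostor_ratio`` times the
    genuine count under ``seed``.
    """
    by_speaker: dict = {}
    for rec in cohort.recordings:
        by_speaker.setdefault(rec.speaker_id, []).append(rec)
    if not any(len(v) >= 2 for v in by_speaker.values()):
        raise ValueError("no speaker with at least two visits")

    emb = {r.recording_id: recording_embedding(cohort.embeddings[r.recording_id],
                                               pooling)
           for r in cohort.recordings}
    severity = {r.recording_id: r.severity_score for r in cohort.recordings}

    trials = []
    for spk, recs in sorted(by_speaker.items()):
        for a, b in combinations(sorted(recs, key=lambda r: r.recording_id), 2):
            trials.append(TrialPair(
                speaker_id=spk,
                recording_a=a.recording_id,
                recording_b=b.recording_id,
                delta_severity=abs(severity[a.recording_id] - severity[b.recording_id]),
                similarity=cosine_similarity(emb[a.recording_id], emb[b.recording_id]),
                genuine=True,
            ))
    n_genuine = len(trials)

    all_recs = sorted(r.recording_id for r in cohort.recordings)
    spk_of = {r.recording_id: r.speaker_id for r in cohort.recordings}
    pool = [(a, b) for a, b in combinations(all_recs, 2) if spk_of[a] != spk_of[b]]
    rng = np.random.default_rng(seed)
    n_imp = min(len(pool), int(round(impostor_ratio * n_genuine)))
    idx = rng.choice(len(pool), size=n_imp, replace=False)
    for i in sorted(idx):
        a, b = pool[i]
        trials.append(TrialPair(
            speaker_id="",
            recording_a=a,
            recording_b=b,
            delta_severity=abs(severity[a] - severity[b]),
            similarity=cosine_similarity(emb[a], emb[b]),
            genuine=False,
        ))
    return trials


def compute_eer(genuine_scores, impostor_scores) -> float:
    """Verification equal error rate by threshold sweep with interpolation.

    At threshold t, FRR(t) is the fraction of genuine scores below t and
    FAR(t) the fraction of impostor scores at or above t.  The EER is taken
    at the FRR/FAR crossing, linearly interpolated between adjacent
    candidate thresholds (the pooled score values).
    """
    g = np.sort(np.asarray(genuine_scores, dtype=float))
    i = np.sort(np.asarray(impostor_scores, dtype=float))
    if g.size == 0 or i.size == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = np.unique(np.concatenate([g, i]))
    # vectorized counts via sorted-array searches
    frr = np.searchsorted(g, thresholds, side="left") / g.size
    far = 1.0 - np.searchsorted(i, thresholds, side="left") / i.size
    diff = far - frr
    # diff starts >= 0 (lowest threshold: frr=0) and ends <= 0
    if diff[0] <= 0:
        return float((far[0] + frr[0]) / 2.0)
    k = int(np.argmax(diff <= 0))
    if k == 0:
        return float((far[-1] + frr[-1]) / 2.0)
    d0, d1 = diff[k - 1], diff[k]
    if d0 == d1:
        w = 0.0
    else:
        w = d0 / (d0 - d1)
    eer = frr[k - 1] + w * (frr[k] - frr[k - 1])
    return float(eer)


def delta_curves(trials, bin_width: float = 5.0, min_count: int = 5,
                 max_delta: float | None = None) -> tuple[DeltaCurve, DeltaCurve]:
    """Similarity and EER curves against binned severity change.

    Bins of ``bin_width`` start at 0.  A bin contributes a value only when it
    holds at least ``min_count`` genuine trials.  The EER of each bin uses
    that bin's genuine similarities against the shared impostor set.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    genuine = [t for t in trials if t.genuine]
    impostor_scores = np.array([t.similarity for t in trials if not t.genuine])
    deltas = np.array([t.delta_severity for t in genuine])
    sims = np.array([t.similarity for t in genuine])
    top = max_delta if max_delta is not None else (deltas.max() if deltas.size else 0)
    n_bins = max(1, int(np.ceil((top + 1e-9) / bin_width)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width

    means = np.full(n_bins, np.nan)
    stds = np.full(n_bins, np.nan)
    eers = np.full(n_bins, np.nan)
    eer_stds = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    which = np.minimum((deltas // bin_width).astype(int), n_bins - 1)
    for b in range(n_bins):
        sel = sims[which == b]
        counts[b] = sel.size
        if sel.size >= min_count:
            means[b] = sel.mean()
            stds[b] = sel.std(ddof=0)
            if impostor_scores.size:
                eers[b] = compute_eer(sel, impostor_scores)
    sim_curve = DeltaCurve(edges, means, stds, counts.copy())
    eer_curve = DeltaCurve(edges, eers, eer_stds, counts.copy())
    return sim_curve, eer_curve


def speaker_probe(segment_embeddings: dict, train_per_speaker: int = 25,
                  test_per_speaker: int = 15, seed: int = 0) -> float:
    """Speaker-classification probe EER (percent).

    ``segment_embeddings`` maps speaker_id to an (n, L) matrix of that
    speaker's segment embeddings.  For each speaker with at least
    ``train_per_speaker + test_per_speaker`` segments, non-overlapping train
    and test subsets are sampled; a multinomial logistic regression (no
    hidden layers) is fitted on the train segments.  Verification scores are
    the test-segment posteriors: the true speaker's posterior is a genuine
    score, every other speaker's posterior an impostor score.
    """
    need = train_per_speaker + test_per_speaker
    rng = np.random.default_rng(seed)
    speakers = []
    for spk in sorted(segment_embeddings):
        if segment_embeddings[spk].shape[0] >= need:
            speakers.append(spk)
        else:
            logger.info("speaker %s has < %d segments; excluded from probe",
                        spk, need)
    if len(speakers) < 2:
        raise ValueError("need at least two speakers with enough segments")

    X_train, y_train, X_test, y_test = [], [], [], []
    for ci, spk in enumerate(speakers):
        mat = np.asarray(segment_embeddings[spk], dtype=float)
        idx = rng.permutation(mat.shape[0])
        X_train.append(mat[idx[:train_per_speaker]])
        y_train += [ci] * train_per_speaker
        X_test.append(mat[idx[train_per_speaker:need]])
        y_test += [ci] * test_per_speaker
    X_train = np.concatenate(X_train)
    X_test = np.concatenate(X_test)
    y_train = np.array(y_train)
    y_test = np.array(y_test)

    clf = LogisticRegression(max_iter=2000, C=10.0)
    clf.fit(X_train, y_train)
    post = clf.predict_proba(X_test)

    rows = np.arange(len(y_test))
    genuine = post[rows, y_test]
    mask = np.ones_like(post, dtype=bool)
    mask[rows, y_test] = False
    impostor = post[mask]
    return 100.0 * compute_eer(genuine, impostor)


def trials_to_frame(trials):
    """Trial list as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([{
        "speaker_id": t.speaker_id,
        "rec_a": t.recording_a,
        "rec_b": t.recording_b,
        "delta": t.delta_severity,
        "cosine": t.similarity,
        "genuine": t.genuine,
    } for t in trials])
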