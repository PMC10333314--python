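"""Manifests, transcripts, participant-speech retention, segmentation and folds.

Recordings are clinical speech samples, each scored on one of two depression
severity scales (PHQ-8, range 0-24, or MADRS, range 0-60; a score >= 10 counts
as depressed on either scale).  Interview transcripts arrive as tab-separated
files with ``start_time``, ``stop_time``, ``speaker`` and ``value`` columns;
only the participant's speech is retained, concatenated, and tiled into
non-overlapping 5-6 s segments whose label is inherited from the recording.

Cross-validation folds are built at the *speaker* level: every recording of a
speaker lands in that speaker's fold, and depressed/healthy speaker
proportions are stratified across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: severity-scale bounds, inclusive
SCALE_RANGES = {"PHQ8": (0.0, 24.0), "MADRS": (0.0, 60.0)}

#: clinical cut-off shared by both scales: score >= 10 -> depressed
DEPRESSION_THRESHOLD = 10.0

#: gap below which adjacent participant intervals are merged (seconds)
MERGE_GAP = 0.05


@dataclass(frozen=True)
class Utterance:
    """One transcript row with half-open time span [start_time, stop_time)."""

    start_time: float
    stop_time: float
    speaker_tag: str  # "participant" or "other"
    text: str = ""

    def __post_init__(self) -> None:
        if not self.stop_time > self.start_time >= 0:
            raise ValueError(
                f"utterance times must satisfy stop > start >= 0, "
                f"got [{self.start_time}, {self.stop_time})"
            )


@dataclass
class RecordingRecord:
    """One scored speech sample from one speaker."""

    recording_id: str
    speaker_id: str
    severity_score: float
    scale: str = "PHQ8"
    dataset_tag: str = ""
    sex: str | None = None
    age: float | None = None
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale not in SCALE_RANGES:
            raise ValueError(f"unknown scale {self.scale!r}")
        lo, hi = SCALE_RANGES[self.scale]
        if not lo <= self.severity_score <= hi:
            raise ValueError(
                f"{self.scale} score {self.severity_score} outside [{lo}, {hi}]"
            )

    @property
    def label(self) -> int:
        return label_recording(self.severity_score, self.scale)


@dataclass
class FoldAssignment:
    """Speaker-disjoint k-fold split of a cohort."""

    k: int
    recording_to_fold: dict
    speaker_to_fold: dict

    def test_recordings(self, fold: int) -> list:
        return [r for r, f in self.recording_to_fold.items() if f == fold]

    def train_recordings(self, fold: int) -> list:
        return [r for r, f in self.recording_to_fold.items() if f != fold]


def read_transcript(path) -> list[Utterance]:
    """Parse a tab-separated transcript into utterances.

    Expects columns ``start_time``, ``stop_time``, ``speaker``, ``value``.
    Speaker tags are mapped case-insensitively: "participant" maps to the
    participant, anything else (interviewer, virtual agent, ...) to "other".
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"start_time", "stop_time", "speaker"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript {path} missing columns {sorted(missing)}")
    utterances = []
    for i, row in df.iterrows():
        try:
            t0 = float(row["start_time"])
            t1 = float(row["stop_time"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"transcript {path} row {i}: non-numeric time") from exc
        if not t1 > t0 >= 0:
            raise ValueError(
                f"transcript {path} row {i}: stop_time {t1} <= start_time {t0}"
            )
        tag = "participant" if str(row["speaker"]).strip().lower() == "participant" else "other"
        text = str(row["value"]) if "value" in df.columns and pd.notna(row.get("value")) else ""
        utterances.append(Utterance(t0, t1, tag, text))
    return utterances


def retain_participant_speech(
    utterances: Iterable[Utterance], merge_gap: float = MERGE_GAP
) -> list[tuple[float, float]]:
    """Keep only participant speech, merging near-adjacent intervals.

    Intervals separated by less than ``merge_gap`` seconds are joined;
    overlapping participant intervals are merged and logged.
    """
    spans = sorted(
        (u.start_time, u.stop_time) for u in utterances if u.speaker_tag == "participant"
    )
    merged: list[list[float]] = []
    for t0, t1 in spans:
        if merged and t0 < merged[-1][1]:
            logger.warning("overlapping participant intervals at %.3f s; merging", t0)
            merged[-1][1] = max(merged[-1][1], t1)
        elif merged and t0 - merged[-1][1] < merge_gap:
            merged[-1][1] = t1
        else:
            merged.append([t0, t1])
    return [(a, b) for a, b in merged]


def segment_intervals(
    intervals: Sequence[tuple[float, float]],
    min_len: float = 5.0,
    max_len: float = 6.0,
) -> list[tuple[float, float]]:
    """Tile concatenated participant speech into non-overlapping segments.

    The intervals are conceptually concatenated end-to-end; fixed ``max_len``
    windows are laid down and the trailing remainder is kept iff it is at
    least ``min_len`` long, otherwise discarded.  Returned spans are in the
    concatenated (participant-speech) timeline.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    total = float(sum(b - a for a, b in intervals))
    segments = []
    t = 0.0
    while total - t >= max_len:
        segments.append((t, t + max_len))
        t += max_len
    if total - t >= min_len:
        segments.append((t, total))
    return segments


def label_recording(score: float, scale: str = "PHQ8") -> int:
    """Binary depression label: 1 iff score >= 10 on either scale."""
    if scale not in SCALE_RANGES:
        raise ValueError(f"unknown scale {scale!r}")
    lo, hi = SCALE_RANGES[scale]
    if not lo <= score <= hi:
        raise ValueError(f"{scale} score {score} outside [{lo}, {hi}]")
    return int(score >= DEPRESSION_THRESHOLD)


def speaker_labels(recordings: Sequence[RecordingRecord]) -> dict:
    """Binary label per speaker, taken from the speaker's first recording.

    For longitudinal speakers whose label varies across visits the first
    visit's label is used (and the discrepancy logged) so folds stay
    well-defined.
    """
    labels: dict = {}
    for rec in recordings:
        lab = rec.label
        if rec.speaker_id not in labels:
            labels[rec.speaker_id] = lab
        elif labels[rec.speaker_id] != lab:
            logger.info(
                "speaker %s changes label across visits; using first visit",
                rec.speaker_id,
            )
    return labels


def make_folds(
    recordings: Sequence[RecordingRecord], k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Speaker-disjoint, label-stratified k-fold assignment.

    Speakers are shuffled within each label stratum under ``seed`` and dealt
    round-robin to folds (a single position counter runs across strata so
    fold sizes stay balanced).  All recordings of a speaker share its fold.
    """
    labels = speaker_labels(recordings)
    speakers = sorted(labels)
    if len(speakers) < k:
        raise ValueError(f"need at least k={k} speakers, got {len(speakers)}")
    rng = np.random.default_rng(seed)
    speaker_to_fold: dict = {}
    pos = 0
    for stratum in (1, 0):  # depressed first, then healthy
        members = [s for s in speakers if labels[s] == stratum]
        rng.shuffle(members)
        for s in members:
            speaker_to_fold[s] = pos % k
            pos += 1
    recording_to_fold = {
        rec.recording_id: speaker_to_fold[rec.speaker_id] for rec in recordings
    }
    return FoldAssignment(k=k, recording_to_fold=recording_to_fold,
                          speaker_to_fold=speaker_to_fold)


# ---------------------------------------------------------------------------
# manifest and feature-array files

MANIFEST_COLUMNS = [
    "recording_id", "speaker_id", "dataset", "scale", "score", "sex", "age", "path",
]


def write_manifest(recordings: Sequence[RecordingRecord], path,
                   feature_paths: dict | None = None) -> None:
    rows = []
    for rec in recordings:
        rows.append({
            "recording_id": rec.recording_id,
            "speaker_id": rec.speaker_id,
            "dataset": rec.dataset_tag,
            "scale": rec.scale,
            "score": rec.severity_score,
            "sex": rec.sex,
            "age": rec.age,
            "path": (feature_paths or {}).get(rec.recording_id, ""),
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> list[RecordingRecord]:
    df = pd.read_csv(path)
    recs = []
    for _, row in df.iterrows():
        recs.append(RecordingRecord(
            recording_id=str(row["recording_id"]),
            speaker_id=str(row["speaker_id"]),
            severity_score=float(row["score"]),
            scale=str(row["scale"]),
            dataset_tag="" if pd.isna(row.get("dataset")) else str(row["dataset"]),
            sex=None if pd.isna(row.get("sex")) else str(row["sex"]),
            age=None if pd.isna(row.get("age")) else float(row["age"]),
        ))
    return recs


def write_feature_matrix(matrix: np.ndarray, path) -> None:
    """One matrix per recording, rows = segments, whitespace-delimited text."""
    np.savetxt(path, np.asarray(matrix, dtype=float))


def read_feature_matrix(path) -> np.ndarray:
    arr = np.loadtxt(path, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def write_segment_table(segments_by_recording: dict, path) -> None:
    rows = []
    for rec_id, segs in segments_by_recording.items():
        for i, (t0, t1) in enumerate(segs):
            rows.append({"recording_id": rec_id, "segment_index": i, "t0": t0, "t1": t1})
    pd.DataFrame(rows, columns=["recording_id", "segment_index", "t0", "t1"]).to_csv(
        path, index=False
    )
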