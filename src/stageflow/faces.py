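"""Facial action-unit stream ingestion and stage-labeled feature tables.

Reads OpenFace-2.0-style CSVs (per-frame AU intensities on a 0-5 scale,
with tracking confidence and a success flag), removes low-confidence
frames, attaches problem-solving stage labels by synchronising timestamps
with a coded protocol, and assembles the labeled feature tables used for
stage classification.

Emotion feature sets follow the EMFACS action-unit combinations: each of
the seven emotions is represented by the joint activation of a fixed AU
subset (e.g. happiness = AU6 + AU12).  The union of the seven
combinations is exactly the 12 AUs carried by every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .protocol import Cohort, CodedProtocol, STAGE_LABELS, StageCode

__all__ = [
    "AU_IDS",
    "EMOTION_AUS",
    "EMOTIONS",
    "RETAINED_STAGES",
    "au_column",
    "AUFrameStream",
    "StageDataset",
    "read_openface_csv",
    "write_openface_csv",
    "filter_by_confidence",
    "label_frames_with_stages",
    "build_stage_datasets",
    "emotion_feature_view",
    "stage_counts_frame",
]

#: The 12 action units used throughout, ascending FACS numbers.
AU_IDS = (1, 4, 5, 6, 7, 9, 10, 12, 15, 17, 20, 23)

#: EMFACS emotion -> AU combination (immutable).
EMOTION_AUS: Mapping[str, tuple[int, ...]] = {
    "Anger": (4, 5, 7, 23),
    "Happiness": (6, 12),
    "Fear": (1, 4, 5),
    "Pride": (6, 7, 12),
    "Sadness": (1, 4, 15),
    "Disgust": (4, 7, 9, 10, 17, 20),
    "Stress": (1, 6, 12, 15),
}

EMOTIONS = tuple(EMOTION_AUS)

#: Stages retained for classification (illumination is too brief to be
#: captured retrospectively; "other" carries no task content).
RETAINED_STAGES = (
    "Preparation",
    "Ideation",
    "Evaluation",
    "Refinement",
    "Production",
    "Block",
)

_DISCARDED_STAGES = ("Illumination", "Other")


def au_column(au: int) -> str:
    """OpenFace intensity column name for an AU, e.g. ``AU01_r``."""
    return f"AU{au:02d}_r"


AU_COLUMNS = tuple(au_column(a) for a in AU_IDS)

_META_COLUMNS = ("frame", "timestamp", "confidence", "success")


@dataclass(frozen=True)
class AUFrameStream:
    """Time-ordered AU intensity frames for one participant.

    ``frames`` holds at least the columns ``frame, timestamp, confidence,
    success`` plus the 12 AU intensity columns; a ``stage`` column is
    present once labels have been attached.  ``n_dropped_unlabeled``
    counts frames discarded because no coded segment covered their
    timestamp.
    """

    frames: pd.DataFrame
    participant_id: str = ""
    n_dropped_unlabeled: int = 0

    def __post_init__(self) -> None:
        ts = self.frames["timestamp"].to_numpy()
        if len(ts) > 1 and not (np.diff(ts) > 0).all():
            raise ValidationError(
                f"timestamps not strictly increasing for {self.participant_id!r}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def labeled(self) -> bool:
        return "stage" in self.frames.columns

    def intensities(self) -> np.ndarray:
        return self.frames[list(AU_COLUMNS)].to_numpy()


def read_openface_csv(path: str | Path, participant_id: str = "") -> AUFrameStream:
    """Read an OpenFace 2.0 CSV, extracting the 12 required AU columns.

    Header tokens may carry surrounding whitespace (OpenFace pads them);
    columns other than frame/timestamp/confidence/success and the 12 AU
    intensity columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    missing_aus = [c for c in AU_COLUMNS if c not in df.columns]
    if missing_aus:
        raise FormatError(
            f"{path}: missing required AU column(s): {', '.join(missing_aus)}"
        )
    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing_meta)}"
        )
    out = df[list(_META_COLUMNS) + list(AU_COLUMNS)].copy()
    out["success"] = out["success"].astype(bool)
    return AUFrameStream(
        frames=out.reset_index(drop=True),
        participant_id=participant_id or path.stem,
    )


def write_openface_csv(stream: AUFrameStream, path: str | Path) -> None:
    """Write a stream in the OpenFace 2.0 dialect (padded headers,
    ``face_id`` column, success as 0/1; stage/emotion columns omitted)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    f = stream.frames
    with path.open("w", encoding="utf-8") as fh:
        header = ["frame", " face_id", " timestamp", " confidence", " success"] + [
            f" {c}" for c in AU_COLUMNS
        ]
        fh.write(",".join(header) + "\n")
        for row in f.itertuples(index=False):
            vals = [
                str(int(row.frame)),
                "0",
                repr(float(row.timestamp)),
                repr(float(row.confidence)),
                str(int(bool(row.success))),
            ] + [repr(float(getattr(row, c))) for c in AU_COLUMNS]
            fh.write(",".join(vals) + "\n")


def filter_by_confidence(
    stream: AUFrameStream, min_confidence: float = 0.95
) -> AUFrameStream:
    """Drop frames with tracking confidence below the threshold or a failed
    fit.  Frames at exactly the threshold are kept (only strictly lower
    confidence is removed); order is preserved."""
    if not 0.0 <= min_confidence <= 1.0:
        raise ValidationError(
            f"min_confidence must be in [0, 1], got {min_confidence}"
        )
    f = stream.frames
    keep = (f["confidence"].to_numpy() >= min_confidence) & f["success"].to_numpy()
    return AUFrameStream(
        frames=f.loc[keep].reset_index(drop=True),
        participant_id=stream.participant_id,
        n_dropped_unlabeled=stream.n_dropped_unlabeled,
    )


def label_frames_with_stages(
    stream: AUFrameStream, protocol: CodedProtocol
) -> AUFrameStream:
    """Attach stage labels by timestamp: a frame gets the stage of the
    segment whose half-open ``[start, end)`` interval contains it; frames
    falling in gaps are dropped and counted."""
    f = stream.frames
    ts = f["timestamp"].to_numpy()
    starts = np.array([s.start_s for s in protocol.segments])
    ends = np.array([s.end_s for s in protocol.segments])
    seg_stage = [s.stage.label for s in protocol.segments]
    idx = np.searchsorted(starts, ts, side="right") - 1
    covered = (idx >= 0) & (ts < ends[idx.clip(min=0)])
    labeled = f.loc[covered].copy()
    labeled["stage"] = [seg_stage[i] for i in idx[covered]]
    return AUFrameStream(
        frames=labeled.reset_index(drop=True),
        participant_id=stream.participant_id,
        n_dropped_unlabeled=int((~covered).sum()) + stream.n_dropped_unlabeled,
    )


@dataclass(frozen=True)
class StageDataset:
    """Labeled AU feature table for one group.

    ``features`` has the 12 AU columns in ascending AU order; ``labels``
    holds one retained-stage label per row.  ``stages`` declares the class
    set the dataset is meant to cover (a stage may legitimately have zero
    rows, which is reported, not silently dropped).
    """

    features: pd.DataFrame
    labels: pd.Series
    group: str = ""
    stages: tuple[str, ...] = RETAINED_STAGES

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValidationError("features and labels differ in length")
        unknown = set(self.labels.unique()) - set(self.stages)
        if unknown:
            raise ValidationError(
                f"labels outside the declared stage set: {sorted(unknown)}"
            )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def counts(self) -> pd.Series:
        """Rows per declared stage (zeros included), in declared order."""
        vc = self.labels.value_counts()
        return pd.Series(
            [int(vc.get(s, 0)) for s in self.stages], index=list(self.stages)
        )


def build_stage_datasets(
    labeled_streams: Iterable[AUFrameStream], group: str
) -> StageDataset:
    """Stack labeled, confidence-filtered streams into one feature table,
    discarding Illumination- and Other-labeled frames."""
    parts = []
    for stream in labeled_streams:
        if not stream.labeled:
            raise ValidationError(
                f"stream {stream.participant_id!r} has no stage labels"
            )
        f = stream.frames
        keep = ~f["stage"].isin(_DISCARDED_STAGES)
        parts.append(f.loc[keep, list(AU_COLUMNS) + ["stage"]])
    if not parts:
        raise ValidationError("no labeled streams provided")
    stacked = pd.concat(parts, ignore_index=True)
    return StageDataset(
        features=stacked[list(AU_COLUMNS)],
        labels=stacked["stage"].rename("stage"),
        group=group,
    )


def emotion_feature_view(dataset: StageDataset, emotion: str) -> pd.DataFrame:
    """Restrict a dataset's features to one emotion's AU combination.

    Columns are exactly the combination's AUs in table order; the row
    count is unchanged.
    """
    if emotion not in EMOTION_AUS:
        raise ValidationError(
            f"unknown emotion {emotion!r}; expected one of {', '.join(EMOTIONS)}"
        )
    cols = [au_column(a) for a in EMOTION_AUS[emotion]]
    return dataset.features[cols]


def stage_counts_frame(datasets: Mapping[str, StageDataset]) -> pd.DataFrame:
    """Per-stage row counts for each group, rows in retained-stage order."""
    out = pd.DataFrame(index=list(RETAINED_STAGES))
    for group, ds in datasets.items():
        out[f"{group}_rows"] = ds.counts.reindex(out.index)
    out.index.name = "stage"
    return out
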