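"""Data model and I/O for stage-coded problem-solving protocols.

A *protocol* is one participant's session, segmented into timestamped units
(verbal utterances or observed task actions), each coded into one of eight
problem-solving stages.  Cohorts group the protocols of one experimental
condition (creative problem solving, CPS, vs. simple problem solving, SPS).

The canonical stage order defined by :class:`StageCode` is used for all
matrix indexing throughout the package.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import FormatError, ValidationError

__all__ = [
    "StageCode",
    "Segment",
    "CodedProtocol",
    "Cohort",
    "read_coded_segments",
    "write_coded_segments",
    "stage_sequence",
    "SEGMENT_SOURCES",
]

SEGMENT_SOURCES = ("verbal_utterance", "task_action")


class StageCode(enum.IntEnum):
    """The eight problem-solving stages, in canonical matrix order."""

    PREPARATION = 0
    IDEATION = 1
    ILLUMINATION = 2
    EVALUATION = 3
    REFINEMENT = 4
    PRODUCTION = 5
    BLOCK = 6
    OTHER = 7

    @property
    def label(self) -> str:
        """Canonical capitalised name, e.g. ``"Preparation"``."""
        return self.name.capitalize()

    @classmethod
    def parse(cls, text: str) -> "StageCode":
        """Parse a stage name case-insensitively; reject anything else."""
        try:
            return cls[str(text).strip().upper()]
        except KeyError:
            raise ValidationError(
                f"unknown stage code {text!r}; expected one of "
                f"{', '.join(s.label for s in cls)}"
            ) from None


#: Canonical stage order as labels (index == StageCode value).
STAGE_LABELS = tuple(s.label for s in StageCode)


@dataclass(frozen=True)
class Segment:
    """One coded unit of a protocol over the half-open interval [start_s, end_s)."""

    participant_id: str
    start_s: float
    end_s: float
    stage: StageCode
    source: str = "verbal_utterance"

    def __post_init__(self) -> None:
        if not self.start_s >= 0:
            raise ValidationError(
                f"segment start must be non-negative, got {self.start_s}"
            )
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"segment must satisfy start_s < end_s, got "
                f"[{self.start_s}, {self.end_s}) for {self.participant_id!r}"
            )
        if self.source not in SEGMENT_SOURCES:
            raise ValidationError(
                f"segment source must be one of {SEGMENT_SOURCES}, got {self.source!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class CodedProtocol:
    """One participant's ordered, non-overlapping stage-coded segments."""

    participant_id: str
    group: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        object.__setattr__(self, "segments", segments)
        if len(segments) < 1:
            raise ValidationError(
                f"protocol {self.participant_id!r} has no segments"
            )
        for prev, cur in zip(segments, segments[1:]):
            if cur.start_s < prev.start_s:
                raise ValidationError(
                    f"segments of {self.participant_id!r} are not sorted by start_s"
                )
            if cur.start_s < prev.end_s:
                raise ValidationError(
                    f"segments of {self.participant_id!r} overlap at t={cur.start_s}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def span_s(self) -> tuple[float, float]:
        """(first start, last end) of the coded time span."""
        return self.segments[0].start_s, self.segments[-1].end_s


@dataclass(frozen=True)
class Cohort:
    """All protocols of one experimental group (e.g. CPS or SPS)."""

    group: str
    protocols: tuple[CodedProtocol, ...]

    def __post_init__(self) -> None:
        protocols = tuple(self.protocols)
        object.__setattr__(self, "protocols", protocols)
        if not protocols:
            raise ValidationError(f"cohort {self.group!r} is empty")
        bad = [p.participant_id for p in protocols if p.group != self.group]
        if bad:
            raise ValidationError(
                f"cohort {self.group!r} contains protocols from another group: {bad}"
            )

    def __len__(self) -> int:
        return len(self.protocols)

    def __iter__(self) -> Iterator[CodedProtocol]:
        return iter(self.protocols)


_CSV_COLUMNS = ("participant_id", "group", "start_s", "end_s", "stage", "source")


def stage_sequence(protocol: CodedProtocol) -> list[StageCode]:
    """The temporal stage sequence of a protocol, one code per segment."""
    return [seg.stage for seg in protocol.segments]


def _format_seconds(x: float) -> str:
    # repr() of a float is the shortest string that round-trips exactly,
    # which gives bit-for-bit stable read/write cycles.
    return repr(float(x))


def read_coded_segments(path: str | Path) -> Cohort:
    """Read a coded-segment CSV into a validated :class:`Cohort`.

    The file must have a header with columns ``participant_id, group,
    start_s, end_s, stage, source``.  Rows are grouped by participant and
    sorted by ``start_s``; all rows must belong to a single group.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _CSV_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        rows: dict[str, list[Segment]] = {}
        groups: set[str] = set()
        order: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                seg = Segment(
                    participant_id=row["participant_id"],
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                    stage=StageCode.parse(row["stage"]),
                    source=row["source"],
                )
            except (ValidationError, ValueError, TypeError) as exc:
                raise ValidationError(f"{path}: row {lineno}: {exc}") from None
            groups.add(row["group"])
            if seg.participant_id not in rows:
                order.append(seg.participant_id)
            rows.setdefault(seg.participant_id, []).append(seg)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    if len(groups) != 1:
        raise ValidationError(
            f"{path}: expected a single group per file, found {sorted(groups)}"
        )
    group = groups.pop()
    protocols = []
    for pid in order:
        segs = sorted(rows[pid], key=lambda s: s.start_s)
        try:
            protocols.append(
                CodedProtocol(participant_id=pid, group=group, segments=tuple(segs))
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from None
    return Cohort(group=group, protocols=tuple(protocols))


def write_coded_segments(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the canonical comma-separated UTF-8 dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for protocol in cohort:
            for seg in protocol.segments:
                writer.writerow(
                    [
                        seg.participant_id,
                        cohort.group,
                        _format_seconds(seg.start_s),
                        _format_seconds(seg.end_s),
                        seg.stage.label,
                        seg.source,
                    ]
                )
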