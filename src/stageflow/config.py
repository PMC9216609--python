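"""Run configuration: one object carrying every tunable of a pipeline run.

A resolved copy (all defaults filled in, master seed included) is written
next to the outputs of every command so that runs are reproducible
byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of a full synthetic-cohort pipeline run."""

    seed: int = 42

    # cohort synthesis (Markov arm)
    n_cps: int = 33
    n_sps: int = 31
    events_per_participant: int = 200
    mean_segment_duration_s: float = 5.0

    # facial arm synthesis: shorter sessions keep the end-to-end run light
    faces_participants_per_group: int = 6
    faces_events_per_participant: int = 120
    fps: float = 25.0
    activation_delta: float = 2.0
    baseline: float = 0.5
    noise_sd: float = 0.35
    episode_persistence: float = 25.0
    low_confidence_rate: float = 0.02

    # thresholds
    min_confidence: float = 0.95
    diagram_min_probability: float = 0.05

    # classifier
    kernel_degree: int = 4
    regularization_weight: float = 1.0
    multiclass_scheme: str = "ovo"
    standardize: bool = False
    max_rows_per_class: int = 1200

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValidationError(
                f"min_confidence must be in [0, 1], got {self.min_confidence}"
            )
        if not 0.0 <= self.diagram_min_probability <= 1.0:
            raise ValidationError(
                "diagram_min_probability must be in [0, 1], "
                f"got {self.diagram_min_probability}"
            )
        for name in ("n_cps", "n_sps", "events_per_participant",
                     "faces_participants_per_group", "faces_events_per_participant"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
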