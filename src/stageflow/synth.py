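"""Synthetic cohorts: stage-coded protocols from known Markov chains and
facial action-unit streams with stage-dependent emotion activation.

The generators define the study conditions the rest of the package is
verified against: two groups of participants (33 creative problem solvers,
31 simple problem solvers) whose stage sequences follow first-order chains,
filmed at 25 frames per second for sessions whose AU intensities (0-5
scale) rise on an emotion's EMFACS combination while that emotion is
active.

Ground-truth chain parameters are exposed so that estimators downstream
can be checked for parameter recovery.  The built-in chains encode the
group-level transition structure reported for creative vs. simple problem
solving: e.g. the creative group's strong production -> ideation loop (57%
of production exits) and the simple group's preparation-centred structure
(40% preparation self-transitions, 82% of production exits returning to
preparation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .faces import AU_IDS, AUFrameStream, EMOTION_AUS, au_column
from .markov import N_STAGES, StationaryDistribution, TransitionModel, stationary_distribution
from .protocol import Cohort, CodedProtocol, STAGE_LABELS, Segment, StageCode

__all__ = [
    "ChainSpec",
    "EmotionProfile",
    "cps_like_chain",
    "sps_like_chain",
    "iid_chain",
    "CPS_STATIONARY_MEAN",
    "SPS_STATIONARY_MEAN",
    "default_emotion_profile",
    "simulate_protocol",
    "simulate_cohort",
    "simulate_stage_index_sequences",
    "simulate_au_stream",
]

_ATOL = 1e-12

#: Group-mean stage-occupancy profiles (canonical stage order) that the
#: default cohorts emulate: creative solvers concentrate effort in ideation
#: and production, simple solvers in preparation and production.
CPS_STATIONARY_MEAN = np.array([0.21, 0.37, 0.00, 0.09, 0.07, 0.23, 0.02, 0.01])
SPS_STATIONARY_MEAN = np.array([0.53, 0.01, 0.00, 0.08, 0.04, 0.32, 0.01, 0.01])


def _rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ChainSpec:
    """Generating parameters of an 8-state stage chain.

    ``P_true`` is the row-stochastic transition matrix over the canonical
    stage order; ``mean_segment_duration_s`` may be a scalar or a length-8
    per-stage array of exponential-duration means.
    """

    P_true: np.ndarray
    initial_distribution: np.ndarray
    mean_segment_duration_s: float | np.ndarray = 5.0

    def __post_init__(self) -> None:
        P = np.asarray(self.P_true, dtype=float)
        init = np.asarray(self.initial_distribution, dtype=float)
        object.__setattr__(self, "P_true", P)
        object.__setattr__(self, "initial_distribution", init)
        if P.shape != (N_STAGES, N_STAGES):
            raise ValidationError(f"P_true must be 8x8, got {P.shape}")
        if (P < 0).any():
            raise ValidationError("P_true entries must be non-negative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=_ATOL):
            raise ValidationError("every row of P_true must sum to 1")
        if init.shape != (N_STAGES,) or (init < 0).any():
            raise ValidationError("initial_distribution must be a length-8 probability vector")
        if not np.isclose(init.sum(), 1.0, atol=_ATOL):
            raise ValidationError("initial_distribution must sum to 1")
        means = np.broadcast_to(
            np.asarray(self.mean_segment_duration_s, dtype=float), (N_STAGES,)
        )
        if (means <= 0).any():
            raise ValidationError("mean segment durations must be positive")

    @property
    def duration_means(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.mean_segment_duration_s, dtype=float), (N_STAGES,)
        ).copy()

    def stationary(self) -> StationaryDistribution:
        """True stationary vector of ``P_true`` (same solver as the estimator)."""
        model = TransitionModel(
            counts=np.zeros((N_STAGES, N_STAGES), dtype=np.int64),
            visit_counts=np.ones(N_STAGES, dtype=np.int64),
            P=self.P_true,
        )
        return stationary_distribution(model)


def iid_chain(
    occupancy: np.ndarray, mean_segment_duration_s: float | np.ndarray = 5.0
) -> ChainSpec:
    """A chain whose every row equals ``occupancy``: events are i.i.d. draws.

    Its stationary vector is ``occupancy`` itself, which makes it the
    natural generator for cohorts with a prescribed mean stage-occupancy
    profile.
    """
    q = np.asarray(occupancy, dtype=float)
    return ChainSpec(
        P_true=np.tile(q, (N_STAGES, 1)),
        initial_distribution=q,
        mean_segment_duration_s=mean_segment_duration_s,
    )


def _chain(rows: Mapping[StageCode, Mapping[StageCode, float]]) -> np.ndarray:
    P = np.zeros((N_STAGES, N_STAGES))
    for src, targets in rows.items():
        for dst, p in targets.items():
            P[src, dst] = p
    return P


_S = StageCode


def cps_like_chain(mean_segment_duration_s: float | np.ndarray = 5.0) -> ChainSpec:
    """Default creative-group chain.

    Anchored rows: production exits to ideation 57% and preparation 12%;
    preparation self-transitions 57% with 19% to production; illumination
    exits to ideation 65% and preparation 5%; refinement to preparation
    22%; other to preparation 33%.  Remaining mass is fixed, plausible
    structure (ideation-centred loops).
    """
    P = _chain(
        {
            _S.PREPARATION: {
                _S.PREPARATION: 0.57, _S.IDEATION: 0.13, _S.ILLUMINATION: 0.01,
                _S.EVALUATION: 0.04, _S.REFINEMENT: 0.02, _S.PRODUCTION: 0.19,
                _S.BLOCK: 0.02, _S.OTHER: 0.02,
            },
            _S.IDEATION: {
                _S.PREPARATION: 0.10, _S.IDEATION: 0.30, _S.ILLUMINATION: 0.02,
                _S.EVALUATION: 0.10, _S.REFINEMENT: 0.05, _S.PRODUCTION: 0.38,
                _S.BLOCK: 0.03, _S.OTHER: 0.02,
            },
            _S.ILLUMINATION: {
                _S.PREPARATION: 0.05, _S.IDEATION: 0.65, _S.EVALUATION: 0.05,
                _S.REFINEMENT: 0.03, _S.PRODUCTION: 0.20, _S.BLOCK: 0.01,
                _S.OTHER: 0.01,
            },
            _S.EVALUATION: {
                _S.PREPARATION: 0.10, _S.IDEATION: 0.20, _S.EVALUATION: 0.15,
                _S.REFINEMENT: 0.25, _S.PRODUCTION: 0.25, _S.BLOCK: 0.02,
                _S.OTHER: 0.03,
            },
            _S.REFINEMENT: {
                _S.PREPARATION: 0.22, _S.IDEATION: 0.12, _S.EVALUATION: 0.13,
                _S.REFINEMENT: 0.20, _S.PRODUCTION: 0.30, _S.BLOCK: 0.01,
                _S.OTHER: 0.02,
            },
            _S.PRODUCTION: {
                _S.PREPARATION: 0.12, _S.IDEATION: 0.57, _S.EVALUATION: 0.05,
                _S.REFINEMENT: 0.03, _S.PRODUCTION: 0.20, _S.BLOCK: 0.02,
                _S.OTHER: 0.01,
            },
            _S.BLOCK: {
                _S.PREPARATION: 0.20, _S.IDEATION: 0.30, _S.EVALUATION: 0.05,
                _S.PRODUCTION: 0.10, _S.BLOCK: 0.20, _S.OTHER: 0.15,
            },
            _S.OTHER: {
                _S.PREPARATION: 0.33, _S.IDEATION: 0.20, _S.EVALUATION: 0.05,
                _S.REFINEMENT: 0.05, _S.PRODUCTION: 0.25, _S.BLOCK: 0.02,
                _S.OTHER: 0.10,
            },
        }
    )
    init = np.zeros(N_STAGES)
    init[_S.PREPARATION] = 1.0  # sessions open with reading the task
    return ChainSpec(P_true=P, initial_distribution=init,
                     mean_segment_duration_s=mean_segment_duration_s)


def sps_like_chain(mean_segment_duration_s: float | np.ndarray = 5.0) -> ChainSpec:
    """Default simple-group chain.

    Anchored rows: preparation self-transitions 40% with 50% to
    production; production exits to preparation 82% and ideation 1%;
    refinement to preparation 50%; other to preparation 49%; illumination
    (if ever entered) returns to preparation with certainty.
    """
    P = _chain(
        {
            _S.PREPARATION: {
                _S.PREPARATION: 0.40, _S.IDEATION: 0.01, _S.EVALUATION: 0.04,
                _S.REFINEMENT: 0.02, _S.PRODUCTION: 0.50, _S.BLOCK: 0.01,
                _S.OTHER: 0.02,
            },
            _S.IDEATION: {
                _S.PREPARATION: 0.30, _S.IDEATION: 0.10, _S.EVALUATION: 0.05,
                _S.PRODUCTION: 0.50, _S.OTHER: 0.05,
            },
            _S.ILLUMINATION: {_S.PREPARATION: 1.00},
            _S.EVALUATION: {
                _S.PREPARATION: 0.30, _S.EVALUATION: 0.15, _S.REFINEMENT: 0.10,
                _S.PRODUCTION: 0.40, _S.BLOCK: 0.02, _S.OTHER: 0.03,
            },
            _S.REFINEMENT: {
                _S.PREPARATION: 0.50, _S.EVALUATION: 0.07, _S.REFINEMENT: 0.10,
                _S.PRODUCTION: 0.30, _S.BLOCK: 0.01, _S.OTHER: 0.02,
            },
            _S.PRODUCTION: {
                _S.PREPARATION: 0.82, _S.IDEATION: 0.01, _S.EVALUATION: 0.04,
                _S.REFINEMENT: 0.02, _S.PRODUCTION: 0.10, _S.OTHER: 0.01,
            },
            _S.BLOCK: {
                _S.PREPARATION: 0.40, _S.EVALUATION: 0.05, _S.PRODUCTION: 0.30,
                _S.BLOCK: 0.15, _S.OTHER: 0.10,
            },
            _S.OTHER: {
                _S.PREPARATION: 0.49, _S.EVALUATION: 0.06, _S.REFINEMENT: 0.03,
                _S.PRODUCTION: 0.30, _S.BLOCK: 0.02, _S.OTHER: 0.10,
            },
        }
    )
    init = np.zeros(N_STAGES)
    init[_S.PREPARATION] = 1.0
    return ChainSpec(P_true=P, initial_distribution=init,
                     mean_segment_duration_s=mean_segment_duration_s)


def simulate_stage_index_sequences(
    spec: ChainSpec,
    n_sequences: int,
    n_events: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n_sequences`` independent stage-index sequences in parallel.

    Returns an ``(n_sequences, n_events)`` int array.  This is the batch
    path used by the per-protocol simulator and by large-replicate
    simulation studies.
    """
    if n_sequences < 1 or n_events < 1:
        raise ValidationError("n_sequences and n_events must be >= 1")
    rng = _rng(seed)
    cum_init = np.cumsum(spec.initial_distribution)
    cum_rows = np.cumsum(spec.P_true, axis=1)
    out = np.empty((n_sequences, n_events), dtype=np.int64)
    out[:, 0] = np.searchsorted(cum_init, rng.random(n_sequences), side="right").clip(
        max=N_STAGES - 1
    )
    for t in range(1, n_events):
        u = rng.random(n_sequences)
        out[:, t] = (u[:, None] < cum_rows[out[:, t - 1]]).argmax(axis=1)
    return out


def simulate_protocol(
    spec: ChainSpec,
    n_events: int,
    seed: int | np.random.Generator,
    participant_id: str = "P01",
    group: str = "CPS",
) -> CodedProtocol:
    """Simulate one participant's coded protocol.

    The first stage is drawn from the initial distribution, each
    subsequent stage from the current stage's row of ``P_true``; segment
    durations are exponential with the configured per-stage mean, and
    timestamps are contiguous from 0.
    """
    rng = _rng(seed)
    states = simulate_stage_index_sequences(spec, 1, n_events, rng)[0]
    durations = rng.exponential(spec.duration_means[states])
    ends = np.cumsum(durations)
    starts = np.concatenate(([0.0], ends[:-1]))  # contiguous, exact
    segments = tuple(
        Segment(
            participant_id=participant_id,
            start_s=float(s),
            end_s=float(e),
            stage=StageCode(int(k)),
            source="task_action" if StageCode(int(k)) in (
                StageCode.PRODUCTION, StageCode.PREPARATION) else "verbal_utterance",
        )
        for s, e, k in zip(starts, ends, states)
    )
    return CodedProtocol(participant_id=participant_id, group=group, segments=segments)


def simulate_cohort(
    spec: ChainSpec,
    n_participants: int,
    events_per_participant: int,
    seed: int,
    group: str = "CPS",
) -> Cohort:
    """Simulate an independent cohort; per-participant seeds are spawned
    deterministically from the master seed."""
    if n_participants < 1:
        raise ValidationError("n_participants must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_participants)
    protocols = tuple(
        simulate_protocol(
            spec,
            events_per_participant,
            np.random.default_rng(child),
            participant_id=f"{group}{i + 1:02d}",
            group=group,
        )
        for i, child in enumerate(children)
    )
    return Cohort(group=group, protocols=protocols)


# ---------------------------------------------------------------------------
# Facial AU stream generation


@dataclass(frozen=True)
class EmotionProfile:
    """Stage-dependent emotion mixture driving synthetic AU streams.

    ``weights[stage_label][emotion]`` gives the probability that an emotion
    episode within that stage expresses that emotion; any mass not
    assigned to one of the seven emotions is implied "neutral" (no
    combination active).  While an emotion is active, every AU in its
    EMFACS combination is raised by ``activation_delta`` above
    ``baseline``; Gaussian noise with ``noise_sd`` is added and the result
    clipped to the 0-5 intensity scale.  Episode lengths are geometric
    with mean ``episode_persistence`` frames.  A fraction
    ``low_confidence_rate`` of frames carries tracking confidence below
    0.95.
    """

    weights: Mapping[str, Mapping[str, float]]
    activation_delta: float = 2.0
    baseline: float = 0.5
    noise_sd: float = 0.35
    episode_persistence: float = 25.0
    low_confidence_rate: float = 0.02

    def __post_init__(self) -> None:
        for stage_label, mix in self.weights.items():
            if stage_label not in STAGE_LABELS:
                raise ValidationError(f"unknown stage label {stage_label!r}")
            total = 0.0
            for emotion, w in mix.items():
                if emotion != "neutral" and emotion not in EMOTION_AUS:
                    raise ValidationError(f"unknown emotion {emotion!r}")
                if w < 0:
                    raise ValidationError(f"negative weight for {emotion!r}")
                total += w
            if total > 1.0 + 1e-9:
                raise ValidationError(
                    f"weights for stage {stage_label!r} sum to {total} > 1"
                )
        if not 0.0 <= self.baseline <= 5.0:
            raise ValidationError("baseline must lie in [0, 5]")
        if not 0.0 <= self.baseline + self.activation_delta <= 5.0:
            raise ValidationError("baseline + activation_delta must lie in [0, 5]")
        if self.episode_persistence < 1.0:
            raise ValidationError("episode_persistence must be >= 1 frame")
        if not 0.0 <= self.low_confidence_rate < 1.0:
            raise ValidationError("low_confidence_rate must lie in [0, 1)")

    def stage_mixture(self, stage: StageCode) -> tuple[list[str], np.ndarray]:
        """(emotion names incl. 'neutral', probabilities) for one stage."""
        mix = dict(self.weights.get(stage.label, {}))
        assigned = sum(w for e, w in mix.items() if e != "neutral")
        mix["neutral"] = mix.get("neutral", 0.0) + max(0.0, 1.0 - assigned - mix.get("neutral", 0.0))
        names = list(mix.keys())
        probs = np.array([mix[n] for n in names], dtype=float)
        return names, probs / probs.sum()


def default_emotion_profile(**overrides) -> EmotionProfile:
    """Default stage-emotion mixtures.

    Block episodes are dominated by the negative emotions (anger, fear,
    sadness, disgust); the productive stages carry ambivalent mixtures of
    happiness, pride, fear and stress, matching the qualitative picture of
    creative-stage affect.
    """
    weights = {
        "Preparation": {"Happiness": 0.22, "Fear": 0.22, "neutral": 0.56},
        "Ideation": {"Happiness": 0.28, "Fear": 0.17, "neutral": 0.55},
        "Illumination": {"Happiness": 0.40, "neutral": 0.60},
        "Evaluation": {"Happiness": 0.20, "Pride": 0.12, "Fear": 0.12,
                       "Stress": 0.14, "neutral": 0.42},
        "Refinement": {"Happiness": 0.28, "Pride": 0.22, "Stress": 0.18,
                       "neutral": 0.32},
        "Production": {"Happiness": 0.24, "Pride": 0.18, "Fear": 0.10,
                       "Stress": 0.14, "neutral": 0.34},
        "Block": {"Anger": 0.22, "Fear": 0.22, "Sadness": 0.22,
                  "Disgust": 0.22, "neutral": 0.12},
        "Other": {"neutral": 1.0},
    }
    return EmotionProfile(weights=weights, **overrides)


def simulate_au_stream(
    protocol: CodedProtocol,
    profile: EmotionProfile,
    fps: float = 25.0,
    seed: int | np.random.Generator = 0,
) -> AUFrameStream:
    """Render a protocol as an OpenFace-style AU intensity stream.

    One frame is emitted per ``1/fps`` seconds across the protocol's
    span.  Each frame carries the stage of the segment whose half-open
    interval contains its timestamp, the latent emotion active at that
    frame, AU intensities per the profile, and a tracking confidence
    (>= 0.95 except for the configured low-confidence fraction).
    """
    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    rng = _rng(seed)
    t0, t1 = protocol.span_s
    n_frames = int(np.floor((t1 - t0) * fps + 1e-9))
    if n_frames < 1:
        raise ValidationError("protocol span too short for a single frame")
    timestamps = t0 + np.arange(n_frames) / fps

    starts = np.array([s.start_s for s in protocol.segments])
    ends = np.array([s.end_s for s in protocol.segments])
    seg_stage = np.array([int(s.stage) for s in protocol.segments])
    seg_idx = np.searchsorted(starts, timestamps, side="right") - 1
    in_seg = timestamps < ends[seg_idx]  # gaps between segments are unlabeled
    stages = np.where(in_seg, seg_stage[seg_idx], -1)

    # latent emotion per frame: geometric-length episodes within stage runs
    emotions = np.empty(n_frames, dtype=object)
    run_breaks = np.flatnonzero(np.diff(stages) != 0) + 1
    run_starts = np.concatenate(([0], run_breaks))
    run_ends = np.concatenate((run_breaks, [n_frames]))
    p_end = 1.0 / profile.episode_persistence
    for rs, re in zip(run_starts, run_ends):
        if stages[rs] < 0:
            emotions[rs:re] = "neutral"
            continue
        names, probs = profile.stage_mixture(StageCode(int(stages[rs])))
        pos = rs
        while pos < re:
            emotion = names[rng.choice(len(names), p=probs)]
            length = int(rng.geometric(p_end))
            emotions[pos : min(pos + length, re)] = emotion
            pos += length

    intensities = np.full((n_frames, len(AU_IDS)), float(profile.baseline))
    au_pos = {au: k for k, au in enumerate(AU_IDS)}
    for emotion, combo in EMOTION_AUS.items():
        mask = emotions == emotion
        if mask.any():
            cols = [au_pos[au] for au in combo]
            intensities[np.ix_(mask, cols)] += profile.activation_delta
    if profile.noise_sd > 0:
        intensities += rng.normal(0.0, profile.noise_sd, size=intensities.shape)
    np.clip(intensities, 0.0, 5.0, out=intensities)

    confidence = rng.uniform(0.95, 1.0, size=n_frames)
    low = rng.random(n_frames) < profile.low_confidence_rate
    confidence[low] = rng.uniform(0.50, 0.9499, size=int(low.sum()))

    import pandas as pd

    frames = pd.DataFrame({"frame": np.arange(1, n_frames + 1),
                           "timestamp": timestamps,
                           "confidence": confidence,
                           "success": np.ones(n_frames, dtype=bool)})
    for k, au in enumerate(AU_IDS):
        frames[au_column(au)] = intensities[:, k]
    stage_labels = np.where(
        stages >= 0, [STAGE_LABELS[s] if s >= 0 else "" for s in stages], ""
    )
    frames["stage"] = stage_labels
    frames["emotion"] = emotions
    return AUFrameStream(frames=frames, participant_id=protocol.participant_id)
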