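"""First-order Markov-chain analysis of stage-coded protocol sequences.

Each participant's stage sequence is summarised by an 8x8 transition-count
matrix N over the canonical stage order, converted to a row-stochastic
transition matrix P, and reduced to the stationary (equilibrium) row vector
pi solving ``pi @ P = pi`` with ``pi.sum() == 1``.  The stationary vector is
used as a per-participant measure of the relative cognitive effort spent in
each stage.  Cohort-level summaries pool counts across participants and
normalise each row, giving the group transition diagram.

Numerical policy
----------------
* Rows of P with no observed exits (the final stage of a sequence, or an
  unvisited stage) are set to the uniform distribution over *visited*
  stages; making them absorbing would concentrate pi spuriously.
* pi is the left eigenvector for eigenvalue 1 of P restricted to the
  visited stages, provided that eigenvalue is simple (tolerance 1e-8);
  otherwise the estimator falls back to empirical visit frequencies and
  flags the result.  Unvisited stages always receive pi mass exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ValidationError
from .protocol import Cohort, CodedProtocol, STAGE_LABELS, StageCode, stage_sequence

__all__ = [
    "TransitionModel",
    "StationaryDistribution",
    "PooledTransitionMatrix",
    "StationaryTable",
    "transition_counts",
    "transition_probabilities",
    "stationary_distribution",
    "participant_model",
    "cohort_stationary_table",
    "pooled_transition_matrix",
    "export_transition_diagram",
]

N_STAGES = len(StageCode)

#: Node abbreviations used in transition diagrams.
STAGE_ABBREV = {
    StageCode.PREPARATION: "Prep",
    StageCode.IDEATION: "Ide",
    StageCode.ILLUMINATION: "Illum",
    StageCode.EVALUATION: "Eva",
    StageCode.REFINEMENT: "Ref",
    StageCode.PRODUCTION: "Prod",
    StageCode.BLOCK: "Blo",
    StageCode.OTHER: "Oth",
}

_EIGEN_TOL = 1e-8


def _as_indices(sequence: Sequence[StageCode] | np.ndarray) -> np.ndarray:
    idx = np.asarray(sequence, dtype=np.int64)
    if idx.ndim != 1:
        raise ValidationError("stage sequence must be one-dimensional")
    if idx.size == 0:
        raise ValidationError("stage sequence is empty")
    if idx.min() < 0 or idx.max() >= N_STAGES:
        raise ValidationError("stage indices must lie in [0, 8)")
    return idx


@dataclass(frozen=True)
class TransitionModel:
    """Transition counts (and optionally probabilities) for one sequence.

    Attributes
    ----------
    counts : (8, 8) int array, ``counts[i, j]`` = observed i -> j transitions.
    visit_counts : length-8 int array of stage occurrence counts.
    P : (8, 8) row-stochastic matrix, present after
        :func:`transition_probabilities`.
    """

    counts: np.ndarray
    visit_counts: np.ndarray
    P: np.ndarray | None = None

    @property
    def visited(self) -> np.ndarray:
        """Boolean mask of stages appearing in the sequence."""
        return self.visit_counts > 0

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class StationaryDistribution:
    """The stationary row vector pi of a participant's chain.

    ``method`` is ``"eigen"`` when pi is the (unique) left eigenvector for
    eigenvalue 1, or ``"visit_frequency_fallback"`` when the eigenspace was
    degenerate and empirical visit frequencies were used instead.
    ``residual`` is ``max |pi @ P - pi|``.
    """

    pi: np.ndarray
    method: str
    residual: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.pi, index=list(STAGE_LABELS))


def transition_counts(sequence: Sequence[StageCode] | np.ndarray) -> TransitionModel:
    """Count adjacent-pair transitions of a stage sequence.

    Accepts a list of :class:`StageCode` or an integer index array.  The
    total count equals ``len(sequence) - 1``.
    """
    idx = _as_indices(sequence)
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    if idx.size > 1:
        np.add.at(counts, (idx[:-1], idx[1:]), 1)
    visit_counts = np.bincount(idx, minlength=N_STAGES)
    return TransitionModel(counts=counts, visit_counts=visit_counts)


def transition_probabilities(model: TransitionModel) -> TransitionModel:
    """Row-normalise counts into a stochastic matrix P.

    Rows with no observed exits — including all rows of unvisited stages —
    are set to the uniform distribution over visited stages, which keeps P
    stochastic without inventing structure.
    """
    counts = model.counts.astype(float)
    row_sums = counts.sum(axis=1)
    visited = model.visited
    if not visited.any():
        raise ValidationError("transition model has no visited stages")
    uniform_visited = visited.astype(float) / visited.sum()
    P = np.empty_like(counts)
    for i in range(N_STAGES):
        P[i] = counts[i] / row_sums[i] if row_sums[i] > 0 else uniform_visited
    return TransitionModel(counts=model.counts, visit_counts=model.visit_counts, P=P)


def stationary_distribution(model: TransitionModel) -> StationaryDistribution:
    """Solve ``pi @ P = pi`` with unit sum for a participant's chain.

    The system is solved on the visited-stage submatrix; unvisited stages
    get pi mass exactly 0 at their canonical index.  If the eigenvalue-1
    eigenspace is not one-dimensional (within 1e-8) the empirical visit
    frequencies are returned with ``method="visit_frequency_fallback"``.
    """
    if model.P is None:
        model = transition_probabilities(model)
    P = np.asarray(model.P, dtype=float)
    if not np.isfinite(P).all():
        raise ValidationError("transition matrix contains non-finite entries")
    visited = model.visited
    vis_idx = np.flatnonzero(visited)
    sub = P[np.ix_(vis_idx, vis_idx)]

    pi = np.zeros(N_STAGES)
    eigvals, eigvecs = scipy.linalg.eig(sub.T)
    at_one = np.flatnonzero(np.abs(eigvals - 1.0) <= _EIGEN_TOL)
    if len(at_one) == 1:
        vec = np.real(eigvecs[:, at_one[0]])
        vec = np.clip(vec if vec.sum() >= 0 else -vec, 0.0, None)
        pi[vis_idx] = vec / vec.sum()
        method = "eigen"
    else:
        freq = model.visit_counts.astype(float)
        pi = freq / freq.sum()
        method = "visit_frequency_fallback"
    residual = float(np.max(np.abs(pi @ P - pi)))
    return StationaryDistribution(pi=pi, method=method, residual=residual)


def participant_model(protocol: CodedProtocol) -> TransitionModel:
    """Full transition model (counts and P) for one protocol."""
    return transition_probabilities(transition_counts(stage_sequence(protocol)))


@dataclass(frozen=True)
class StationaryTable:
    """Per-participant stationary vectors for one group, plus summaries."""

    group: str
    pi: pd.DataFrame  # participants x 8, columns = stage labels
    methods: pd.Series  # per-participant solver method flag

    @property
    def mean(self) -> pd.Series:
        return self.pi.mean(axis=0)

    @property
    def sd(self) -> pd.Series:
        """Across-participant SD (ddof=1); 0 when only one participant."""
        if len(self.pi) < 2:
            return pd.Series(0.0, index=self.pi.columns)
        return self.pi.std(axis=0, ddof=1)

    @property
    def sd_defined(self) -> bool:
        return len(self.pi) >= 2

    def to_csv(self, path: str | Path) -> None:
        self.pi.to_csv(path, index_label="participant_id")


def cohort_stationary_table(cohort: Cohort) -> StationaryTable:
    """Estimate each participant's stationary vector; summarise per stage."""
    rows, methods, ids = [], [], []
    for protocol in cohort:
        sd = stationary_distribution(participant_model(protocol))
        rows.append(sd.pi)
        methods.append(sd.method)
        ids.append(protocol.participant_id)
    pi = pd.DataFrame(np.vstack(rows), index=ids, columns=list(STAGE_LABELS))
    return StationaryTable(
        group=cohort.group, pi=pi, methods=pd.Series(methods, index=ids)
    )


@dataclass(frozen=True)
class PooledTransitionMatrix:
    """Cohort-pooled transition counts and row-conditional relative frequencies.

    ``relfreq[i, j]`` is the fraction of all observed exits from stage i
    that go to stage j; rows with no pooled exits are NaN and listed in
    ``empty_rows`` rather than being fabricated.
    """

    group: str
    counts: np.ndarray
    relfreq: np.ndarray

    @property
    def empty_rows(self) -> list[str]:
        return [
            STAGE_LABELS[i]
            for i in range(N_STAGES)
            if not np.isfinite(self.relfreq[i]).any()
        ]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.relfreq, index=list(STAGE_LABELS), columns=list(STAGE_LABELS)
        )

    def to_csv(self, path: str | Path) -> None:
        self.as_frame().to_csv(path, index_label="from_stage")


def pooled_transition_matrix(cohort: Cohort) -> PooledTransitionMatrix:
    """Sum transition counts across participants, then row-normalise."""
    total = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    for protocol in cohort:
        total += transition_counts(stage_sequence(protocol)).counts
    row_sums = total.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        relfreq = np.where(row_sums > 0, total / row_sums, np.nan)
    return PooledTransitionMatrix(group=cohort.group, counts=total, relfreq=relfreq)


def export_transition_diagram(
    matrix: PooledTransitionMatrix, min_probability: float = 0.05
) -> str:
    """Render a pooled matrix as a DOT directed graph.

    One node per stage (field abbreviations); one edge per cell with
    relative frequency >= ``min_probability``, labelled with the
    probability to two decimals and drawn with pen width proportional to
    it.
    """
    if not 0.0 <= min_probability <= 1.0:
        raise ValidationError(
            f"min_probability must be in [0, 1], got {min_probability}"
        )
    lines = [
        f'digraph "{matrix.group}" {{',
        "  rankdir=LR;",
        "  node [shape=circle, fontsize=12];",
    ]
    for stage in StageCode:
        lines.append(f'  {STAGE_ABBREV[stage]} [label="{STAGE_ABBREV[stage]}"];')
    for i in range(N_STAGES):
        for j in range(N_STAGES):
            p = matrix.relfreq[i, j]
            if np.isfinite(p) and p >= min_probability and p > 0:
                width = 0.5 + 6.0 * p
                lines.append(
                    f"  {STAGE_ABBREV[StageCode(i)]} -> {STAGE_ABBREV[StageCode(j)]}"
                    f' [label="{p:.2f}", penwidth={width:.2f}];'
                )
    lines.append("}")
    return "\n".join(lines) + "\n"
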