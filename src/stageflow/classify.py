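"""Balanced polynomial-kernel SVM classification of problem-solving stages.

The labeled AU feature tables are heavily imbalanced (block frames are
orders of magnitude rarer than production frames), so every class is first
randomly undersampled without replacement to the minority-class count.
The balanced data are split 80/20 (stratified), and a soft-margin SVM with
a degree-4 polynomial kernel and one-vs-one multiclass decomposition is
trained per (emotion feature set, group).  Per-stage accuracy is per-class
recall on the balanced test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.pipeline import make_pipeline
from sklearn.svm import SVC

from .errors import ValidationError
from .faces import EMOTION_AUS, EMOTIONS, RETAINED_STAGES, StageDataset, emotion_feature_view

__all__ = [
    "ClassifierSpec",
    "random_undersample",
    "split_train_test",
    "train_stage_classifier",
    "per_stage_accuracy",
    "accuracy_matrix",
    "accuracy_matrix_table",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Stage-classifier hyperparameters.

    ``multiclass_scheme`` is ``"ovo"`` (a single multiclass SVM with
    one-vs-one decomposition, the default reading) or ``"ovr"``
    (independent one-vs-rest binary classifiers per stage).
    """

    kernel: str = "poly"
    degree: int = 4
    regularization_weight: float = 1.0
    multiclass_scheme: str = "ovo"
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValidationError("kernel degree must be >= 1")
        if self.regularization_weight <= 0:
            raise ValidationError("regularization weight (C) must be positive")
        if self.multiclass_scheme not in ("ovo", "ovr"):
            raise ValidationError("multiclass_scheme must be 'ovo' or 'ovr'")


def random_undersample(dataset: StageDataset, seed: int) -> StageDataset:
    """Downsample every class, without replacement, to the minority count.

    Rows are selected uniformly at random per class; the result is
    reproducible from the seed.  Any declared stage with zero rows is an
    error (there is nothing to balance to).
    """
    counts = dataset.counts
    empty = list(counts.index[counts == 0])
    if empty:
        raise ValidationError(
            f"cannot undersample: stage(s) with zero rows: {', '.join(empty)}"
        )
    if len(counts) < 2:
        raise ValidationError("undersampling needs at least two classes")
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    labels = dataset.labels.to_numpy()
    keep: list[np.ndarray] = []
    for stage in dataset.stages:
        idx = np.flatnonzero(labels == stage)
        keep.append(np.sort(rng.choice(idx, size=target, replace=False)))
    sel = np.concatenate(keep)
    return StageDataset(
        features=dataset.features.iloc[sel].reset_index(drop=True),
        labels=dataset.labels.iloc[sel].reset_index(drop=True),
        group=dataset.group,
        stages=dataset.stages,
    )


def split_train_test(
    dataset: StageDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[StageDataset, StageDataset]:
    """Disjoint stratified partition with ``round((1 - f) * n)`` test rows.

    Test rows are apportioned across classes proportionally (largest
    remainder), so a balanced input yields a balanced test set (+-1 per
    class).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError(
            f"train_fraction must be in (0, 1), got {train_fraction}"
        )
    n = len(dataset)
    if n == 0:
        raise ValidationError("cannot split an empty dataset")
    n_test = int(round((1.0 - train_fraction) * n))
    labels = dataset.labels.to_numpy()
    classes = [s for s in dataset.stages if (labels == s).any()]
    quotas = np.array([(labels == s).sum() * n_test / n for s in classes])
    base = np.floor(quotas).astype(int)
    remainder = n_test - base.sum()
    order = np.argsort(-(quotas - base))
    base[order[:remainder]] += 1
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for stage, k in zip(classes, base):
        idx = np.flatnonzero(labels == stage)
        test_idx.append(rng.choice(idx, size=int(k), replace=False))
    test_mask = np.zeros(n, dtype=bool)
    test_mask[np.concatenate(test_idx).astype(int)] = True

    def _subset(mask: np.ndarray) -> StageDataset:
        return StageDataset(
            features=dataset.features.iloc[mask].reset_index(drop=True),
            labels=dataset.labels.iloc[mask].reset_index(drop=True),
            group=dataset.group,
            stages=dataset.stages,
        )

    return _subset(~test_mask), _subset(test_mask)


def train_stage_classifier(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
):
    """Fit the soft-margin polynomial-kernel stage classifier."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data contains a single class")
    svc = SVC(
        kernel=spec.kernel,
        degree=spec.degree,
        C=spec.regularization_weight,
        decision_function_shape="ovo",
        random_state=spec.seed,
    )
    clf = OneVsRestClassifier(svc) if spec.multiclass_scheme == "ovr" else svc
    if spec.standardize:
        clf = make_pipeline(StandardScaler(), clf)
    clf.fit(np.asarray(features, dtype=float), y)
    return clf


def per_stage_accuracy(
    classifier,
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | np.ndarray,
) -> pd.Series:
    """Per-class recall on a test set, plus an ``overall`` entry.

    A stage absent from the test set gets NaN rather than a fabricated
    score.
    """
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValidationError("test set is empty")
    pred = classifier.predict(np.asarray(features, dtype=float))
    stages = list(dict.fromkeys(list(RETAINED_STAGES) + list(np.unique(y))))
    out = {}
    for stage in stages:
        mask = y == stage
        out[stage] = float((pred[mask] == stage).mean()) if mask.any() else np.nan
    out["overall"] = float((pred == y).mean())
    return pd.Series(out)


def accuracy_matrix(
    datasets: Mapping[str, StageDataset],
    spec: ClassifierSpec = ClassifierSpec(),
    train_fraction: float = 0.8,
    max_rows_per_class: int | None = None,
) -> pd.DataFrame:
    """Per-stage accuracies for every emotion feature set and group.

    For each (emotion, group): undersample to balance, split 80/20
    stratified, train on the emotion's AU columns, and score per-stage
    recall on the held-out rows.  Rows are the 7 emotions; columns are
    ``<stage>_<group>``.  ``max_rows_per_class`` optionally caps the
    balanced class size (a runtime control; sampling stays uniform).
    """
    if not datasets:
        raise ValidationError("no group datasets provided")
    cols: dict[str, pd.Series] = {}
    root = np.random.SeedSequence(spec.seed)
    group_seeds = {g: s for g, s in zip(datasets, root.spawn(len(datasets)))}
    for group, dataset in datasets.items():
        for e_idx, emotion in enumerate(EMOTIONS):
            us_seed, split_seed = [
                int(s.generate_state(1)[0] % (2**31))
                for s in group_seeds[group].spawn(2 * len(EMOTIONS))[2 * e_idx : 2 * e_idx + 2]
            ]
            balanced = random_undersample(dataset, seed=us_seed)
            if max_rows_per_class is not None:
                balanced = _cap_per_class(balanced, max_rows_per_class, us_seed)
            train, test = split_train_test(balanced, train_fraction, seed=split_seed)
            clf = train_stage_classifier(
                emotion_feature_view(train, emotion), train.labels, spec
            )
            acc = per_stage_accuracy(
                clf, emotion_feature_view(test, emotion), test.labels
            )
            for stage in dataset.stages:
                cols.setdefault(f"{stage}_{group}", pd.Series(dtype=float))[emotion] = acc[stage]
    out = pd.DataFrame(cols, index=list(EMOTIONS))
    out.index.name = "emotion"
    return out


def _cap_per_class(dataset: StageDataset, cap: int, seed: int) -> StageDataset:
    if int(dataset.counts.min()) <= cap:
        return dataset
    rng = np.random.default_rng(seed + 1)
    labels = dataset.labels.to_numpy()
    keep = np.concatenate(
        [
            np.sort(rng.choice(np.flatnonzero(labels == s), size=cap, replace=False))
            for s in dataset.stages
        ]
    )
    return StageDataset(
        features=dataset.features.iloc[keep].reset_index(drop=True),
        labels=dataset.labels.iloc[keep].reset_index(drop=True),
        group=dataset.group,
        stages=dataset.stages,
    )


def accuracy_matrix_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Report layout: emotion, AU combination, accuracies as percentages."""
    out = pd.DataFrame(index=matrix.index)
    out["au_combination"] = [
        "+".join(str(a) for a in EMOTION_AUS[e]) for e in matrix.index
    ]
    for col in matrix.columns:
        out[col] = (matrix[col] * 100).map(lambda v: f"{v:.2f}%")
    return out
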