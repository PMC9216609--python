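"""Undersampling, splitting, and SVM stage classification."""

import numpy as np
import pandas as pd
import pytest

from stageflow import (
    ClassifierSpec,
    StageCode,
    accuracy_matrix,
    build_stage_datasets,
    default_emotion_profile,
    per_stage_accuracy,
    random_undersample,
    simulate_au_stream,
    split_train_test,
    train_stage_classifier,
)
from stageflow.errors import ValidationError
from stageflow.faces import EMOTIONS, RETAINED_STAGES

from conftest import make_dataset, make_protocol

#: Per-stage row counts of the two groups' labeled datasets (preparation
#: through block), as produced by the full-scale study.
CPS_STAGE_COUNTS = {
    "Preparation": 307599, "Ideation": 319334, "Evaluation": 47475,
    "Refinement": 127176, "Production": 531279, "Block": 2947,
}
SPS_STAGE_COUNTS = {
    "Preparation": 631997, "Ideation": 3820, "Evaluation": 61185,
    "Refinement": 75230, "Production": 554815, "Block": 4109,
}


class TestRandomUndersample:
    def test_minimum_rule(self):
        ds = make_dataset({"Preparation": 10, "Ideation": 4, "Production": 7})
        out = random_undersample(ds, seed=0)
        assert out.counts.tolist() == [4, 4, 4]

    def test_balanced_input_unchanged_in_counts(self):
        ds = make_dataset({"Preparation": 5, "Ideation": 5, "Block": 5})
        out = random_undersample(ds, seed=1)
        assert out.counts.tolist() == [5, 5, 5]

    def test_no_replacement_no_duplicates(self):
        ds = make_dataset({"Preparation": 50, "Ideation": 20})
        out = random_undersample(ds, seed=2)
        # distinct feature rows stay distinct after sampling
        assert not out.features.duplicated().any()

    def test_reproducible_by_seed(self):
        ds = make_dataset({"Preparation": 40, "Ideation": 15, "Block": 25})
        a = random_undersample(ds, seed=3)
        b = random_undersample(ds, seed=3)
        pd.testing.assert_frame_equal(a.features, b.features)

    def test_zero_row_class_rejected_by_name(self):
        ds = make_dataset({"Preparation": 5, "Ideation": 5})
        ds = ds.__class__(features=ds.features, labels=ds.labels,
                          group="CPS", stages=("Preparation", "Ideation", "Block"))
        with pytest.raises(ValidationError, match="Block"):
            random_undersample(ds, seed=0)


class TestSplitTrainTest:
    def test_eighty_twenty_arithmetic(self):
        ds = make_dataset({"Preparation": 5, "Ideation": 5})
        train, test = split_train_test(ds, seed=0)
        assert len(train) == 8 and len(test) == 2

    def test_partition_is_disjoint_and_complete(self):
        ds = make_dataset({"Preparation": 33, "Ideation": 27, "Block": 40})
        train, test = split_train_test(ds, seed=1)
        assert len(train) + len(test) == len(ds)
        merged = pd.concat([train.features, test.features]).sort_values(
            list(train.features.columns)
        )
        original = ds.features.sort_values(list(ds.features.columns))
        pd.testing.assert_frame_equal(
            merged.reset_index(drop=True), original.reset_index(drop=True)
        )

    def test_stratified_on_balanced_input(self):
        counts = {s: 50 for s in RETAINED_STAGES}
        train, test = split_train_test(make_dataset(counts), seed=2)
        per_class = test.counts
        assert (per_class >= 9).all() and (per_class <= 11).all()

    def test_reproducible_by_seed(self):
        ds = make_dataset({"Preparation": 30, "Ideation": 30})
        a_train, a_test = split_train_test(ds, seed=4)
        b_train, b_test = split_train_test(ds, seed=4)
        pd.testing.assert_frame_equal(a_test.features, b_test.features)

    def test_bad_fraction_rejected(self):
        ds = make_dataset({"Preparation": 5, "Ideation": 5})
        with pytest.raises(ValidationError):
            split_train_test(ds, train_fraction=1.0)


class TestTrainAndScore:
    def test_separable_clusters_perfect_accuracy(self):
        ds = make_dataset(
            {"Preparation": 60, "Block": 60},
            shift={"Block": (0, 5.0)},
        )
        train, test = split_train_test(ds, seed=0)
        clf = train_stage_classifier(train.features, train.labels)
        acc = per_stage_accuracy(clf, test.features, test.labels)
        assert acc["overall"] == 1.0

    def test_uninformative_features_near_chance(self):
        rng = np.random.default_rng(5)
        counts = {s: 120 for s in RETAINED_STAGES}
        ds = make_dataset(counts, seed=5)  # identical feature distribution
        train, test = split_train_test(ds, seed=5)
        clf = train_stage_classifier(train.features, train.labels)
        acc = per_stage_accuracy(clf, test.features, test.labels)
        n_test = len(test)
        se = np.sqrt((1 / 6) * (5 / 6) / n_test)
        assert abs(acc["overall"] - 1 / 6) < 4 * se

    def test_single_class_training_rejected(self):
        ds = make_dataset({"Preparation": 10})
        with pytest.raises(ValidationError):
            train_stage_classifier(ds.features, ds.labels)

    def test_absent_test_stage_flagged_nan(self):
        ds = make_dataset({"Preparation": 30, "Block": 30})
        clf = train_stage_classifier(ds.features, ds.labels)
        acc = per_stage_accuracy(clf, ds.features.iloc[:5], ds.labels.iloc[:5])
        assert np.isnan(acc["Ideation"])

    def test_constant_predictor_degenerate_scores(self):
        class Always:
            def predict(self, X):
                return np.array(["Block"] * len(X))

        ds = make_dataset({s: 10 for s in RETAINED_STAGES})
        acc = per_stage_accuracy(Always(), ds.features, ds.labels)
        assert acc["Block"] == 1.0
        assert acc["Preparation"] == 0.0
        assert acc["overall"] == pytest.approx(1 / 6)


def _synthetic_group_dataset(delta, seed, n_events=60):
    """Labeled dataset from the generator with controllable activation."""
    from stageflow.synth import cps_like_chain

    from stageflow import simulate_protocol

    profile = default_emotion_profile(
        activation_delta=delta, low_confidence_rate=0.0
    )
    streams = []
    for k in range(3):
        protocol = simulate_protocol(
            cps_like_chain(), n_events, seed=seed + k, participant_id=f"P{k}"
        )
        streams.append(simulate_au_stream(protocol, profile, seed=seed + 100 + k))
    ds = build_stage_datasets(streams, "CPS")
    present = [s for s in RETAINED_STAGES if ds.counts[s] > 0]
    return ds.__class__(features=ds.features, labels=ds.labels, group="CPS",
                        stages=tuple(present))


class TestEndToEndClassification:
    def test_block_dominates_under_negative_emotion_profile(self):
        """Block frames are driven by negative emotions; under the Anger
        feature view Block recall must top every other stage."""
        from stageflow import EmotionProfile, simulate_protocol
        from stageflow.faces import emotion_feature_view
        from stageflow.synth import cps_like_chain

        # Block expresses only negative emotions; every other stage mixes
        # positive emotions whose combinations avoid the Anger AUs
        weights = {
            stage: {"Happiness": 0.4, "Stress": 0.2, "neutral": 0.4}
            for stage in ("Preparation", "Ideation", "Illumination",
                          "Evaluation", "Refinement", "Production", "Other")
        }
        weights["Block"] = {"Anger": 0.5, "Fear": 0.25, "Sadness": 0.15,
                            "Disgust": 0.10}
        profile = EmotionProfile(
            weights=weights, activation_delta=2.5, baseline=0.5,
            noise_sd=0.35, episode_persistence=12.0, low_confidence_rate=0.0,
        )
        streams = []
        for k in range(3):
            protocol = simulate_protocol(
                cps_like_chain(), 150, seed=20 + k, participant_id=f"P{k}"
            )
            streams.append(simulate_au_stream(protocol, profile, seed=120 + k))
        ds = build_stage_datasets(streams, "CPS")
        present = tuple(s for s in RETAINED_STAGES if ds.counts[s] > 0)
        ds = ds.__class__(features=ds.features, labels=ds.labels,
                          group="CPS", stages=present)
        balanced = random_undersample(ds, seed=0)
        train, test = split_train_test(balanced, seed=0)
        clf = train_stage_classifier(
            emotion_feature_view(train, "Anger"), train.labels
        )
        acc = per_stage_accuracy(
            clf, emotion_feature_view(test, "Anger"), test.labels
        )
        block = acc["Block"]
        others = [acc[s] for s in balanced.stages if s != "Block"]
        assert block > max(others)

    def test_accuracy_monotone_in_activation(self):
        """Mean per-stage accuracy does not decrease as the emotion
        activation grows (one binomial SE slack)."""
        means, ns = [], []
        for delta in (0.4, 1.2, 2.0):
            ds = _synthetic_group_dataset(delta=delta, seed=40)
            balanced = random_undersample(ds, seed=1)
            train, test = split_train_test(balanced, seed=1)
            clf = train_stage_classifier(train.features, train.labels)
            acc = per_stage_accuracy(clf, test.features, test.labels)
            means.append(acc["overall"])
            ns.append(len(test))
        for lo, hi, n in zip(means, means[1:], ns[1:]):
            se = np.sqrt(max(lo, 1e-3) * (1 - min(lo, 0.999)) / n)
            assert hi >= lo - se, (means, ns)

    def test_accuracy_matrix_shape_contract(self):
        datasets = {
            "CPS": make_dataset({s: 30 for s in RETAINED_STAGES}, seed=1),
            "SPS": make_dataset({s: 30 for s in RETAINED_STAGES}, seed=2,
                                group="SPS"),
        }
        matrix = accuracy_matrix(datasets, ClassifierSpec(seed=0))
        assert matrix.shape == (7, 12)
        assert list(matrix.index) == list(EMOTIONS)
        vals = matrix.to_numpy()
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0

    def test_ovr_switch_runs(self):
        ds = make_dataset({"Preparation": 40, "Block": 40},
                          shift={"Block": (0, 5.0)})
        train, test = split_train_test(ds, seed=0)
        clf = train_stage_classifier(
            train.features, train.labels,
            ClassifierSpec(multiclass_scheme="ovr"),
        )
        acc = per_stage_accuracy(clf, test.features, test.labels)
        assert acc["overall"] == 1.0
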