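import numpy as np
import pandas as pd
import pytest

from stageflow import Cohort, CodedProtocol, Segment, StageCode, StageDataset
from stageflow.faces import AU_COLUMNS


def make_protocol(stages, pid="P01", group="CPS", duration=2.0):
    """Contiguous protocol from a list of StageCode, durations uniform."""
    segs = []
    t = 0.0
    for st in stages:
        segs.append(Segment(participant_id=pid, start_s=t, end_s=t + duration, stage=st))
        t += duration
    return CodedProtocol(participant_id=pid, group=group, segments=tuple(segs))


def make_dataset(class_counts, group="CPS", seed=0, shift=None):
    """StageDataset with given per-class row counts (Gaussian features).

    ``shift`` optionally maps class -> (column index, offset) to make the
    classes separable.
    """
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for stage, n in class_counts.items():
        X = rng.normal(1.0, 0.3, size=(n, len(AU_COLUMNS)))
        if shift and stage in shift:
            col, off = shift[stage]
            X[:, col] += off
        frames.append(X)
        labels.extend([stage] * n)
    features = pd.DataFrame(np.vstack(frames), columns=list(AU_COLUMNS))
    return StageDataset(
        features=features,
        labels=pd.Series(labels, name="stage"),
        group=group,
        stages=tuple(class_counts),
    )


@pytest.fixture
def prep_ide_prod_protocol():
    return make_protocol(
        [StageCode.PREPARATION, StageCode.IDEATION, StageCode.PRODUCTION]
    )
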