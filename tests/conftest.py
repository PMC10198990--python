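import numpy as np
import pandas as pd
import pytest

from emotrack import SyntheticConfig, generate_cohort, score_study


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 20 x 8 cohort with short clips for structural tests."""
    cfg = SyntheticConfig(
        n_participants=20, n_videos=8, duration_range_s=(30.0, 50.0), seed=5
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study conditions: 102 participants x 35 clips of
    1-3 minutes, competency loading on AQ at -0.4."""
    cfg = SyntheticConfig(seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_scored(default_cohort):
    ratings, _, _ = default_cohort
    return score_study(ratings)


def make_accuracy_table(matrix: pd.DataFrame, dimension: str = "valence"):
    """Build an AccuracyTable from a participant x video cell matrix."""
    from emotrack.consensus import AccuracyTable, pool_fisher_z

    cells = (
        matrix.rename_axis(index="participant_id", columns="video_id")
        .stack()
        .rename("r")
        .reset_index()
    )
    cells["dimension"] = dimension
    cells = cells[["participant_id", "video_id", "dimension", "r"]]
    pp = (
        cells.groupby(["participant_id", "dimension"])["r"]
        .apply(pool_fisher_z)
        .reset_index()
        .rename(columns={"r": "accuracy"})
    )
    vp = (
        cells.groupby(["video_id", "dimension"])["r"]
        .apply(pool_fisher_z)
        .reset_index()
        .rename(columns={"r": "accuracy"})
    )
    return AccuracyTable(cells=cells, participant_pooled=pp, video_pooled=vp,
                         consensus={})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
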