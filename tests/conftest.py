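import numpy as np
import pandas as pd
import pytest

from perilink import (
    RecordSet,
    SyntheticConfig,
    generate_linked_datasets,
)
from perilink.presets import BEST_GUESS


@pytest.fixture
def tiny_cohort() -> RecordSet:
    df = pd.DataFrame(
        {
            "id": ["c1", "c2", "c3"],
            "date_of_birth": pd.to_datetime(["1995-06-01", "1995-06-01", "1995-07-15"]),
            "sex": ["male", "female", "female"],
            "gestational_age": pd.array([24, 25, 23], dtype="Int64"),
            "birth_weight": pd.array([650, 720, pd.NA], dtype="Int64"),
        }
    )
    return RecordSet(df, "cohort")


@pytest.fixture
def tiny_episodes() -> RecordSet:
    df = pd.DataFrame(
        {
            "id": ["e1", "e2", "e3", "e4"],
            "date_of_birth": pd.to_datetime(
                ["1995-06-01", "1995-06-01", "1995-06-01", pd.NaT]
            ),
            "sex": ["male", "female", None, "female"],
            "gestational_age": pd.array([24, 25, 30, 23], dtype="Int64"),
            "birth_weight": pd.array([650, 700, 3200, 560], dtype="Int64"),
        }
    )
    return RecordSet(df, "episodes")


@pytest.fixture(scope="session")
def small_linked():
    """A small generated pair of registers with full cohort overlap."""
    cfg = SyntheticConfig(
        n_cohort=60,
        n_episodes=600,
        n_true_matches=60,
        probability_table=BEST_GUESS,
        missingness_rates=None,
        discordance_rate=0.0,
        seed=11,
    )
    return generate_linked_datasets(cfg)
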