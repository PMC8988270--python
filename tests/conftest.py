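import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_cohort_df():
    """A 6-row valid cohort with 3 items and two groups."""
    return pd.DataFrame({
        "item1": [0, 1, 2, 3, 1, 0],
        "item2": [1, 1, 0, 2, 3, 1],
        "item3": [0, 0, 1, 1, 2, 2],
        "age": [30.0, 40.0, 50.0, 35.0, 45.0, 55.0],
        "sex": [0, 1, 0, 1, 0, 1],
        "group": ["A", "A", "A", "B", "B", "B"],
    })


@pytest.fixture
def cohort_csv(tmp_path, small_cohort_df):
    path = tmp_path / "cohort.csv"
    small_cohort_df.to_csv(path, index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240311)
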