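import numpy as np
import pandas as pd
import pytest

from sleeprec.ratings import RatingMatrix
from sleeprec.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    """A compact cohort: 60 users, 3 well-separated archetypes."""
    return SyntheticConfig(
        n_users=60,
        k_true=3,
        nights_per_user=3,
        archetype_means=(
            (4.5, 20.0, 38.0, 1.0, 24.0),
            (6.5, 15.0, 55.0, 6.0, 31.0),
            (9.5, 4.0, 25.0, 0.2, 18.0),
        ),
        feature_noise_sd=(0.3, 2.0, 2.0, 0.3, 1.0),
        missing_rate=0.3,
        seed=7,
    )


@pytest.fixture
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def toy_matrix():
    """Four users, three patterns, hand-set ratings with gaps."""
    raw = np.array(
        [
            [5.0, 1.0, 3.0],
            [5.0, 1.0, np.nan],
            [1.0, 5.0, np.nan],
            [np.nan, np.nan, np.nan],
        ]
    )
    return RatingMatrix(["A", "B", "C", "D"], ["SM1", "SM2", "SM3"], raw)


def random_rating_matrix(rng, n_users=20, n_items=8, missing=0.4):
    """Random integer 1-5 matrix with missing entries, for fuzz tests."""
    raw = rng.integers(1, 6, size=(n_users, n_items)).astype(float)
    raw[rng.random((n_users, n_items)) < missing] = np.nan
    uids = [f"U{i:02d}" for i in range(n_users)]
    smids = [f"SM{j + 1}" for j in range(n_items)]
    return RatingMatrix(uids, smids, raw)
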