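import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from topicscep import CodingScheme, PreferenceWeights, ProRatingPolicy
from topicscep.scoring import ITEM_COLS


@pytest.fixture(scope="session")
def scheme() -> CodingScheme:
    return CodingScheme.default()


@pytest.fixture(scope="session")
def policy() -> ProRatingPolicy:
    return ProRatingPolicy()


@pytest.fixture(scope="session")
def weights(scheme) -> PreferenceWeights:
    return PreferenceWeights.for_scheme(scheme)


def make_record(scheme: CodingScheme, state: str = "best", n: int = 1) -> pd.DataFrame:
    """Item table with every item at its best or worst native level."""
    row = {}
    for col in ITEM_COLS:
        spec = scheme.items[col]
        if state == "best":
            row[col] = spec.native_max if spec.higher_is_better else spec.native_min
        else:
            row[col] = spec.native_min if spec.higher_is_better else spec.native_max
    return pd.DataFrame([row] * n)


@pytest.fixture
def best_record(scheme) -> pd.DataFrame:
    return make_record(scheme, "best")


@pytest.fixture
def worst_record(scheme) -> pd.DataFrame:
    return make_record(scheme, "worst")
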