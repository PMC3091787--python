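import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture
def small_map() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(1, 7)],
            "chromosome": ["7", "7", "7", "7", "18", "18"],
            "position": [100, 150, 200, 10_000, 500, 1_000],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20101129)
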