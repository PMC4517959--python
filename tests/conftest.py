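import numpy as np
import pandas as pd
import pytest

from odglmm import Dataset


@pytest.fixture
def toy_dataset() -> Dataset:
    """Two populations, three rows; the standard small fixture for oracles."""
    frame = pd.DataFrame(
        {
            "population": [0, 0, 1],
            "prey": [0.5, -1.2, 0.3],
            "bodysize": [2.0, -5.0, 1.0],
            "clutch": [5, 5, 5],
            "hatched": [2, 0, 4],
        }
    )
    return Dataset(frame=frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
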