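import numpy as np
import pandas as pd
import pytest

from neurobalance.datasets import load_stroke_cohort


@pytest.fixture(scope="session")
def cohort() -> pd.DataFrame:
    """The packaged eight-patient stroke cohort feature table."""
    return load_stroke_cohort()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
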