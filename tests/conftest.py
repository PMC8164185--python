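import numpy as np
import pandas as pd
import pytest

from violence_survey.synthetic_data import default_config, generate_dataset


@pytest.fixture(scope="session")
def default_dataset() -> pd.DataFrame:
    """One full-size survey drawn under the default study conditions."""
    return generate_dataset(default_config(seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240501)
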