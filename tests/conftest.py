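import numpy as np
import pandas as pd
import pytest

from qsarlab import datasets


@pytest.fixture(scope="session")
def validation_set() -> pd.DataFrame:
    """The 12 validation compounds with descriptors and printed predictions."""
    return datasets.load_validation_set()


@pytest.fixture(scope="session")
def all_predictions() -> pd.DataFrame:
    """Observed/printed-predicted activities for all 39 compounds."""
    return datasets.load_model1_predictions()


@pytest.fixture(scope="session")
def designed_properties() -> pd.DataFrame:
    """Property table of the 18 designed compounds."""
    return datasets.load_designed_properties()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_descriptors(rng) -> pd.DataFrame:
    """A 20 x 5 random descriptor matrix with distinct pairwise distances."""
    X = pd.DataFrame(
        rng.standard_normal((20, 5)),
        columns=[f"d{j}" for j in range(5)],
        index=[f"c{i}" for i in range(20)],
    )
    return X
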