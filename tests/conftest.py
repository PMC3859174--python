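import numpy as np
import pandas as pd
import pytest

from qsbr import dataset_io, synthetic


@pytest.fixture(scope="session")
def packaged() -> pd.DataFrame:
    """The packaged 227-peptide table as a DataFrame."""
    return dataset_io.packaged_frame()


@pytest.fixture(scope="session")
def six_descriptor_data():
    """A seeded six-descriptor design with an equation-driven response."""
    X, _ = synthetic.gen_joint(synthetic.SyntheticConfig(n=181, seed=11))
    y = synthetic.gen_equation_response(X, noise_sd=0.43, seed=12)
    return X, y


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
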