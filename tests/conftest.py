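import warnings

import numpy as np
import pytest

from diazobloom import generate_dataset, make_worked_fixture


@pytest.fixture(scope="session")
def worked():
    """Tiny deterministic dataset with hand-checkable values."""
    return make_worked_fixture()


@pytest.fixture(scope="session")
def synth_small():
    """A modest synthetic dataset shared by slower integration tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(seed=11, n_samples=250, n_taxa=40)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
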