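import warnings

import numpy as np
import pytest

from berghia_social import load_packaged_choices, load_packaged_trials


@pytest.fixture(scope="session")
def table1():
    """The packaged 28-trial group-feeding table (trial-4 warning silenced)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return load_packaged_trials()


@pytest.fixture(scope="session")
def seven_day(table1):
    return table1.subset(7)


@pytest.fixture(scope="session")
def three_day(table1):
    return table1.subset(3)


@pytest.fixture(scope="session")
def choice_records():
    return load_packaged_choices()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
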