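import numpy as np
import pytest

from mrnapkpd.estimation import ModelParameters
from mrnapkpd.synthetic import default_designs, default_truth


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def truth_model(truth):
    return ModelParameters(
        pk=truth.pk, pd=truth.pd, biomarkers=truth.biomarkers, pop=truth.pop
    )


@pytest.fixture(scope="session")
def designs():
    return default_designs()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
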