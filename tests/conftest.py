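import numpy as np
import pytest

from crisisqueue.params import GroundTruthParams
from crisisqueue.synthetic import generate_synthetic_log


@pytest.fixture(scope="session")
def reference_log():
    """A full 30-day synthetic log at reference operating statistics.

    Eight single-chat servers keep most accepted cases served so every
    duration stratum (including the ~0.7% high/crisis one) is fittable.
    """
    params = GroundTruthParams.reference()
    return generate_synthetic_log(params, 43_200.0, n_counselors=8, seed=123)


@pytest.fixture(scope="session")
def reference_truth():
    return GroundTruthParams.reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
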