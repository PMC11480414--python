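import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# statsmodels emits convergence chatter on boundary random-effect fits;
# the fits themselves carry an explicit converged flag we assert on.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
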