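import warnings

import pytest
from hypothesis import HealthCheck, settings

from newance.fdr_core import SmallStratumWarning

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_small_strata():
    """Synthetic test datasets are far below the recommended stratum size."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallStratumWarning)
        yield
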