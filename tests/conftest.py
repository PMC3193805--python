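import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def post_times():
    """Default post-contrast time grid: 12 s frames over 20 min, minutes."""
    return np.arange(1, 101) * 0.2


@pytest.fixture
def small_design():
    """A reduced two-arm cohort design for fast end-to-end tests."""
    from brixflow.cohort import CohortDesign, GroupSpec

    return CohortDesign(
        groups=(
            GroupSpec("Control", 2, 0.82, 1.45, 1.0),
            GroupSpec("RT", 2, 1.29, 0.73, 0.25),
        ),
        seed=11,
        grid_size=16,
        roi_semi_axes=(5.6, 4.5),
    )
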