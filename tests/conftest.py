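import numpy as np
import pytest
from hypothesis import settings

from hccmet.diffexp import ExpressionCohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from hccmet.tracer import build_default_network, load_default_routes


@pytest.fixture(scope="session")
def network():
    return build_default_network()


@pytest.fixture(scope="session")
def routes():
    return load_default_routes()


@pytest.fixture()
def toy_cohort():
    """4 genes x 6 samples; gene order: strong up, strong down, null, constant."""
    values = np.array([
        [9.0, 9.1, 8.9, 5.0, 5.1, 4.9],   # up ~ +4
        [3.0, 3.1, 2.9, 7.0, 7.1, 6.9],   # down ~ -4
        [5.0, 5.2, 4.8, 5.1, 4.9, 5.0],   # null
        [6.0, 6.0, 6.0, 6.0, 6.0, 6.0],   # zero variance, equal means
    ])
    return ExpressionCohort(
        "toy", ["up1", "down1", "null1", "flat1"],
        [f"S{i}" for i in range(6)], values,
        ["tumor"] * 3 + ["normal"] * 3,
    )
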