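import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp1_schedule():
    from pulsegap import build_exp1_schedule

    return build_exp1_schedule(seed=11)


@pytest.fixture(scope="session")
def exp2_schedule():
    from pulsegap import build_exp2_schedule

    return build_exp2_schedule(seed=11)


@pytest.fixture(scope="session")
def exp1_small_table(exp1_schedule):
    """Trial table from 4 synthetic subjects on the rate task."""
    from pulsegap import RateObserverParams, simulate_dataset

    return simulate_dataset(
        exp1_schedule, RateObserverParams(), 4, np.random.default_rng(5)
    )


@pytest.fixture(scope="session")
def exp2_small_table(exp2_schedule):
    """Trial table from 6 synthetic subjects on the gap task."""
    from pulsegap import GapObserverParams, simulate_dataset

    return simulate_dataset(
        exp2_schedule, GapObserverParams(), 6, np.random.default_rng(5)
    )
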