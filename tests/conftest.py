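import numpy as np
import pytest

from gaitbarrier.preprocess import preprocess_cohort
from gaitbarrier.synth import (
    Barrier,
    GenerationBounds,
    RouteSpec,
    generate_subject,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def short_route():
    """100 m route with two well-separated high-severity barriers."""
    return RouteSpec(
        length_m=100.0,
        barriers=(
            Barrier(position_m=30.0, extent_m=3.0, severity=0.9, kind="uneven_sidewalk"),
            Barrier(position_m=70.0, extent_m=2.0, severity=1.0, kind="curb_drop"),
        ),
    )


@pytest.fixture(scope="session")
def small_cohort(short_route):
    """3 subjects x 1 trial on the short route (deterministic)."""
    return simulate_cohort(n_subjects=3, n_trials=1, route=short_route, master_seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, short_route):
    return preprocess_cohort(small_cohort, short_route)


@pytest.fixture(scope="session")
def profile():
    return generate_subject(123, GenerationBounds())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def lorenz_x():
    from oracles import lorenz_x_series

    return lorenz_x_series(5000)


@pytest.fixture(scope="session")
def benettin_lambda():
    from oracles import benettin_max_lyapunov

    return benettin_max_lyapunov()
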