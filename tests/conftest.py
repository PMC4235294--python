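import warnings

import numpy as np
import pytest

from carbarylsim import (
    default_params,
    draw_exposure_profile,
    draw_subjects,
    monte_carlo,
    panels_to_frame,
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def population_500():
    """The full-size virtual population (subjects only; cheap)."""
    return draw_subjects(500, seed=20)


@pytest.fixture(scope="session")
def profiles_500(population_500):
    """A year of exposure events for every subject (~2 s)."""
    return {s.id: draw_exposure_profile(s, seed=20) for s in population_500}


@pytest.fixture(scope="session")
def desk_records(params):
    """The scaled-down Monte Carlo run (50 subjects x 2 reps) shared by the
    bookkeeping and regression tests; exercises the full-scale code path."""
    subjects = draw_subjects(50, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return monte_carlo(params, subjects, reps=2, seed=11)


@pytest.fixture(scope="session")
def desk_panels(desk_records):
    return panels_to_frame(desk_records)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
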