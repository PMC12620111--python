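import numpy as np
import pytest

import sourcesink as ss


@pytest.fixture(scope="session")
def small_schedule():
    """Three populations, ten years, one staggered invasion."""
    return ss.InvasionSchedule(
        populations=("A", "B", "C"),
        invasion_year={"A": 2003, "B": 2006},
        study_years=(2000, 2009),
    )


@pytest.fixture(scope="session")
def flat_truth_surface():
    """A truth surface with no invasion response anywhere."""
    null = ss.TsiEffect("null")
    return ss.default_truth().with_(
        theta_tsi=null, attempts_tsi=null, nest_tsi=null,
        fledged_tsi=null, survival_tsi=null, survival_juv_tsi_slope=0.0,
        move_tsi=null)


@pytest.fixture(scope="session")
def small_truth(small_schedule, flat_truth_surface):
    return ss.realize_truth(small_schedule, flat_truth_surface)


@pytest.fixture(scope="session")
def small_dataset(small_truth, small_schedule):
    """~1,800 histories over 10 occasions with nests and breeder records."""
    return ss.simulate_dataset(
        small_truth, small_schedule,
        ss.CohortDesign(nestlings=40, adults=20), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
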