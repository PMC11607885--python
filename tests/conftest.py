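import warnings

import numpy as np
import pytest

from circagest.cohort import generate_cohort
from circagest.preprocess import aggregate, filter_food_events, to_five_min
from circagest.profiles import CohortConfig, PregnancyEffectSpec

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


def small_config(n=4, seed=0, **kw):
    """Small balanced cohort with everyone surviving to day 17.5."""
    return CohortConfig(
        n_nonpregnant=n,
        n_pregnant=n,
        termination_schedule={"nonpregnant": (0, 0, n), "pregnant": (0, 0, n)},
        random_seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def null_effects():
    """Pregnancy indistinguishable from control."""
    return PregnancyEffectSpec(onset_delay=np.zeros(17))


@pytest.fixture(scope="session")
def small_cohort(null_effects):
    return generate_cohort(small_config(n=4, seed=11), effects=null_effects)


@pytest.fixture(scope="session")
def small_blocks(small_cohort):
    return to_five_min(filter_food_events(small_cohort))


@pytest.fixture(scope="session")
def small_hourly(small_cohort):
    return aggregate(small_cohort)
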