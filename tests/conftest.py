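import numpy as np
import pytest

from ticsupp.synthetic_data import CONDITIONS, CohortConfig, generate_cohort, simulate_cohort_ics


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale cohort: 4 subjects/group, uniform moderate event rates."""
    return CohortConfig(
        n_per_group={"TDC": 4, "CTD": 4},
        event_rate={(g, c): 6.0 for g in ("TDC", "CTD") for c in CONDITIONS},
        sampling_rate=125.0,
        ics_per_subject=(1, 2),
        min_events=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_ic_data(small_cohort):
    return simulate_cohort_ics(small_cohort)
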