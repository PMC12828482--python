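import logging

import pytest

from congenialmi import induce_missingness, make_data


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.getLogger("congenialmi").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cohort_linear_het():
    """One medium complete cohort under the heterogeneous linear scenario."""
    return make_data(2000, "linear_het", seed=20260101)


@pytest.fixture(scope="session")
def observed_confounder(cohort_linear_het):
    """The same cohort with MAR-masked confounder."""
    return induce_missingness(cohort_linear_het, "confounder", seed=42)


@pytest.fixture(scope="session")
def observed_outcome(cohort_linear_het):
    return induce_missingness(cohort_linear_het, "outcome", seed=43)
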