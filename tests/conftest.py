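import numpy as np
import pytest

from hemaflux.params import (
    AgeGroup,
    IndividualParameters,
    Scenario,
    default_population,
)


@pytest.fixture(scope="session")
def pop():
    return default_population()


@pytest.fixture()
def lt_individual(pop):
    """A single-LT mouse with population-average donor parameters."""
    return IndividualParameters(
        scale={},
        LC0=pop.LC0_pop,
        SC0=pop.SC0_pop,
        age_group=AgeGroup.young,
        scenario=Scenario.single_LT,
        individual_id="lt-avg",
    )


@pytest.fixture()
def st_individual(pop):
    return IndividualParameters(
        scale={},
        LC0=pop.LC0_pop,
        SC0=pop.SC0_pop,
        age_group=AgeGroup.young,
        scenario=Scenario.single_ST,
        individual_id="st-avg",
    )
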