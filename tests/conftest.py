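import numpy as np
import pytest

from hostcycle import (
    CompetitionMatrix,
    PopulationState,
    Scenario,
    Traits,
    scenario_matrix,
)


@pytest.fixture
def source_sink_traits() -> Traits:
    """The running example: slow host, fast environment, symmetric migration."""
    return Traits(r_E=1.0, r_H=0.1, m_E=0.5, m_H=0.5)


@pytest.fixture
def no_competition() -> CompetitionMatrix:
    return scenario_matrix(Scenario.NONE)


@pytest.fixture
def mixed_start() -> PopulationState:
    return PopulationState(n_H=0.5, n_E=0.5)


def random_traits(rng: np.random.Generator, *, r_range=(-1.0, 2.0), m_range=(0.0, 3.0)) -> Traits:
    return Traits(
        r_E=float(rng.uniform(*r_range)),
        r_H=float(rng.uniform(*r_range)),
        m_E=float(rng.uniform(*m_range)),
        m_H=float(rng.uniform(*m_range)),
    )
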