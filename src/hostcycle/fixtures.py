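"""Reproducible random parameter draws for property-based testing.

Draw ranges mirror the regime the model is studied in: replication rates
in [-1, 2] (host replication may be negative — net death), migration
rates in [0, 3], competition intensities in (0, 2].  Draws respect all
type invariants by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import CompetitionMatrix, Scenario, Traits, scenario_matrix

__all__ = ["fixture_draws", "ParameterDraw"]

_SCENARIOS = (
    Scenario.NONE,
    Scenario.GLOBAL,
    Scenario.HOST_ONLY,
    Scenario.ENV_ONLY,
    Scenario.EQUAL_PER_COMPARTMENT,
)


@dataclass(frozen=True)
class ParameterDraw:
    traits: Traits
    k: CompetitionMatrix


def fixture_draws(
    seed: int,
    n: int,
    *,
    r_range: tuple[float, float] = (-1.0, 2.0),
    m_range: tuple[float, float] = (0.0, 3.0),
    k_range: tuple[float, float] = (0.1, 2.0),
    scenarios: tuple[Scenario, ...] = _SCENARIOS,
) -> list[ParameterDraw]:
    """``n`` reproducible (Traits, CompetitionMatrix) draws for seed ``seed``."""
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        traits = Traits(
            r_E=float(rng.uniform(*r_range)),
            r_H=float(rng.uniform(*r_range)),
            m_E=float(rng.uniform(*m_range)),
            m_H=float(rng.uniform(*m_range)),
        )
        scenario = scenarios[int(rng.integers(len(scenarios)))]
        k_val = 0.0 if scenario is Scenario.NONE else float(rng.uniform(*k_range))
        out.append(ParameterDraw(traits=traits, k=scenario_matrix(scenario, k_val)))
    return out
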