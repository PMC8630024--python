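"""Finite-horizon fitness Λ and its finite-difference selection gradient.

When competition makes the dynamics nonlinear the asymptotic growth rate
loses meaning (with global saturation it is simply zero), so fitness is
measured over a finite window instead:

    Λ = log( n(t_max) / n(0) ) / t_max,

the effective exponential growth rate over the probing window [0, t_max],
with n the total abundance n_E + n_H (or a single compartment when
selection acts on one compartment only, e.g. in a serial-passage
experiment that harvests just the host).  Λ depends on the probing time,
on the initial distribution of microbes across compartments, and on the
competition intensities — all of which are part of the measurement
protocol captured by :class:`ProbeSpec`.

Sensitivities of Λ are forward differences

    S_i = (Λ(x + δx_i e_i) - Λ(x)) / δx_i,

with the step halved until two successive estimates agree to the
requested tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from .model_core import (
    CompetitionMatrix,
    InvalidParameterError,
    PopulationState,
    Traits,
    Trajectory,
    integrate,
)
from .linear_model import SensitivityVector, TRAIT_NAMES

__all__ = [
    "FitnessScope",
    "ProbeSpec",
    "FitnessResult",
    "effective_growth_rate",
    "finite_difference_sensitivities",
    "stage_biased_initial",
]


class UndefinedFitnessError(ArithmeticError):
    """The scoped abundance vanishes at an endpoint, so Λ is undefined."""


class FitnessScope(str, Enum):
    """Which abundance Λ is measured on: the whole lineage or one compartment."""

    TOTAL = "total"
    HOST_ONLY = "host_only"
    ENV_ONLY = "env_only"


@dataclass(frozen=True)
class ProbeSpec:
    """Finite-horizon fitness measurement protocol.

    Parameters
    ----------
    t_max : float
        Probing time, in units of 1/r_E under the standard scaling. A
        modeling choice with biological meaning (experiment duration,
        ecological time scale), not a numerical knob.
    n0 : PopulationState
        Initial distribution of microbes across compartments.
    scope : FitnessScope
        Abundance Λ is computed on (whole lineage by default).
    delta_x : float
        Initial forward-difference step for sensitivities, same units as
        the perturbed trait.
    delta_refinement : float
        Two successive halved-step estimates must agree to within this
        before a sensitivity is flagged converged.
    max_halvings : int
        Cap on step halvings before the non-convergence flag is raised.
    rtol, atol : float
        Integration tolerances used for every Λ evaluation under this
        probe. Tight defaults keep solver noise below the finite-difference
        refinement tolerance.
    """

    t_max: float
    n0: PopulationState = PopulationState(0.5, 0.5)
    scope: FitnessScope = FitnessScope.TOTAL
    delta_x: float = 1e-4
    delta_refinement: float = 1e-6
    max_halvings: int = 10
    rtol: float = 1e-12
    atol: float = 1e-16

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise InvalidParameterError(f"t_max must be > 0, got {self.t_max}")
        if self.n0.total <= 0:
            raise InvalidParameterError("initial total abundance must be > 0")
        if self.delta_x <= 0:
            raise InvalidParameterError(f"delta_x must be > 0, got {self.delta_x}")
        object.__setattr__(self, "scope", FitnessScope(self.scope))

    def as_dict(self) -> dict:
        return {
            "t_max": self.t_max,
            "n0": {"n_H": self.n0.n_H, "n_E": self.n0.n_E},
            "scope": self.scope.value,
            "delta_x": self.delta_x,
            "delta_refinement": self.delta_refinement,
        }


@dataclass(frozen=True)
class FitnessResult:
    """Effective growth rate Λ plus the trajectory and protocol behind it."""

    Lambda: float
    trajectory: Trajectory
    probe: ProbeSpec

    def as_record(self, traits: Traits, k: CompetitionMatrix) -> dict:
        """JSON-ready record with full provenance."""
        return {
            "traits": traits.as_dict(),
            "competition": k.as_dict(),
            "probe": self.probe.as_dict(),
            "Lambda": self.Lambda,
        }


def _scoped(n_H: float, n_E: float, scope: FitnessScope) -> float:
    if scope is FitnessScope.TOTAL:
        return n_H + n_E
    if scope is FitnessScope.HOST_ONLY:
        return n_H
    return n_E


def stage_biased_initial(which: str) -> PopulationState:
    """Extreme (stage-biased) or mixed initial distributions.

    ``HOST`` puts the whole lineage in the host, ``ENVIRONMENT`` in the
    environment, ``MIXED`` splits it evenly — the three initial conditions
    used to probe transient effects.
    """
    table = {
        "HOST": PopulationState(n_H=1.0, n_E=0.0),
        "ENVIRONMENT": PopulationState(n_H=0.0, n_E=1.0),
        "MIXED": PopulationState(n_H=0.5, n_E=0.5),
    }
    try:
        return table[which.upper()]
    except KeyError:
        raise InvalidParameterError(
            f"unknown initial-condition bias {which!r}; expected HOST, ENVIRONMENT or MIXED"
        ) from None


def effective_growth_rate(
    traits: Traits,
    k: CompetitionMatrix,
    probe: ProbeSpec,
) -> FitnessResult:
    """Measure Λ = log(n(t_max)/n(0)) / t_max for the configured scope."""
    start = _scoped(probe.n0.n_H, probe.n0.n_E, probe.scope)
    if start <= 0:
        raise UndefinedFitnessError(
            f"scoped abundance is {start} at t=0; Λ undefined for scope {probe.scope.value}"
        )
    traj = integrate(
        traits,
        k,
        probe.n0,
        probe.t_max,
        t_eval=[0.0, probe.t_max],
        rtol=probe.rtol,
        atol=probe.atol,
    )
    if traj.log_total is not None:
        # stay in log space: immune to abundance overflow at long horizons
        u_T, p_T = float(traj.log_total[-1]), float(traj.host_fraction[-1])
        if probe.scope is FitnessScope.TOTAL:
            log_end = u_T
        elif probe.scope is FitnessScope.HOST_ONLY:
            if p_T <= 0:
                raise UndefinedFitnessError("host abundance is 0 at t_max")
            log_end = u_T + math.log(p_T)
        else:
            if p_T >= 1:
                raise UndefinedFitnessError("environment abundance is 0 at t_max")
            log_end = u_T + math.log(1.0 - p_T)
        Lam = (log_end - math.log(start)) / probe.t_max
        return FitnessResult(Lambda=Lam, trajectory=traj, probe=probe)

    end = _scoped(float(traj.n_H[-1]), float(traj.n_E[-1]), probe.scope)
    if end <= 0:
        raise UndefinedFitnessError(
            f"scoped abundance is {end} at t_max; Λ undefined for scope {probe.scope.value}"
        )
    Lam = math.log(end / start) / probe.t_max
    return FitnessResult(Lambda=Lam, trajectory=traj, probe=probe)


def _perturbed(traits: Traits, trait: str, step: float) -> Traits:
    return replace(traits, **{trait: getattr(traits, trait) + step})


def finite_difference_sensitivities(
    traits: Traits,
    k: CompetitionMatrix,
    probe: ProbeSpec,
    *,
    refine: bool = True,
    central: bool = False,
) -> SensitivityVector:
    """Selection gradient of Λ by trait perturbation.

    Forward differences are the default estimator; ``central=True`` gives
    the O(δ²) cross-check variant used in validation.  With ``refine`` the
    step is halved until two successive estimates agree to
    ``probe.delta_refinement``; failure to converge within
    ``probe.max_halvings`` is flagged on the result, never silent.

    At a boundary where a migration rate is exactly zero the perturbation
    is applied in the admissible (positive) direction only — which is
    already what a forward step does, and central differencing falls back
    to a forward step there.
    """
    base = effective_growth_rate(traits, k, probe).Lambda

    comps: dict[str, float] = {}
    all_converged = True
    for trait in TRAIT_NAMES:
        at_boundary = trait in ("m_E", "m_H") and getattr(traits, trait) == 0.0

        def estimate(step: float) -> float:
            if central and not at_boundary:
                up = effective_growth_rate(_perturbed(traits, trait, step), k, probe).Lambda
                dn = effective_growth_rate(_perturbed(traits, trait, -step), k, probe).Lambda
                return (up - dn) / (2.0 * step)
            up = effective_growth_rate(_perturbed(traits, trait, step), k, probe).Lambda
            return (up - base) / step

        step = probe.delta_x
        value = estimate(step)
        if refine:
            converged = False
            for _ in range(probe.max_halvings):
                step *= 0.5
                new = estimate(step)
                if abs(new - value) < probe.delta_refinement:
                    value = new
                    converged = True
                    break
                value = new
            all_converged = all_converged and converged
        comps[trait] = value

    return SensitivityVector(
        s_rE=comps["r_E"],
        s_rH=comps["r_H"],
        s_mE=comps["m_E"],
        s_mH=comps["m_H"],
        method="finite_difference",
        probe=probe,
        converged=all_converged if refine else None,
    )
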