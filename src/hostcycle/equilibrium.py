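"""Steady states of the two-compartment model per competition scenario.

A "positive equilibrium" means both compartments strictly occupied.  The
limit cases behave very differently:

* HOST_ONLY (competition in the slow compartment): the environment eq.
  forces n_E* = m_E n_H* / (m_H - r_E), so a positive equilibrium requires
  m_H > r_E — if migration out of the environment is slower than
  replication there, the environment keeps growing exponentially and the
  host share becomes negligible.  Closed form:

      n_H* = (r_H - m_E + m_H m_E / (m_H - r_E)) / k_HH,
      n_E* = m_E n_H* / (m_H - r_E).

* ENV_ONLY: the index-swapped expressions, existence requires m_E > r_H
  (plus positivity).

* GLOBAL (all k_ij = k): competition subtracts the same crowding term from
  both compartments, so the compartment split at equilibrium is the stable
  distribution of the linear model and the total solves λN - kN² = 0:
  N* = λ/k, existing iff λ > 0.

* EQUAL_PER_COMPARTMENT and CUSTOM: no closed form is used; the positive
  root is found numerically and verified by a residual check.

Sensitivities of the total equilibrium abundance N* = n_H* + n_E* are the
long-time limits of the finite-horizon strategy contours.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize

from .model_core import (
    CompetitionMatrix,
    InvalidParameterError,
    PopulationState,
    Scenario,
    Traits,
    rhs,
)
from .linear_model import (
    SensitivityVector,
    TRAIT_NAMES,
    analytic_sensitivities,
    dominant_growth_rate,
    stable_distribution,
)

__all__ = [
    "EquilibriumResult",
    "equilibrium",
    "existence_threshold",
    "equilibrium_sensitivities",
]

_RESIDUAL_TOL = 1e-9


class RootFindError(RuntimeError):
    """Equilibrium root-finding did not converge; existence is unknown."""


class NoEquilibriumError(ValueError):
    """The requested quantity needs an equilibrium that does not exist."""


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of an equilibrium computation.

    ``exists`` is True only for strictly positive steady states; boundary
    fixed points with an empty compartment are reported as absent, with a
    human-readable ``note``.  ``stable`` is the sign test on the Jacobian's
    eigenvalue real parts at the state.
    """

    exists: bool
    state: Optional[PopulationState]
    method: str  # "closed_form" or "root_find"
    residual: float
    stable: Optional[bool] = None
    note: str = ""

    @property
    def total(self) -> float:
        if not self.exists:
            raise NoEquilibriumError(self.note or "no positive equilibrium")
        return self.state.total

    def as_dict(self) -> dict:
        d: dict = {"exists": self.exists, "method": self.method, "residual": self.residual}
        if self.state is not None:
            d["n_H"] = self.state.n_H
            d["n_E"] = self.state.n_E
        if self.stable is not None:
            d["stable"] = self.stable
        if self.note:
            d["note"] = self.note
        return d


def _jacobian(n: tuple[float, float], traits: Traits, k: CompetitionMatrix) -> np.ndarray:
    n_H, n_E = n
    return np.array(
        [
            [
                traits.r_H - traits.m_E - k.k_HE * n_E - 2.0 * k.k_HH * n_H,
                traits.m_H - k.k_HE * n_H,
            ],
            [
                traits.m_E - k.k_EH * n_E,
                traits.r_E - traits.m_H - k.k_EH * n_H - 2.0 * k.k_EE * n_E,
            ],
        ]
    )


def _finish(
    n_H: float, n_E: float, traits: Traits, k: CompetitionMatrix, method: str
) -> EquilibriumResult:
    res = rhs((n_H, n_E), traits, k)
    residual = max(abs(res[0]), abs(res[1]))
    if n_H <= 0 or n_E <= 0:
        return EquilibriumResult(
            False, None, method, residual, note="steady state not strictly positive"
        )
    eigs = np.linalg.eigvals(_jacobian((n_H, n_E), traits, k))
    return EquilibriumResult(
        True,
        PopulationState(n_H=n_H, n_E=n_E),
        method,
        residual,
        stable=bool(np.all(eigs.real < 0)),
    )


def _host_only_closed_form(traits: Traits, k_HH: float) -> tuple[float, float] | None:
    d = traits.m_H - traits.r_E
    if d <= 0:
        return None
    n_H = (traits.r_H - traits.m_E + traits.m_H * traits.m_E / d) / k_HH
    n_E = traits.m_E * n_H / d
    return n_H, n_E


def _root_find(
    traits: Traits,
    k: CompetitionMatrix,
    seed: Optional[int] = None,
) -> EquilibriumResult:
    k_eff = max(k.k_HH, k.k_HE, k.k_EH, k.k_EE)
    scale = max(abs(traits.r_E), abs(traits.r_H), 1e-3) / k_eff
    guesses = [np.array([scale, scale])]
    rng = np.random.default_rng(0 if seed is None else seed)
    guesses += [scale * rng.uniform(0.05, 3.0, size=2) for _ in range(3)]

    fun = lambda y: np.array(rhs((y[0], y[1]), traits, k))
    jac = lambda y: _jacobian((y[0], y[1]), traits, k)
    for guess in guesses:
        sol = optimize.root(fun, guess, jac=jac, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        n_H, n_E = sol.x
        if max(abs(v) for v in fun(sol.x)) > _RESIDUAL_TOL:
            continue
        if n_H > 0 and n_E > 0:
            return _finish(float(n_H), float(n_E), traits, k, "root_find")
    # No positive root found from any start: distinguish "converged to a
    # boundary/negative state" from outright failure.
    sol = optimize.root(fun, guesses[0], jac=jac, method="hybr", tol=1e-13)
    if sol.success:
        return _finish(float(sol.x[0]), float(sol.x[1]), traits, k, "root_find")
    raise RootFindError(
        f"equilibrium root-finding did not converge for {traits}, {k}; existence unknown"
    )


def equilibrium(
    traits: Traits,
    k: CompetitionMatrix,
    *,
    seed: Optional[int] = None,
) -> EquilibriumResult:
    """Positive steady state of the dynamics under the given competition.

    Closed forms are used for the HOST_ONLY / ENV_ONLY / GLOBAL limit
    cases; EQUAL_PER_COMPARTMENT and CUSTOM use a Newton-type root find
    from a positive initial guess (with seeded random restarts).  Every
    reported state satisfies ``max |dn/dt| < 1e-9``.
    """
    s = k.scenario
    if k.is_zero:
        return EquilibriumResult(
            False,
            None,
            "closed_form",
            0.0,
            note="no competition: growth is unconstrained, no positive equilibrium",
        )
    if s is Scenario.GLOBAL:
        lam = dominant_growth_rate(traits)
        if lam <= 0:
            return EquilibriumResult(
                False, None, "closed_form", 0.0, note=f"dominant growth rate {lam} <= 0"
            )
        total = lam / k.k_HH
        p = stable_distribution(traits)
        return _finish(total * p, total * (1.0 - p), traits, k, "closed_form")
    if s is Scenario.HOST_ONLY:
        cf = _host_only_closed_form(traits, k.k_HH)
        if cf is None:
            return EquilibriumResult(
                False,
                None,
                "closed_form",
                0.0,
                note="m_H <= r_E: environment grows unconstrained, no positive equilibrium",
            )
        return _finish(cf[0], cf[1], traits, k, "closed_form")
    if s is Scenario.ENV_ONLY:
        swapped = equilibrium(traits.swapped(), k.swapped(), seed=seed)
        if not swapped.exists:
            return replace(
                swapped,
                note=swapped.note.replace("m_H <= r_E", "m_E <= r_H").replace(
                    "environment grows", "host grows"
                ),
            )
        return _finish(
            swapped.state.n_E, swapped.state.n_H, traits, k, "closed_form"
        )
    return _root_find(traits, k, seed=seed)


def existence_threshold(
    traits: Traits,
    scenario: Scenario | str,
    varying_trait: str,
    *,
    lo: float = 0.0,
    hi: float = 5.0,
    k_intensity: float = 1.0,
    xtol: float = 1e-6,
) -> float:
    """Critical migration rate at which a positive equilibrium appears.

    Bisects the ``exists`` flag of :func:`equilibrium` over
    ``varying_trait`` in ``[lo, hi]``.  For HOST_ONLY varying ``m_H`` the
    analytic boundary is ``r_E``; for ENV_ONLY varying ``m_E`` it is
    ``r_H``.
    """
    scenario = Scenario(scenario)
    if scenario not in (Scenario.HOST_ONLY, Scenario.ENV_ONLY):
        raise InvalidParameterError(
            f"no existence threshold for scenario {scenario.value!r}: "
            "a positive equilibrium exists whenever growth is bounded"
        )
    if varying_trait not in ("m_E", "m_H"):
        raise InvalidParameterError(f"varying trait must be a migration rate, got {varying_trait!r}")

    from .model_core import scenario_matrix

    k = scenario_matrix(scenario, k_intensity)

    def exists_at(value: float) -> bool:
        return equilibrium(replace(traits, **{varying_trait: value}), k).exists

    lo_exists, hi_exists = exists_at(lo), exists_at(hi)
    if lo_exists == hi_exists:
        raise InvalidParameterError(
            f"no existence change in [{lo}, {hi}] for {varying_trait}: "
            f"exists={lo_exists} at both ends"
        )
    a, b = lo, hi
    while b - a > xtol:
        mid = 0.5 * (a + b)
        if exists_at(mid) == lo_exists:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def _closed_form_total_sensitivities_host_only(
    traits: Traits, k_HH: float
) -> dict[str, float]:
    """Hand-derived partials of N* = n_H*(1 + m_E/d), d = m_H - r_E > 0."""
    d = traits.m_H - traits.r_E
    m_E, m_H = traits.m_E, traits.m_H
    n_H = (traits.r_H - m_E + m_H * m_E / d) / k_HH
    f = 1.0 + m_E / d
    dn_H = {
        "r_E": (m_E * m_H / d**2) / k_HH,
        "r_H": 1.0 / k_HH,
        "m_E": (-1.0 + m_H / d) / k_HH,
        "m_H": (-m_E * traits.r_E / d**2) / k_HH,
    }
    df = {
        "r_E": m_E / d**2,
        "r_H": 0.0,
        "m_E": 1.0 / d,
        "m_H": -m_E / d**2,
    }
    return {x: dn_H[x] * f + n_H * df[x] for x in TRAIT_NAMES}


def equilibrium_sensitivities(
    traits: Traits,
    k: CompetitionMatrix,
    *,
    delta: float = 1e-6,
    seed: Optional[int] = None,
) -> SensitivityVector:
    """Selection gradient of the total equilibrium abundance N* = n_H* + n_E*.

    Closed-form partials for HOST_ONLY / ENV_ONLY / GLOBAL; central finite
    differences of the root-found equilibrium otherwise.  These are the
    long-horizon limits of the finite-probing-time strategy contours.
    """
    base = equilibrium(traits, k, seed=seed)
    if not base.exists:
        raise NoEquilibriumError(
            base.note or "equilibrium sensitivities need a positive equilibrium"
        )
    s = k.scenario
    if s is Scenario.GLOBAL:
        lam_s = analytic_sensitivities(traits)
        return SensitivityVector(
            s_rE=lam_s.s_rE / k.k_HH,
            s_rH=lam_s.s_rH / k.k_HH,
            s_mE=lam_s.s_mE / k.k_HH,
            s_mH=lam_s.s_mH / k.k_HH,
            method="analytic",
        )
    if s is Scenario.HOST_ONLY:
        if traits.m_H - traits.r_E < 1e-9:
            raise NoEquilibriumError(
                "at the existence boundary m_H = r_E the derivative diverges"
            )
        p = _closed_form_total_sensitivities_host_only(traits, k.k_HH)
        return SensitivityVector(
            s_rE=p["r_E"], s_rH=p["r_H"], s_mE=p["m_E"], s_mH=p["m_H"], method="analytic"
        )
    if s is Scenario.ENV_ONLY:
        sw = _closed_form_total_sensitivities_host_only(traits.swapped(), k.k_EE)
        # map the swapped partials back: x-partial here = swapped-partial of swap(x)
        return SensitivityVector(
            s_rE=sw["r_H"], s_rH=sw["r_E"], s_mE=sw["m_H"], s_mH=sw["m_E"], method="analytic"
        )

    # generic: central differences of the root-found total
    comps: dict[str, float] = {}
    for trait in TRAIT_NAMES:
        x0 = getattr(traits, trait)
        lo_step = delta if (trait not in ("m_E", "m_H") or x0 - delta >= 0) else 0.0
        up = equilibrium(replace(traits, **{trait: x0 + delta}), k, seed=seed)
        dn = (
            equilibrium(replace(traits, **{trait: x0 - lo_step}), k, seed=seed)
            if lo_step
            else base
        )
        if not (up.exists and dn.exists):
            raise NoEquilibriumError(
                f"equilibrium disappears under perturbation of {trait}; "
                "sensitivity undefined at the existence boundary"
            )
        comps[trait] = (up.total - dn.total) / (delta + lo_step)
    return SensitivityVector(
        s_rE=comps["r_E"],
        s_rH=comps["r_H"],
        s_mE=comps["m_E"],
        s_mH=comps["m_H"],
        method="finite_difference",
    )
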