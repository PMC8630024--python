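"""Core parameter types and the nonlinear two-compartment dynamics.

A single microbial lineage lives in two communicating habitats: a host
(abundance ``n_H``) and an environment (abundance ``n_E``).  Microbes
replicate clonally at net rates ``r_H`` and ``r_E`` (which may be negative),
migrate host -> environment at rate ``m_E`` and environment -> host at rate
``m_H``, and experience intraspecific competition for space with intensity
``k_ij`` (pressure felt in compartment ``i`` from the abundance in
compartment ``j``)::

    dn_H/dt = r_H n_H + m_H n_E - m_E n_H - k_HE n_H n_E - k_HH n_H^2
    dn_E/dt = r_E n_E + m_E n_H - m_H n_E - k_EH n_E n_H - k_EE n_E^2

All rates are constant in time.  Time is conventionally measured in units
of ``1/r_E`` (the presets set ``r_E = 1``), but the core never enforces
that scaling: host and environment are mathematically interchangeable
under a relabeling of indices, and keeping the symmetry intact is part of
the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Traits",
    "Scenario",
    "CompetitionMatrix",
    "PopulationState",
    "Trajectory",
    "scenario_matrix",
    "rhs",
    "integrate",
]


class InvalidParameterError(ValueError):
    """A model parameter or state violates its invariants."""


class OverflowIntegrationError(ArithmeticError):
    """Abundances overflowed during integration and no guard was active."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class Traits:
    """The four life-history rates defining a phenotype.

    Parameters
    ----------
    r_E : float
        Net replication rate in the environment (1/time). May be negative.
    r_H : float
        Net replication rate in the host (1/time). May be negative.
    m_E : float
        Migration rate host -> environment (1/time). Nonnegative.
    m_H : float
        Migration rate environment -> host (1/time). Nonnegative.
    """

    r_E: float
    r_H: float
    m_E: float
    m_H: float

    def __post_init__(self) -> None:
        for name in ("r_E", "r_H", "m_E", "m_H"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.m_E < 0 or self.m_H < 0:
            raise InvalidParameterError(
                f"migration rates must be nonnegative, got m_E={self.m_E}, m_H={self.m_H}"
            )

    def swapped(self) -> "Traits":
        """The relabeled phenotype with host and environment exchanged."""
        return Traits(r_E=self.r_H, r_H=self.r_E, m_E=self.m_H, m_H=self.m_E)

    def as_dict(self) -> dict[str, float]:
        return {"r_E": self.r_E, "r_H": self.r_H, "m_E": self.m_E, "m_H": self.m_H}


class Scenario(str, Enum):
    """Named competition patterns studied as limit cases."""

    NONE = "none"
    GLOBAL = "global"
    HOST_ONLY = "host_only"
    ENV_ONLY = "env_only"
    EQUAL_PER_COMPARTMENT = "equal_per_compartment"
    CUSTOM = "custom"


@dataclass(frozen=True)
class CompetitionMatrix:
    """Pairwise competition intensities ``k_ij`` plus a named scenario.

    ``k_ij`` is the per-capita rate at which microbes in compartment *i*
    lose out to the abundance in compartment *j* (units 1/(abundance*time)).
    """

    k_HH: float = 0.0
    k_HE: float = 0.0
    k_EH: float = 0.0
    k_EE: float = 0.0
    scenario: Scenario = Scenario.CUSTOM

    def __post_init__(self) -> None:
        for name in ("k_HH", "k_HE", "k_EH", "k_EE"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise InvalidParameterError(f"{name} must be nonnegative, got {v}")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        self._check_scenario()

    def _check_scenario(self) -> None:
        s, k = self.scenario, (self.k_HH, self.k_HE, self.k_EH, self.k_EE)
        ok = True
        if s is Scenario.NONE:
            ok = all(v == 0 for v in k)
        elif s is Scenario.GLOBAL:
            ok = len(set(k)) == 1
        elif s is Scenario.HOST_ONLY:
            ok = self.k_HE == self.k_EH == self.k_EE == 0
        elif s is Scenario.ENV_ONLY:
            ok = self.k_HE == self.k_EH == self.k_HH == 0
        elif s is Scenario.EQUAL_PER_COMPARTMENT:
            ok = self.k_HH == self.k_EE and self.k_HE == self.k_EH == 0
        if not ok:
            raise InvalidParameterError(
                f"competition intensities {k} inconsistent with scenario {s.value!r}"
            )

    @property
    def is_zero(self) -> bool:
        return self.k_HH == self.k_HE == self.k_EH == self.k_EE == 0

    def swapped(self) -> "CompetitionMatrix":
        """Competition matrix under the host/environment relabeling."""
        swap = {
            Scenario.HOST_ONLY: Scenario.ENV_ONLY,
            Scenario.ENV_ONLY: Scenario.HOST_ONLY,
        }
        return CompetitionMatrix(
            k_HH=self.k_EE,
            k_HE=self.k_EH,
            k_EH=self.k_HE,
            k_EE=self.k_HH,
            scenario=swap.get(self.scenario, self.scenario),
        )

    def as_dict(self) -> dict[str, float | str]:
        return {
            "k_HH": self.k_HH,
            "k_HE": self.k_HE,
            "k_EH": self.k_EH,
            "k_EE": self.k_EE,
            "scenario": self.scenario.value,
        }


def scenario_matrix(scenario: Scenario | str, k: float = 0.0) -> CompetitionMatrix:
    """Build the named competition pattern with intensity ``k``.

    ``NONE`` ignores ``k``; ``GLOBAL`` sets all four entries to ``k``;
    ``HOST_ONLY``/``ENV_ONLY`` set only the within-compartment term;
    ``EQUAL_PER_COMPARTMENT`` sets both within-compartment terms and no
    cross terms.
    """
    scenario = Scenario(scenario)
    if k < 0:
        raise InvalidParameterError(f"competition intensity must be >= 0, got {k}")
    if scenario is Scenario.NONE:
        return CompetitionMatrix(scenario=Scenario.NONE)
    if scenario is Scenario.GLOBAL:
        return CompetitionMatrix(k, k, k, k, scenario=Scenario.GLOBAL)
    if scenario is Scenario.HOST_ONLY:
        return CompetitionMatrix(k_HH=k, scenario=Scenario.HOST_ONLY)
    if scenario is Scenario.ENV_ONLY:
        return CompetitionMatrix(k_EE=k, scenario=Scenario.ENV_ONLY)
    if scenario is Scenario.EQUAL_PER_COMPARTMENT:
        return CompetitionMatrix(
            k_HH=k, k_EE=k, scenario=Scenario.EQUAL_PER_COMPARTMENT
        )
    raise InvalidParameterError(
        "CUSTOM pattern has no single intensity; construct CompetitionMatrix directly"
    )


@dataclass(frozen=True)
class PopulationState:
    """Abundances in the two compartments at one instant."""

    n_H: float
    n_E: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_H", "n_E", "t"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.n_H < 0 or self.n_E < 0:
            raise InvalidParameterError(
                f"abundances must be nonnegative, got n_H={self.n_H}, n_E={self.n_E}"
            )

    @property
    def total(self) -> float:
        return self.n_H + self.n_E

    def swapped(self) -> "PopulationState":
        return PopulationState(n_H=self.n_E, n_E=self.n_H, t=self.t)


@dataclass
class Trajectory:
    """A solved trajectory: abundances on a strictly increasing time grid.

    For unconstrained (k = 0) runs integrated in log space the raw
    abundances may exceed the floating-point range even though the solve
    itself is exact; ``log_total`` and ``host_fraction`` then carry the
    full-precision answer and accessing ``n_H``/``n_E`` raises instead of
    silently returning infinities.
    """

    t: np.ndarray
    rtol: float
    atol: float
    method: str
    log_transformed: bool = False
    clamped_points: int = 0
    _n_H: np.ndarray | None = None
    _n_E: np.ndarray | None = None
    log_total: np.ndarray | None = None
    host_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self._n_H is not None:
            self._n_H = np.asarray(self._n_H, dtype=float)
            self._n_E = np.asarray(self._n_E, dtype=float)
        if not np.all(np.diff(self.t) > 0):
            raise InvalidParameterError("trajectory times must be strictly increasing")

    @property
    def n_H(self) -> np.ndarray:
        if self._n_H is None:
            raise OverflowIntegrationError(
                "raw abundances exceed the floating-point range; "
                "use log_total / host_fraction"
            )
        return self._n_H

    @property
    def n_E(self) -> np.ndarray:
        if self._n_E is None:
            raise OverflowIntegrationError(
                "raw abundances exceed the floating-point range; "
                "use log_total / host_fraction"
            )
        return self._n_E

    @property
    def total(self) -> np.ndarray:
        return self.n_H + self.n_E

    def state(self, index: int = -1) -> PopulationState:
        return PopulationState(
            n_H=float(self.n_H[index]), n_E=float(self.n_E[index]), t=float(self.t[index])
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation with columns ``t, n_H, n_E``."""
        return pd.DataFrame({"t": self.t, "n_H": self.n_H, "n_E": self.n_E})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rhs(
    state: PopulationState | tuple[float, float],
    traits: Traits,
    k: CompetitionMatrix,
) -> tuple[float, float]:
    """Time derivatives ``(dn_H/dt, dn_E/dt)`` of the two-compartment model."""
    if isinstance(state, PopulationState):
        n_H, n_E = state.n_H, state.n_E
    else:
        n_H, n_E = state
        if not (math.isfinite(n_H) and math.isfinite(n_E)):
            raise InvalidParameterError(f"non-finite abundances ({n_H}, {n_E})")
    dn_H = (
        traits.r_H * n_H
        + traits.m_H * n_E
        - traits.m_E * n_H
        - k.k_HE * n_H * n_E
        - k.k_HH * n_H * n_H
    )
    dn_E = (
        traits.r_E * n_E
        + traits.m_E * n_H
        - traits.m_H * n_E
        - k.k_EH * n_E * n_H
        - k.k_EE * n_E * n_E
    )
    return dn_H, dn_E


def _rhs_vec(traits: Traits, k: CompetitionMatrix) -> Callable[[float, np.ndarray], np.ndarray]:
    r_H, r_E, m_E, m_H = traits.r_H, traits.r_E, traits.m_E, traits.m_H
    k_HH, k_HE, k_EH, k_EE = k.k_HH, k.k_HE, k.k_EH, k.k_EE

    def f(t: float, y: np.ndarray) -> np.ndarray:
        n_H, n_E = y
        return np.array(
            [
                r_H * n_H + m_H * n_E - m_E * n_H - k_HE * n_H * n_E - k_HH * n_H * n_H,
                r_E * n_E + m_E * n_H - m_H * n_E - k_EH * n_E * n_H - k_EE * n_E * n_E,
            ]
        )

    return f


def _rhs_log_fraction(traits: Traits) -> Callable[[float, np.ndarray], np.ndarray]:
    """Dynamics of (log total, host fraction) for the competition-free model.

    With k = 0 the system is linear, so the total abundance N grows at a
    rate set by the current host fraction p while p itself follows an
    autonomous equation.  Integrating (u, p) = (log N, n_H/N) avoids
    floating-point overflow at long horizons.
    """
    a11 = traits.r_H - traits.m_E
    a12 = traits.m_H
    a21 = traits.m_E
    a22 = traits.r_E - traits.m_H

    def f(t: float, y: np.ndarray) -> np.ndarray:
        _, p = y
        q = 1.0 - p
        g_H = a11 * p + a12 * q  # d n_H/dt per unit total
        g_E = a21 * p + a22 * q
        du = g_H + g_E
        dp = g_H - p * du
        return np.array([du, dp])

    return f


def integrate(
    traits: Traits,
    k: CompetitionMatrix,
    n0: PopulationState,
    t_max: float,
    *,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    method: str = "DOP853",
    log_transform: bool | None = None,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the two-compartment dynamics from ``n0`` up to ``t_max``.

    Parameters
    ----------
    log_transform
        Integrate (log total abundance, host fraction) instead of raw
        abundances.  Only valid for the competition-free model with a
        strictly positive total; default: on exactly when all ``k_ij = 0``
        (unconstrained growth can overflow floats at long horizons, the
        linear change of variables cannot).
    t_eval
        Optional explicit output times (must include values in
        ``[0, t_max]``); defaults to the solver's accepted steps.

    Raises
    ------
    OverflowIntegrationError
        If abundances leave the floating-point range and the log-transform
        guard is off.  Overflow is never silently clipped.
    """
    if t_max <= 0:
        raise InvalidParameterError(f"t_max must be > 0, got {t_max}")
    if log_transform is None:
        log_transform = k.is_zero
    if log_transform and not k.is_zero:
        raise InvalidParameterError("log_transform requires all k_ij = 0")
    if log_transform and n0.total <= 0:
        raise InvalidParameterError("log_transform requires a positive total abundance")

    if log_transform:
        y0 = np.array([math.log(n0.total), n0.n_H / n0.total])
        fun = _rhs_log_fraction(traits)
    else:
        y0 = np.array([n0.n_H, n0.n_E])
        fun = _rhs_vec(traits, k)

    sol = solve_ivp(
        fun,
        (0.0, float(t_max)),
        y0,
        method=method,
        t_eval=None if t_eval is None else np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        dense_output=False,
    )
    if not sol.success:
        raise OverflowIntegrationError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0.0}: {sol.message}"
        )

    t = sol.t
    if t[0] == t[-1]:
        raise OverflowIntegrationError("degenerate trajectory: no time elapsed")
    keep = np.concatenate(([True], np.diff(t) > 0))

    if log_transform:
        u, p = sol.y[:, keep]
        p = np.clip(p, 0.0, 1.0)  # round-off only; the fraction ODE preserves [0,1]
        n_H = n_E = None
        if np.max(u) < math.log(np.finfo(float).max) - 1.0:
            total = np.exp(u)
            n_H = total * p
            n_E = total * (1.0 - p)
        return Trajectory(
            t=t[keep],
            rtol=rtol,
            atol=atol,
            method=method,
            log_transformed=True,
            _n_H=n_H,
            _n_E=n_E,
            log_total=u,
            host_fraction=p,
        )

    n_H, n_E = sol.y[:, keep]
    if not (np.all(np.isfinite(n_H)) and np.all(np.isfinite(n_E))):
        raise OverflowIntegrationError(
            "abundance overflow; rerun with log_transform=True (k = 0 only) "
            "or a shorter horizon"
        )
    # Round-off can push abundances marginally below zero; clamp only
    # within the absolute tolerance, anything larger is a solver failure.
    clamped = 0
    for arr in (n_H, n_E):
        neg = arr < 0
        if np.any(neg):
            if np.min(arr[neg]) < -atol:
                raise OverflowIntegrationError(
                    f"negative abundance {np.min(arr[neg])} beyond tolerance {atol}"
                )
            clamped += int(np.count_nonzero(neg))
            arr[neg] = 0.0

    return Trajectory(
        t=t[keep],
        rtol=rtol,
        atol=atol,
        method=method,
        log_transformed=False,
        clamped_points=clamped,
        _n_H=n_H,
        _n_E=n_E,
    )
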