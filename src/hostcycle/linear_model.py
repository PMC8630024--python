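"""Competition-free theory: projection matrix, dominant eigenvalue, and
analytic sensitivities.

With all competition intensities zero the dynamics are linear,

    d/dt (n_H, n_E)^T = A (n_H, n_E)^T,
    A = [[r_H - m_E, m_H], [m_E, r_E - m_H]],

and the dominant eigenvalue λ of the projection matrix A is the asymptotic
overall growth rate of the lineage — the fitness measure that integrates
replication in both compartments with migration between them.  Writing
T = tr A and D = det A,

    λ = (T + sqrt(T² - 4D)) / 2,

which is always real for nonnegative migration rates because the
discriminant equals (a11 - a22)² + 4 m_E m_H ≥ 0.

The selection gradient is the vector of sensitivities s_i = ∂λ/∂x_i, one
per life-history trait.  They are computed here in closed form by the
chain rule through T and D, and cross-validated in the test suite against
central finite differences and the eigenvector perturbation formula
(l·∂A/∂x·w)/(l·w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import InvalidParameterError, Traits

__all__ = [
    "SensitivityVector",
    "projection_matrix",
    "dominant_growth_rate",
    "lambda_sym",
    "stable_distribution",
    "analytic_sensitivities",
    "landscape_frame",
]

TRAIT_NAMES = ("r_E", "r_H", "m_E", "m_H")


class DegenerateEigenvalueError(ArithmeticError):
    """The dominant eigenvalue is repeated; the requested quantity is undefined."""


@dataclass(frozen=True)
class SensitivityVector:
    """Selection-gradient components: one signed partial per trait.

    ``method`` records provenance — ``"analytic"`` for closed-form partials
    of the dominant eigenvalue, ``"finite_difference"`` for perturbations of
    a finite-horizon or equilibrium fitness measure (``probe`` then points
    to the measurement protocol used).
    """

    s_rE: float
    s_rH: float
    s_mE: float
    s_mH: float
    method: str
    probe: Optional[object] = None
    converged: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("s_rE", "s_rH", "s_mE", "s_mH"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, v)
        if self.method not in ("analytic", "finite_difference"):
            raise InvalidParameterError(f"unknown method tag {self.method!r}")

    def __getitem__(self, trait: str) -> float:
        try:
            return getattr(self, "s_" + trait.replace("_", ""))
        except AttributeError:
            raise KeyError(trait) from None

    def as_dict(self) -> dict[str, float]:
        return {
            "s_rE": self.s_rE,
            "s_rH": self.s_rH,
            "s_mE": self.s_mE,
            "s_mH": self.s_mH,
        }


def projection_matrix(traits: Traits) -> np.ndarray:
    """The 2x2 linear-dynamics matrix A (host row first)."""
    return np.array(
        [
            [traits.r_H - traits.m_E, traits.m_H],
            [traits.m_E, traits.r_E - traits.m_H],
        ]
    )


def _trace_det_disc(traits: Traits) -> tuple[float, float, float]:
    T = traits.r_E + traits.r_H - traits.m_E - traits.m_H
    D = (
        traits.r_E * traits.r_H
        - traits.r_E * traits.m_E
        - traits.r_H * traits.m_H
    )
    disc = T * T - 4.0 * D
    return T, D, disc


def dominant_growth_rate(traits: Traits) -> float:
    """Asymptotic overall growth rate λ (closed form).

    Equals the larger eigenvalue of :func:`projection_matrix`; real for all
    nonnegative migration rates.
    """
    T, _, disc = _trace_det_disc(traits)
    if disc < 0:
        # only reachable through catastrophic cancellation; the exact
        # discriminant (a11-a22)^2 + 4 m_E m_H is nonnegative
        if disc < -1e-12 * max(1.0, T * T):
            raise ArithmeticError(f"negative discriminant {disc} for {traits}")
        disc = 0.0
    return 0.5 * (T + math.sqrt(disc))


def lambda_sym(r_H: float, m: float) -> float:
    """Overall growth rate for symmetric migration with r_E = 1 scaling time.

    λ_sym(r_H, m) = (1 + r_H - 2m + sqrt((1 - r_H)² + 4m²)) / 2, the
    specialization of the dominant eigenvalue to m_E = m_H = m in units of
    the environmental replication rate.
    """
    if m < 0:
        raise InvalidParameterError(f"migration rate must be >= 0, got {m}")
    return 0.5 * (1.0 + r_H - 2.0 * m + math.sqrt((1.0 - r_H) ** 2 + 4.0 * m * m))


def stable_distribution(traits: Traits) -> float:
    """Asymptotic fraction of the lineage found in the host.

    The dominant right eigenvector w of the projection matrix gives the
    stable split of microbes between compartments; this returns
    w_H / (w_H + w_E).  Undefined when the dominant eigenvalue is repeated
    (decoupled compartments with equal rates).
    """
    T, _, disc = _trace_det_disc(traits)
    lam = dominant_growth_rate(traits)
    if disc <= 0:
        raise DegenerateEigenvalueError(
            "repeated dominant eigenvalue: stable distribution is non-unique"
        )
    a11 = traits.r_H - traits.m_E
    a22 = traits.r_E - traits.m_H
    # A w = λ w with w = (w_H, w_E): use whichever row is better conditioned
    if traits.m_H > 0 or traits.m_E > 0:
        if abs(lam - a11) >= abs(lam - a22):
            w_H, w_E = traits.m_H, lam - a11
        else:
            w_H, w_E = lam - a22, traits.m_E
    else:
        # decoupled compartments with distinct rates: all mass in the faster one
        w_H, w_E = (1.0, 0.0) if a11 > a22 else (0.0, 1.0)
    s = w_H + w_E
    if s == 0:
        raise DegenerateEigenvalueError("degenerate eigenvector")
    return float(w_H / s)


def analytic_sensitivities(traits: Traits) -> SensitivityVector:
    """Closed-form selection gradient ∂λ/∂(r_E, r_H, m_E, m_H).

    Differentiates λ = (T + sqrt(T² - 4D))/2 through the trace and
    determinant:

        ∂λ/∂x = (∂T/∂x + (T ∂T/∂x - 2 ∂D/∂x) / sqrt(T² - 4D)) / 2.

    Raises at the non-differentiable locus where the discriminant vanishes
    (the two eigenvalues collide and λ has a corner there).
    """
    T, _, disc = _trace_det_disc(traits)
    if disc <= 0:
        raise DegenerateEigenvalueError(
            "discriminant is zero: λ is not differentiable at an eigenvalue collision"
        )
    root = math.sqrt(disc)
    # (dT/dx, dD/dx) per trait
    partials = {
        "r_E": (1.0, traits.r_H - traits.m_E),
        "r_H": (1.0, traits.r_E - traits.m_H),
        "m_E": (-1.0, -traits.r_E),
        "m_H": (-1.0, -traits.r_H),
    }
    s = {
        name: 0.5 * (dT + (T * dT - 2.0 * dD) / root)
        for name, (dT, dD) in partials.items()
    }
    return SensitivityVector(
        s_rE=s["r_E"], s_rH=s["r_H"], s_mE=s["m_E"], s_mH=s["m_H"], method="analytic"
    )


def landscape_frame(
    r_H_values: np.ndarray,
    m_values: np.ndarray,
    r_E: float = 1.0,
) -> pd.DataFrame:
    """Tidy λ/sensitivity landscape over a symmetric-migration grid.

    One row per (r_H, m) with columns ``r_H, m, lambda, s_rE, s_rH, s_mE,
    s_mH`` — the export format for growth-rate maps.
    """
    rows = []
    for r_H in np.asarray(r_H_values, dtype=float):
        for m in np.asarray(m_values, dtype=float):
            tr = Traits(r_E=r_E, r_H=float(r_H), m_E=float(m), m_H=float(m))
            s = analytic_sensitivities(tr)
            rows.append(
                {
                    "r_H": float(r_H),
                    "m": float(m),
                    "lambda": dominant_growth_rate(tr),
                    **s.as_dict(),
                }
            )
    return pd.DataFrame(rows)
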