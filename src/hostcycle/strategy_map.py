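"""Optimal adaptive strategies over trait space, and the contours between them.

If a lineage can tune only one life-history trait at a time, the locally
optimal move is along the trait with the largest absolute sensitivity.
The replication rate in the fast compartment (``r_E``) always wins when
migration is on, so it is excluded by default: the lineage is taken to be
fully adapted to the environment already.  Among the remaining traits the
recurring strategies have canonical names:

    I   increase r_H   (catch up on within-host replication)
    II  decrease m_H   (stay longer in the fast-replicating environment)
    III increase m_E   (colonize an initially empty environment)
    IV  increase m_H   (escape a competition-limited environment)

A :class:`StrategyMap` labels every node of a two-trait grid with its
optimal strategy and carries the underlying sensitivity vectors.  The
boundary between two strategy regions is the zero-level contour of the
*deciding difference* |s_a| - |s_b|, extracted by linear interpolation on
grid-cell edges.  Contour movement with probing time and competition
intensity is quantified by the discrete Hausdorff distance to a reference
contour (typically the analytic no-competition contour, or the
equilibrium-sensitivity contour at long times).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from contourpy import contour_generator
from scipy.spatial.distance import directed_hausdorff

from .model_core import (
    CompetitionMatrix,
    InvalidParameterError,
    PopulationState,
    Scenario,
    Traits,
)
from .linear_model import SensitivityVector, analytic_sensitivities
from .effective_fitness import ProbeSpec, finite_difference_sensitivities
from .equilibrium import NoEquilibriumError, equilibrium_sensitivities

__all__ = [
    "StrategyLabel",
    "TraitGridSpec",
    "StrategyMap",
    "classify_strategy",
    "strategy_grid",
    "extract_contours",
    "contour_convergence",
    "hausdorff_distance",
    "STRATEGY_ROMAN",
]

# canonical (trait, direction) -> roman numeral
STRATEGY_ROMAN = {
    ("r_H", "increase"): "I",
    ("m_H", "decrease"): "II",
    ("m_E", "increase"): "III",
    ("m_H", "increase"): "IV",
}

# deterministic tie-break order for exact ties
_TIE_ORDER = ("r_H", "m_H", "m_E", "r_E")


class UndefinedStrategyError(ValueError):
    """All candidate sensitivities vanish; no direction is selected for."""


@dataclass(frozen=True)
class StrategyLabel:
    """One locally optimal single-trait move."""

    trait: str
    direction: str  # "increase" | "decrease"
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise InvalidParameterError(f"bad direction {self.direction!r}")

    @property
    def roman(self) -> Optional[str]:
        """Canonical name I-IV, or None for combinations outside the catalog."""
        return STRATEGY_ROMAN.get((self.trait, self.direction))

    def __str__(self) -> str:
        r = self.roman
        arrow = "+" if self.direction == "increase" else "-"
        s = f"{r} ({arrow}{self.trait})" if r else f"{arrow}{self.trait}"
        return s + (" [boundary]" if self.boundary else "")


def classify_strategy(
    s: SensitivityVector,
    excluded: frozenset[str] | set[str] = frozenset({"r_E"}),
) -> StrategyLabel:
    """Pick the non-excluded trait with maximal |sensitivity|.

    Direction is the sign of that component.  Exact ties are flagged as
    boundary points and broken deterministically in the order
    (r_H, m_H, m_E).
    """
    candidates = [t for t in _TIE_ORDER if t not in excluded]
    if not candidates:
        raise InvalidParameterError("all traits excluded from classification")
    mags = {t: abs(s[t]) for t in candidates}
    best = max(candidates, key=lambda t: mags[t])
    if mags[best] == 0.0:
        raise UndefinedStrategyError("zero selection gradient on all candidate traits")
    tied = [t for t in candidates if mags[t] == mags[best]]
    winner = next(t for t in _TIE_ORDER if t in tied)
    direction = "increase" if s[winner] > 0 else "decrease"
    return StrategyLabel(trait=winner, direction=direction, boundary=len(tied) > 1)


@dataclass(frozen=True)
class TraitGridSpec:
    """A rectangular grid over two trait axes.

    ``y_trait="m"`` with ``symmetric_migration`` means the single axis m
    drives both migration rates (m_E = m_H = m).  Fixed values supply the
    remaining traits; the presets use r_E = 1 to scale time.
    """

    x_trait: str = "r_H"
    x_range: tuple[float, float] = (-1.0, 1.0)
    x_num: int = 101
    y_trait: str = "m"
    y_range: tuple[float, float] = (0.02, 2.0)
    y_num: int = 100
    fixed: dict = field(default_factory=lambda: {"r_E": 1.0})
    symmetric_migration: bool = True

    def __post_init__(self) -> None:
        if self.x_range[0] >= self.x_range[1] or self.y_range[0] >= self.y_range[1]:
            raise InvalidParameterError("grid ranges must be non-degenerate")
        if self.x_num < 2 or self.y_num < 2:
            raise InvalidParameterError("grids need at least 2 points per axis")

    @property
    def x_values(self) -> np.ndarray:
        return np.linspace(*self.x_range, self.x_num)

    @property
    def y_values(self) -> np.ndarray:
        return np.linspace(*self.y_range, self.y_num)

    @property
    def step(self) -> tuple[float, float]:
        return (
            (self.x_range[1] - self.x_range[0]) / (self.x_num - 1),
            (self.y_range[1] - self.y_range[0]) / (self.y_num - 1),
        )

    def traits_at(self, x: float, y: float) -> Traits:
        values = {"r_E": 1.0, "r_H": 0.0, "m_E": 0.0, "m_H": 0.0}
        values.update(self.fixed)
        for trait, v in ((self.x_trait, x), (self.y_trait, y)):
            if trait == "m":
                if not self.symmetric_migration:
                    raise InvalidParameterError(
                        "axis 'm' requires symmetric_migration=True"
                    )
                values["m_E"] = values["m_H"] = v
            else:
                values[trait] = v
        return Traits(**values)

    def as_dict(self) -> dict:
        return {
            "x_trait": self.x_trait,
            "x_range": list(self.x_range),
            "x_num": self.x_num,
            "y_trait": self.y_trait,
            "y_range": list(self.y_range),
            "y_num": self.y_num,
            "fixed": dict(self.fixed),
            "symmetric_migration": self.symmetric_migration,
        }


@dataclass
class StrategyMap:
    """Labeled strategy grid plus per-point sensitivities and provenance."""

    grid: TraitGridSpec
    labels: np.ndarray  # object array of StrategyLabel or None (failed points)
    sensitivities: np.ndarray  # object array of SensitivityVector or None
    method: str
    k: CompetitionMatrix
    probe: Optional[ProbeSpec] = None
    errors: list = field(default_factory=list)

    def label_at(self, ix: int, iy: int) -> Optional[StrategyLabel]:
        return self.labels[iy, ix]

    def deciding_difference(self, pair: tuple[str, str] = ("m_H", "r_H")) -> np.ndarray:
        """|s_a| - |s_b| on the grid; NaN where a point failed."""
        a, b = pair
        out = np.full(self.labels.shape, np.nan)
        for iy in range(self.labels.shape[0]):
            for ix in range(self.labels.shape[1]):
                s = self.sensitivities[iy, ix]
                if s is not None:
                    out[iy, ix] = abs(s[a]) - abs(s[b])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV form: one row per grid node with label and sensitivities."""
        rows = []
        xs, ys = self.grid.x_values, self.grid.y_values
        for iy, y in enumerate(ys):
            for ix, x in enumerate(xs):
                lab = self.labels[iy, ix]
                s = self.sensitivities[iy, ix]
                rows.append(
                    {
                        self.grid.x_trait: x,
                        self.grid.y_trait: y,
                        "strategy": lab.roman if lab else None,
                        "trait": lab.trait if lab else None,
                        "direction": lab.direction if lab else None,
                        "boundary": lab.boundary if lab else None,
                        **(s.as_dict() if s else {}),
                    }
                )
        return pd.DataFrame(rows)

    def provenance(self) -> dict:
        return {
            "method": self.method,
            "grid": self.grid.as_dict(),
            "competition": self.k.as_dict(),
            "probe": self.probe.as_dict() if self.probe else None,
            "n_errors": len(self.errors),
        }


def strategy_grid(
    grid: TraitGridSpec,
    method: str,
    k: CompetitionMatrix,
    probe: Optional[ProbeSpec] = None,
    *,
    excluded: frozenset[str] | set[str] = frozenset({"r_E"}),
    refine: bool = False,
) -> StrategyMap:
    """Label every grid node with its locally optimal strategy.

    ``method`` selects the sensitivity backend: ``"analytic"`` (partials of
    the dominant eigenvalue; requires k = 0), ``"finite_difference"``
    (perturbations of the finite-horizon growth rate Λ; requires a probe),
    or ``"equilibrium"`` (partials of the total equilibrium abundance).
    Per-point failures (no equilibrium, undefined Λ) are recorded in
    ``errors`` and leave the node unlabeled rather than aborting the scan.

    ``refine=False`` evaluates finite differences at the probe's base step
    without halving — ranking and signs, which decide the label, are far
    less step-sensitive than the sensitivity values themselves.
    """
    if method == "analytic" and not k.is_zero:
        raise InvalidParameterError("analytic sensitivities require k = 0")
    if method == "finite_difference" and probe is None:
        raise InvalidParameterError("finite_difference method requires a probe")
    xs, ys = grid.x_values, grid.y_values
    labels = np.empty((len(ys), len(xs)), dtype=object)
    sens = np.empty((len(ys), len(xs)), dtype=object)
    errors: list[tuple[int, int, str]] = []
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            traits = grid.traits_at(float(x), float(y))
            try:
                if method == "analytic":
                    s = analytic_sensitivities(traits)
                elif method == "finite_difference":
                    s = finite_difference_sensitivities(
                        traits, k, probe, refine=refine
                    )
                elif method == "equilibrium":
                    s = equilibrium_sensitivities(traits, k)
                else:
                    raise InvalidParameterError(f"unknown method {method!r}")
                labels[iy, ix] = classify_strategy(s, excluded=excluded)
                sens[iy, ix] = s
            except (ArithmeticError, NoEquilibriumError, UndefinedStrategyError) as exc:
                labels[iy, ix] = None
                sens[iy, ix] = None
                errors.append((ix, iy, f"{type(exc).__name__}: {exc}"))
    return StrategyMap(
        grid=grid, labels=labels, sensitivities=sens,
        method=method, k=k, probe=probe, errors=errors,
    )


def extract_contours(
    smap: StrategyMap,
    pair: tuple[str, str] = ("m_H", "r_H"),
) -> list[np.ndarray]:
    """Zero-crossing polylines of the deciding difference |s_a| - |s_b|.

    Marching-squares with linear interpolation along grid-cell edges; each
    polyline is an (n, 2) array of (x_trait, y_trait) coordinates.  An
    empty list means one region covers the whole grid.
    """
    z = smap.deciding_difference(pair)
    if np.all(np.isnan(z)):
        return []
    gen = contour_generator(
        x=smap.grid.x_values, y=smap.grid.y_values, z=np.ma.masked_invalid(z)
    )
    lines = gen.lines(0.0)
    return [np.asarray(line) for line in lines if len(line) >= 2]


def hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric discrete Hausdorff distance between two vertex sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return math.nan
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def _stack(polylines: Sequence[np.ndarray]) -> np.ndarray:
    return np.vstack(polylines) if polylines else np.empty((0, 2))


def baseline_contour(grid: TraitGridSpec) -> np.ndarray:
    """Analytic no-competition contour on a symmetric-migration grid.

    Extracted from the closed-form selection gradient; on the standard
    (r_H, m) plane with r_E = 1 this is the straight line m = 1 - r_H.
    """
    from .model_core import CompetitionMatrix as CM, Scenario as Sc

    smap = strategy_grid(grid, "analytic", CM(scenario=Sc.NONE))
    return _stack(extract_contours(smap))


def contour_convergence(
    grid: TraitGridSpec,
    t_max_list: Sequence[float],
    k_list: Sequence[float],
    scenario: Scenario | str,
    n0: PopulationState,
    *,
    reference: Optional[np.ndarray] = None,
    pair: tuple[str, str] = ("m_H", "r_H"),
) -> pd.DataFrame:
    """Contour distance to a reference, per (t_max, k) cell.

    For each probing time and competition intensity the strategy map is
    rebuilt with finite-difference sensitivities, the region boundary is
    extracted, and its Hausdorff distance to ``reference`` (default: the
    analytic no-competition contour) is tabulated.  NaN distance marks an
    empty contour.
    """
    from .model_core import scenario_matrix

    scenario = Scenario(scenario)
    if reference is None:
        reference = baseline_contour(grid)
    rows = []
    for k_val in k_list:
        k = scenario_matrix(scenario, k_val)
        for t_max in t_max_list:
            probe = ProbeSpec(t_max=t_max, n0=n0)
            smap = strategy_grid(grid, "finite_difference", k, probe)
            contour = _stack(extract_contours(smap, pair))
            dist = hausdorff_distance(contour, reference)
            rows.append(
                {
                    "scenario": scenario.value,
                    "k": k_val,
                    "t_max": t_max,
                    "n_contour_points": len(contour),
                    "hausdorff_distance": dist,
                }
            )
    return pd.DataFrame(rows)


def contours_to_json(polylines: Sequence[np.ndarray]) -> str:
    """Serialize contour polylines as a JSON list of [x, y] point lists."""
    return json.dumps([np.asarray(p).tolist() for p in polylines])
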