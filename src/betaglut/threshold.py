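"""Metabolic-threshold ("tipping point") analysis of the reduced model.

In a healthy beta cell glucokinase is far slower than outward diffusion, so
GK is the glucose sensor and the rate-limiting step of G6P formation.  As
membrane transporter expression falls, outward transport slows until it
becomes comparable to the GK rate; beyond that point transport, not GK,
limits G6P production.  The threshold is operationalized as the iso-GK-rate
level attained at the anchor scenario (no GLUT-1, 20% GLUT-2) at 16.8 mM
extracellular glucose, and the analysis maps the (epsilon1, epsilon2)
combinations that attain exactly that critical rate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import ReducedModelParams, gk_rate, mm_flux, solve_steady_state

__all__ = [
    "ExpressionScenario",
    "Regime",
    "ThresholdResult",
    "rate_comparison_curves",
    "gk_rate_surface",
    "find_threshold_epsilon2",
    "iso_rate_contour",
    "classify_regime",
    "threshold_analysis",
]


@dataclass(frozen=True)
class ExpressionScenario:
    """A (GLUT-1, GLUT-2) membrane-expression scenario."""

    epsilon1: float
    epsilon2: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.epsilon1 < 0 or self.epsilon2 < 0:
            raise ValueError("expression fractions must be non-negative")


class Regime(str, enum.Enum):
    TRANSPORT_LIMITED = "transport_limited"
    PHOSPHORYLATION_LIMITED = "phosphorylation_limited"


@dataclass(frozen=True)
class ThresholdResult:
    critical_gk_rate: float
    anchor_epsilon2: float
    contour: pd.DataFrame
    regimes: pd.DataFrame


def _steady_gk(params: ReducedModelParams, e1: float, e2: float, glucose_out: float) -> float:
    return solve_steady_state(params.with_epsilons(e1, e2), glucose_out).gk_rate


def rate_comparison_curves(
    params: ReducedModelParams,
    scenario: ExpressionScenario,
    glucose_in_grid,
) -> pd.DataFrame:
    """Outward transport arms vs the GK rate over intracellular glucose.

    The outward arm is the unidirectional Michaelis-Menten flux of
    intracellular glucose alone, the quantity GK competes with once glucose
    is inside the cell.
    """
    grid = np.asarray(glucose_in_grid, dtype=float)
    if (grid < 0).any():
        raise ValueError("glucose grid must be non-negative")
    v1 = scenario.epsilon1 * params.glut1.vmax_normal
    v2 = scenario.epsilon2 * params.glut2.vmax_normal
    return pd.DataFrame(
        {
            "glucose_in_mM": grid,
            "outward_glut1": [mm_flux(v1, params.glut1.km, g) for g in grid],
            "outward_glut2": [mm_flux(v2, params.glut2.km, g) for g in grid],
            "gk_rate": [gk_rate(params.gk, g) for g in grid],
        }
    )


def gk_rate_surface(
    params: ReducedModelParams,
    epsilon1_grid,
    epsilon2_grid,
    glucose_out: float,
) -> np.ndarray:
    """Steady-state GK rate over an (epsilon1, epsilon2) grid.

    Element ``[i, j]`` corresponds to ``epsilon1_grid[i]``,
    ``epsilon2_grid[j]``; the surface is non-decreasing along both axes.
    """
    e1s = np.asarray(epsilon1_grid, dtype=float)
    e2s = np.asarray(epsilon2_grid, dtype=float)
    out = np.empty((e1s.size, e2s.size))
    for i, e1 in enumerate(e1s):
        for j, e2 in enumerate(e2s):
            out[i, j] = _steady_gk(params, e1, e2, glucose_out)
    return out


def find_threshold_epsilon2(
    params: ReducedModelParams,
    glucose_out: float,
    critical_rate: float,
    xtol: float = 1e-6,
) -> float:
    """GLUT-2 fraction (no GLUT-1) whose steady GK rate equals the critical rate."""
    if critical_rate < 0:
        raise ValueError("critical_rate must be non-negative")
    if critical_rate == 0.0:
        return 0.0
    top = _steady_gk(params, 0.0, 1.0, glucose_out)
    if critical_rate > top:
        raise ValueError(
            f"critical rate {critical_rate} exceeds the GK rate {top:.4g} at "
            "full GLUT-2 expression; unattainable with epsilon1 = 0"
        )
    if critical_rate == top:
        return 1.0
    return float(
        brentq(
            lambda e2: _steady_gk(params, 0.0, e2, glucose_out) - critical_rate,
            0.0,
            1.0,
            xtol=xtol,
        )
    )


def iso_rate_contour(
    params: ReducedModelParams,
    glucose_out: float,
    critical_rate: float,
    epsilon1_grid,
    xtol: float = 1e-6,
) -> pd.DataFrame:
    """The iso-critical-GK-rate line in the (epsilon1, epsilon2) plane.

    For each GLUT-1 fraction, solves for the GLUT-2 fraction at which the
    steady GK rate equals the critical rate.  Where GLUT-1 alone already
    reaches the critical rate, ``epsilon2`` is 0 and ``saturated`` is True
    (GLUT-1 fully compensates for the absence of GLUT-2).
    """
    rows = []
    for e1 in np.asarray(epsilon1_grid, dtype=float):
        floor = _steady_gk(params, e1, 0.0, glucose_out)
        if floor >= critical_rate:
            rows.append((e1, 0.0, True))
            continue
        e2 = brentq(
            lambda e2: _steady_gk(params, e1, e2, glucose_out) - critical_rate,
            0.0,
            1.0,
            xtol=xtol,
        )
        rows.append((e1, float(e2), False))
    return pd.DataFrame(rows, columns=["epsilon1", "epsilon2", "saturated"])


def classify_regime(
    params: ReducedModelParams,
    scenario: ExpressionScenario,
    glucose_out: float,
    critical_rate: float,
) -> Regime:
    """Transport-limited iff the scenario's steady GK rate is below critical."""
    rate = _steady_gk(params, scenario.epsilon1, scenario.epsilon2, glucose_out)
    return (
        Regime.TRANSPORT_LIMITED
        if rate < critical_rate
        else Regime.PHOSPHORYLATION_LIMITED
    )


def threshold_analysis(
    params: ReducedModelParams,
    scenarios: list[ExpressionScenario] | None = None,
    glucose_out: float = 16.8,
    anchor_epsilon2: float = 0.2,
    epsilon1_grid=None,
) -> ThresholdResult:
    """Full threshold analysis: critical rate, contour, regime classification.

    The critical rate is defined by the anchor scenario (epsilon1 = 0,
    epsilon2 = ``anchor_epsilon2``) at ``glucose_out``.
    """
    if epsilon1_grid is None:
        epsilon1_grid = np.linspace(0.0, 1.0, 101)
    critical = _steady_gk(params, 0.0, anchor_epsilon2, glucose_out)
    contour = iso_rate_contour(params, glucose_out, critical, epsilon1_grid)
    scenarios = scenarios or []
    regimes = pd.DataFrame(
        {
            "label": [s.label for s in scenarios],
            "epsilon1": [s.epsilon1 for s in scenarios],
            "epsilon2": [s.epsilon2 for s in scenarios],
            "gk_rate": [
                _steady_gk(params, s.epsilon1, s.epsilon2, glucose_out)
                for s in scenarios
            ],
            "regime": [
                classify_regime(params, s, glucose_out, critical).value
                for s in scenarios
            ],
        }
    )
    return ThresholdResult(critical, anchor_epsilon2, contour, regimes)
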