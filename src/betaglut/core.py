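"""Reduced kinetic model of glucose entry and phosphorylation in the human
pancreatic beta cell.

The model tracks intracellular unphosphorylated glucose and a lumped pool of
phosphorylated glucose (G6P plus its downstream glycolytic derivatives).
Glucose crosses the plasma membrane by facilitated diffusion through two
transporters, GLUT-1 (Km ~ 3 mM) and GLUT-2 (Km ~ 17 mM), each described by
bidirectional Michaelis-Menten kinetics whose maximum rate scales with the
fraction ``epsilon`` of membrane-resident transporter relative to a healthy
cell.  Intracellular glucose is phosphorylated by glucokinase (GK), the
beta cell's glucose sensor, with Hill kinetics (S0.5 = 8 mM, exponent 1.7).

Units
-----
Concentrations are mM, time is minutes, and fluxes are nmol/min/1e5 cells
(the unit glucose-uptake assays report).  Converting a flux into a
concentration rate requires the aqueous volume of 1e5 cells; steady states
are provably independent of that volume, which only sets the kinetic
timescale of time courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "TransporterKinetics",
    "GKKinetics",
    "CellState",
    "ReducedModelParams",
    "SteadyState",
    "mm_flux",
    "gk_rate",
    "net_transport_flux",
    "reduced_rhs",
    "solve_steady_state",
    "steady_state_by_integration",
    "simulate_excursion",
]

#: nmol/min/1e5 cells -> mM/min, divided by the cell-volume factor (litres).
_NMOL_TO_MMOL = 1e-6


def mm_flux(vmax: float, km: float, conc: float) -> float:
    """Unidirectional Michaelis-Menten flux ``vmax * c / (km + c)``.

    Parameters
    ----------
    vmax : maximum flux, nmol/min/1e5 cells.
    km : half-saturation concentration, mM (must be > 0).
    conc : substrate concentration, mM (must be >= 0).
    """
    if km <= 0:
        raise ValueError(f"km must be positive, got {km}")
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return vmax * conc / (km + conc)


@dataclass(frozen=True)
class TransporterKinetics:
    """Michaelis-Menten kinetics of one facilitative glucose transporter.

    ``vmax_normal`` is the maximum rate at healthy expression; the effective
    maximum rate is ``epsilon * vmax_normal`` where ``epsilon`` is the
    fraction of plasma-membrane-resident transporter relative to a healthy
    beta cell (values above 1 model overexpression and are allowed).
    """

    name: str
    km: float
    vmax_normal: float
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValueError(f"{self.name}: km must be positive, got {self.km}")
        if self.vmax_normal < 0:
            raise ValueError(f"{self.name}: vmax_normal must be >= 0")
        if self.epsilon < 0:
            raise ValueError(f"{self.name}: epsilon must be >= 0, got {self.epsilon}")

    @property
    def vmax(self) -> float:
        """Effective maximum rate ``epsilon * vmax_normal``."""
        return self.epsilon * self.vmax_normal

    def with_epsilon(self, epsilon: float) -> "TransporterKinetics":
        return replace(self, epsilon=epsilon)


@dataclass(frozen=True)
class GKKinetics:
    """Hill kinetics of glucokinase (hexokinase IV)."""

    s_half: float = 8.0
    hill_exponent: float = 1.7
    vmax_gk: float = 0.0

    def __post_init__(self) -> None:
        if self.s_half <= 0:
            raise ValueError("s_half must be positive")
        if self.hill_exponent <= 0:
            raise ValueError("hill_exponent must be positive")
        if self.vmax_gk < 0:
            raise ValueError("vmax_gk must be >= 0")


def gk_rate(gk: GKKinetics, conc: float) -> float:
    """Glucokinase phosphorylation rate at intracellular glucose ``conc``."""
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    if conc == 0.0:
        return 0.0
    ch = conc**gk.hill_exponent
    return gk.vmax_gk * ch / (gk.s_half**gk.hill_exponent + ch)


def net_transport_flux(
    transporter: TransporterKinetics, glucose_out: float, glucose_in: float
) -> float:
    """Net facilitated-diffusion flux (positive = net uptake).

    The inward and outward arms are independent Michaelis-Menten fluxes of
    the extracellular and intracellular concentrations; at equal
    concentrations the net flux is exactly zero.
    """
    vmax = transporter.vmax
    return mm_flux(vmax, transporter.km, glucose_out) - mm_flux(
        vmax, transporter.km, glucose_in
    )


@dataclass(frozen=True)
class CellState:
    """Intracellular glucose and the cumulative phosphorylated-glucose pool.

    The G6P pool lumps every downstream derivative and has no efflux term,
    so it is non-decreasing along any trajectory; steady-state analyses use
    the GK rate, never the pool level.
    """

    glucose_in: float
    g6p_pool: float = 0.0

    def __post_init__(self) -> None:
        if self.glucose_in < 0 or self.g6p_pool < 0:
            raise ValueError("CellState concentrations must be non-negative")


@dataclass(frozen=True)
class ReducedModelParams:
    """Parameters of the reduced transport + phosphorylation model.

    ``volume_per_1e5_cells`` (litres) converts fluxes into concentration
    rates; the default 1e-7 L corresponds to ~1 pL of cell water per cell,
    typical for a beta cell.  Steady states do not depend on it.
    """

    glut1: TransporterKinetics
    glut2: TransporterKinetics
    gk: GKKinetics
    volume_per_1e5_cells: float = 1.0e-7

    def __post_init__(self) -> None:
        if self.volume_per_1e5_cells <= 0:
            raise ValueError("volume_per_1e5_cells must be positive")

    @property
    def flux_to_mm_per_min(self) -> float:
        """Conversion factor: nmol/min/1e5 cells -> mM/min."""
        return _NMOL_TO_MMOL / self.volume_per_1e5_cells

    def with_epsilons(self, epsilon1: float, epsilon2: float) -> "ReducedModelParams":
        """Return a copy with the two membrane-expression fractions replaced."""
        return replace(
            self,
            glut1=self.glut1.with_epsilon(epsilon1),
            glut2=self.glut2.with_epsilon(epsilon2),
        )

    def total_net_uptake(self, glucose_out: float, glucose_in: float) -> float:
        return net_transport_flux(self.glut1, glucose_out, glucose_in) + net_transport_flux(
            self.glut2, glucose_out, glucose_in
        )


def reduced_rhs(
    state: CellState, params: ReducedModelParams, glucose_out: float
) -> tuple[float, float]:
    """Time derivatives (mM/min) of ``(glucose_in, g6p_pool)``."""
    phos = gk_rate(params.gk, state.glucose_in)
    net = params.total_net_uptake(glucose_out, state.glucose_in)
    conv = params.flux_to_mm_per_min
    return ((net - phos) * conv, phos * conv)


@dataclass(frozen=True)
class SteadyState:
    """Steady state of the reduced model at fixed extracellular glucose."""

    glucose_in: float
    net_flux_glut1: float
    net_flux_glut2: float
    gk_rate: float
    glucose_out: float

    @property
    def total_net_flux(self) -> float:
        return self.net_flux_glut1 + self.net_flux_glut2


def solve_steady_state(
    params: ReducedModelParams, glucose_out: float, xtol: float = 1e-10
) -> SteadyState:
    """Steady intracellular glucose where net uptake balances the GK rate.

    The balance ``uptake(g) - gk(g)`` is strictly decreasing on
    ``[0, glucose_out]`` and bracketed by construction, so Brent's method
    finds the unique root.  With no transporter expressed the degenerate
    steady state ``glucose_in = 0`` is returned.
    """
    if glucose_out < 0:
        raise ValueError("glucose_out must be non-negative")

    def packaged(gi: float) -> SteadyState:
        return SteadyState(
            glucose_in=gi,
            net_flux_glut1=net_transport_flux(params.glut1, glucose_out, gi),
            net_flux_glut2=net_transport_flux(params.glut2, glucose_out, gi),
            gk_rate=gk_rate(params.gk, gi),
            glucose_out=glucose_out,
        )

    if glucose_out == 0.0 or (params.glut1.vmax == 0.0 and params.glut2.vmax == 0.0):
        return packaged(0.0)

    def balance(gi: float) -> float:
        return params.total_net_uptake(glucose_out, gi) - gk_rate(params.gk, gi)

    hi = balance(glucose_out)
    if hi >= 0.0:  # vmax_gk == 0: diffusive equilibrium
        return packaged(glucose_out)
    root = brentq(balance, 0.0, glucose_out, xtol=xtol)
    return packaged(float(root))


def _rhs_vector(t, y, params: ReducedModelParams, profile) -> list[float]:
    gi = max(y[0], 0.0)
    dgi, dg6p = reduced_rhs(CellState(gi, max(y[1], 0.0)), params, profile(t))
    return [dgi, dg6p]


def steady_state_by_integration(
    params: ReducedModelParams,
    glucose_out: float,
    initial: CellState | None = None,
    deriv_tol: float = 1e-8,
    chunk_min: float = 500.0,
    max_chunks: int = 60,
) -> SteadyState:
    """Long-time limit of the ODE, the independent oracle for the root solve.

    Integrates with a stiff-capable solver in chunks until
    ``|d glucose_in/dt| < deriv_tol`` (mM/min).
    """
    y = [initial.glucose_in if initial else 0.0, initial.g6p_pool if initial else 0.0]
    profile = lambda t: glucose_out  # noqa: E731
    t0 = 0.0
    for _ in range(max_chunks):
        sol = solve_ivp(
            _rhs_vector,
            (t0, t0 + chunk_min),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
            args=(params, profile),
        )
        if not sol.success:
            raise RuntimeError(f"steady-state integration failed: {sol.message}")
        y = [float(sol.y[0, -1]), float(sol.y[1, -1])]
        t0 = float(sol.t[-1])
        if abs(_rhs_vector(t0, y, params, profile)[0]) < deriv_tol:
            break
    else:
        raise RuntimeError("steady-state integration did not converge")
    gi = y[0]
    return SteadyState(
        glucose_in=gi,
        net_flux_glut1=net_transport_flux(params.glut1, glucose_out, gi),
        net_flux_glut2=net_transport_flux(params.glut2, glucose_out, gi),
        gk_rate=gk_rate(params.gk, gi),
        glucose_out=glucose_out,
    )


def simulate_excursion(
    params: ReducedModelParams,
    glucose_profile: Callable[[float], float],
    t_end: float,
    initial: CellState | None = None,
    n_points: int = 501,
) -> pd.DataFrame:
    """Simulate a glucose excursion and report the dense trajectory.

    ``glucose_profile`` maps time (min) to extracellular glucose (mM); a
    profile object exposing ``switch_times`` is integrated piecewise so
    discontinuities (e.g. the postprandial 2.8 -> 16.8 mM step) are handled
    exactly.  When ``initial`` is omitted the cell starts at rest: the
    steady state of the pre-excursion glucose level.

    Returns a DataFrame with columns ``time_min, glucose_out_mM,
    glucose_in_mM, g6p_mM, net_flux_glut1, net_flux_glut2, gk_rate`` (flux
    columns in nmol/min/1e5 cells).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial is None:
        rest = solve_steady_state(params, glucose_profile(0.0))
        initial = CellState(rest.glucose_in, 0.0)

    breaks = sorted(
        {0.0, t_end}
        | {t for t in getattr(glucose_profile, "switch_times", ()) if 0.0 < t < t_end}
    )
    times = np.linspace(0.0, t_end, n_points)
    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    y = [initial.glucose_in, initial.g6p_pool]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        t_eval = times[(times >= lo) & (times <= hi)]
        if t_eval.size == 0 or t_eval[0] > lo:
            t_eval = np.concatenate([[lo], t_eval])
        if t_eval[-1] < hi:
            t_eval = np.concatenate([t_eval, [hi]])
        # evaluate the profile strictly inside the segment so a step at `lo`
        # takes its post-switch value throughout
        mid = 0.5 * (lo + hi)
        level = glucose_profile(mid)
        seg_profile = (
            glucose_profile
            if getattr(glucose_profile, "kind", "constant") == "meal"
            else (lambda t, _lvl=level: _lvl)
        )
        sol = solve_ivp(
            _rhs_vector,
            (lo, hi),
            y,
            t_eval=t_eval,
            method="LSODA",
            rtol=1e-8,
            atol=1e-10,
            args=(params, seg_profile),
        )
        if not sol.success:
            raise RuntimeError(
                f"excursion integration failed on [{lo}, {hi}]: {sol.message}"
            )
        out_t.append(sol.t)
        out_y.append(sol.y)
        y = [float(sol.y[0, -1]), float(sol.y[1, -1])]

    t = np.concatenate(out_t)
    ys = np.concatenate(out_y, axis=1)
    go = np.array([glucose_profile(v) if v not in breaks[1:] else glucose_profile(min(v + 1e-9, t_end)) for v in t])
    gi = np.clip(ys[0], 0.0, None)
    f1 = np.array([net_transport_flux(params.glut1, o, g) for o, g in zip(go, gi)])
    f2 = np.array([net_transport_flux(params.glut2, o, g) for o, g in zip(go, gi)])
    vgk = np.array([gk_rate(params.gk, g) for g in gi])
    return pd.DataFrame(
        {
            "time_min": t,
            "glucose_out_mM": go,
            "glucose_in_mM": gi,
            "g6p_mM": np.clip(ys[1], 0.0, None),
            "net_flux_glut1": f1,
            "net_flux_glut2": f2,
            "gk_rate": vgk,
        }
    ).drop_duplicates(subset="time_min", keep="last", ignore_index=True)
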