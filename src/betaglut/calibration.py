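"""Reconstruction of the reduced model's unprinted maximum rates.

Only the transporter Km values, the GK Hill parameters, and a handful of
steady-state anchors are printed for the beta-cell model: at 16.8 mM
extracellular glucose a cell with 20% GLUT-2 and no GLUT-1 sits at ~6.5 mM
intracellular glucose with a GK rate of 0.07 nmol/min/1e5 cells, which is
50% of the healthy intracellular glucose and ~60% of the healthy GK rate of
0.12 nmol/min/1e5 cells.  Those anchors over-determine the three maximum
rates, so calibration solves three of them exactly (the threshold pair plus
the healthy glucose level) and reports the residual against the redundant
healthy GK rate rather than silently absorbing the inconsistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

from .core import (
    GKKinetics,
    ReducedModelParams,
    TransporterKinetics,
    gk_rate,
    solve_steady_state,
)

__all__ = [
    "CalibrationAnchors",
    "calibrate_full",
    "CalibratedParams",
    "calibrate_reduced",
    "gk_vmax_from_anchor",
    "invert_gk",
]


@dataclass(frozen=True)
class CalibrationAnchors:
    """Printed kinetic constants and steady-state anchors.

    ``healthy_glucose_in`` comes from reading the "50% of normal" statement
    against the 6.5 mM threshold glucose; ``healthy_gk_rate`` is kept as a
    redundancy check (printed to two significant figures).
    """

    km_glut1: float = 3.0
    km_glut2: float = 17.0
    s_half: float = 8.0
    hill_exponent: float = 1.7
    glucose_out_high: float = 16.8
    threshold_epsilon1: float = 0.0
    threshold_epsilon2: float = 0.2
    threshold_glucose_in: float = 6.5
    threshold_gk_rate: float = 0.07
    healthy_gk_rate: float = 0.12
    healthy_glucose_in: float = 13.0

    def __post_init__(self) -> None:
        vals = [
            self.km_glut1, self.km_glut2, self.s_half, self.hill_exponent,
            self.glucose_out_high, self.threshold_epsilon2,
            self.threshold_glucose_in, self.threshold_gk_rate,
            self.healthy_gk_rate, self.healthy_glucose_in,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("calibration anchors must be positive")
        if not (
            self.threshold_glucose_in < self.healthy_glucose_in < self.glucose_out_high
        ):
            raise ValueError(
                "anchors must satisfy threshold < healthy < extracellular glucose"
            )


@dataclass(frozen=True)
class CalibratedParams:
    """Maximum rates reconstructed from the anchors, with provenance.

    ``provenance`` maps each anchor to the relative residual it leaves when
    the calibrated model is evaluated against it; anchors used exactly in
    the derivation have residual ~0, redundant anchors carry the printed
    rounding error.
    """

    vmax_gk: float
    vmax_normal_glut1: float
    vmax_normal_glut2: float
    anchors: CalibrationAnchors = field(default_factory=CalibrationAnchors)
    provenance: dict[str, float] = field(default_factory=dict)

    def to_reduced_params(
        self,
        epsilon1: float = 1.0,
        epsilon2: float = 1.0,
        volume_per_1e5_cells: float = 1.0e-7,
    ) -> ReducedModelParams:
        a = self.anchors
        return ReducedModelParams(
            glut1=TransporterKinetics("GLUT1", a.km_glut1, self.vmax_normal_glut1, epsilon1),
            glut2=TransporterKinetics("GLUT2", a.km_glut2, self.vmax_normal_glut2, epsilon2),
            gk=GKKinetics(a.s_half, a.hill_exponent, self.vmax_gk),
            volume_per_1e5_cells=volume_per_1e5_cells,
        )


def gk_vmax_from_anchor(
    rate: float, conc: float, s_half: float = 8.0, hill_exponent: float = 1.7
) -> float:
    """GK maximum rate such that the Hill rate at ``conc`` equals ``rate``."""
    if rate <= 0 or conc <= 0:
        raise ValueError("rate and concentration must be positive")
    occ = conc**hill_exponent / (s_half**hill_exponent + conc**hill_exponent)
    return rate / occ


def invert_gk(gk: GKKinetics, rate: float) -> float:
    """Intracellular glucose at which the GK Hill rate equals ``rate``."""
    if not 0.0 < rate < gk.vmax_gk:
        raise ValueError("rate must lie strictly between 0 and vmax_gk")
    frac = rate / gk.vmax_gk
    return (gk.s_half**gk.hill_exponent * frac / (1.0 - frac)) ** (
        1.0 / gk.hill_exponent
    )


def _mm_gradient(km: float, glucose_out: float, glucose_in: float) -> float:
    """Per-unit-Vmax net diffusive flux between the two compartments."""
    return glucose_out / (km + glucose_out) - glucose_in / (km + glucose_in)


def calibrate_reduced(
    anchors: CalibrationAnchors | None = None, tolerance: float = 0.10
) -> CalibratedParams:
    """Solve the three maximum rates from the steady-state anchors.

    1. ``vmax_gk`` from the threshold GK rate at the threshold glucose.
    2. GLUT-2's normal Vmax from the threshold flux balance (20% GLUT-2,
       no GLUT-1, uptake = GK rate at 6.5 mM).
    3. GLUT-1's normal Vmax from the healthy flux balance at the healthy
       intracellular glucose, using the calibrated GK curve there.

    The calibrated model is then re-evaluated against every anchor; a hard
    error is raised if a redundant anchor disagrees by more than
    ``tolerance`` relative.
    """
    a = anchors or CalibrationAnchors()

    vmax_gk = gk_vmax_from_anchor(
        a.threshold_gk_rate, a.threshold_glucose_in, a.s_half, a.hill_exponent
    )
    gk = GKKinetics(a.s_half, a.hill_exponent, vmax_gk)

    grad2_thr = _mm_gradient(a.km_glut2, a.glucose_out_high, a.threshold_glucose_in)
    v2 = a.threshold_gk_rate / (a.threshold_epsilon2 * grad2_thr)

    gk_healthy = gk_rate(gk, a.healthy_glucose_in)
    grad1 = _mm_gradient(a.km_glut1, a.glucose_out_high, a.healthy_glucose_in)
    grad2 = _mm_gradient(a.km_glut2, a.glucose_out_high, a.healthy_glucose_in)
    v1 = (gk_healthy - v2 * grad2) / grad1
    if v1 <= 0:
        raise ValueError(
            "anchor set implies a non-positive GLUT-1 Vmax; anchors inconsistent"
        )

    calibrated = CalibratedParams(vmax_gk, v1, v2, a)

    # Residual report over every printed anchor.
    thr = solve_steady_state(
        calibrated.to_reduced_params(a.threshold_epsilon1, a.threshold_epsilon2),
        a.glucose_out_high,
    )
    healthy = solve_steady_state(
        calibrated.to_reduced_params(1.0, 1.0), a.glucose_out_high
    )
    provenance = {
        "threshold_gk_rate": thr.gk_rate / a.threshold_gk_rate - 1.0,
        "threshold_glucose_in": thr.glucose_in / a.threshold_glucose_in - 1.0,
        "healthy_glucose_in": healthy.glucose_in / a.healthy_glucose_in - 1.0,
        "healthy_gk_rate": healthy.gk_rate / a.healthy_gk_rate - 1.0,
    }
    worst = max(abs(r) for r in provenance.values())
    if worst > tolerance:
        offender = max(provenance, key=lambda k: abs(provenance[k]))
        raise ValueError(
            f"anchor inconsistency {worst:.1%} on '{offender}' exceeds "
            f"{tolerance:.0%}: {provenance}"
        )
    return CalibratedParams(vmax_gk, v1, v2, a, provenance)


# ---------------------------------------------------------------------------
# Full-model calibration
# ---------------------------------------------------------------------------

def calibrate_full(
    reduced: CalibratedParams,
    t2d_epsilon1: float = 0.14,
    t2d_epsilon2: float = 0.05,
    glycan_targets: dict[str, float] | None = None,
    epsilon_tolerance: float = 0.01,
    glycan_tolerance: float = 0.05,
):
    """Fit the full regulatory model's free parameters to printed constraints.

    The healthy steady state is the normalized fixed point by construction.
    The free parameters are solved sequentially and exactly, exploiting the
    feed-forward structure:

    1. the T2D nuclear-exclusion factor, so membrane GLUT-1 lands on
       ``t2d_epsilon1`` (the promoter kinetic order of GLUT1/MGAT4A is held
       at its default, and GLUT1 under exclusion depends only on the
       factor);
    2. the GLUT2 promoter kinetic order, so the same single factor also
       lands membrane GLUT-2 on ``t2d_epsilon2`` (a shared factor can only
       produce unequal reductions through gene-specific promoter response);
    3. one competitive strength per soluble glycan, matching the mean
       printed membrane reduction (per-transporter means; shared
       post-translational kinetics force equal fractional reductions for
       both transporters, the printed spread is treated as assay noise).

    Returns the fitted :class:`~betaglut.regulatory.NetworkParams`; raises
    if any constraint residual exceeds its tolerance.
    """
    from scipy.optimize import brentq as _brentq

    from .regulatory import NetworkParams, PerturbationSpec, steady_state_full

    if glycan_targets is None:
        glycan_targets = {"LacNAc": 0.775, "(LacNAc)3": 0.525}

    base = NetworkParams(reduced=reduced.to_reduced_params(1.0, 1.0))

    def eps_under_exclusion(phi: float, params: NetworkParams):
        ss = steady_state_full(
            params, PerturbationSpec(nuclear_exclusion_factor=phi)
        )
        return ss.epsilon1, ss.epsilon2

    phi = _brentq(
        lambda f: eps_under_exclusion(f, base)[0] - t2d_epsilon1,
        1e-9,
        1e6,
        xtol=1e-10,
        rtol=1e-12,
    )

    def with_h2(h2: float) -> NetworkParams:
        hp = dict(base.hill_promoter)
        hp["GLUT2"] = h2
        return replace(base, hill_promoter=hp)

    h2 = _brentq(
        lambda h: eps_under_exclusion(phi, with_h2(h))[1] - t2d_epsilon2,
        0.01,
        50.0,
        xtol=1e-12,
    )
    fitted = with_h2(h2)

    # Glycan competition: membrane = hillL(1/(1+s)) / hillL(1) at healthy
    # glycosylated pools; solve each strength against the mean reduction.
    strengths: dict[str, float] = {}
    for name, target in glycan_targets.items():
        if not 0.0 < target < 1.0:
            raise ValueError(f"glycan target for {name} must be in (0, 1)")

        def mem_fraction(s: float) -> float:
            from .regulatory import GlycanCompetitor

            ss = steady_state_full(
                fitted,
                PerturbationSpec(glycan_competitor=GlycanCompetitor(name, s)),
            )
            return ss.epsilon1

        strengths[name] = _brentq(
            lambda s: mem_fraction(s) - target, 0.0, 1e4, xtol=1e-10
        )

    fitted = replace(
        fitted, t2d_exclusion_factor=float(phi), glycan_strengths=strengths
    )

    # Constraint residual report.
    e1, e2 = eps_under_exclusion(phi, fitted)
    residuals = {
        "t2d_epsilon1": e1 / t2d_epsilon1 - 1.0,
        "t2d_epsilon2": e2 / t2d_epsilon2 - 1.0,
    }
    from .regulatory import GlycanCompetitor

    for name, target in glycan_targets.items():
        ss = steady_state_full(
            fitted,
            PerturbationSpec(
                glycan_competitor=GlycanCompetitor(name, strengths[name])
            ),
        )
        residuals[f"glycan_{name}_glut1"] = ss.epsilon1 / target - 1.0
        residuals[f"glycan_{name}_glut2"] = ss.epsilon2 / target - 1.0

    for key, res in residuals.items():
        tol = epsilon_tolerance if key.startswith("t2d") else glycan_tolerance
        if abs(res) > tol:
            raise ValueError(
                f"full-model fit residual {res:.2%} on '{key}' exceeds {tol:.0%}"
            )
    return fitted
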