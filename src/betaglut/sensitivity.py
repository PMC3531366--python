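"""Local sensitivity analysis of the steady-state GK rate to RNA abundance.

Ranks candidate therapeutic control points in the diabetic beta cell: each
gene's RNA is clamped slightly above and below its (perturbed) steady
abundance, the downstream steady state is re-solved through the
feed-forward cascade, and the normalized coefficient

    S_j = (RNA_j / v_GK) * d v_GK / d RNA_j

is estimated by central differences.  Coefficients are computed at the
T2D-perturbed steady state (nuclear exclusion of HNF1A/FOXA2) at both a
fasting (2.8 mM) and a postprandial (16.8 mM) plasma glucose level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .regulatory import (
    NETWORK_GENES,
    NetworkParams,
    PerturbationSpec,
    steady_state_full,
)

__all__ = ["SensitivityResult", "sensitivity_coefficient", "sensitivity_table"]

_RNA_STATE_NAME = {
    "HNF1A": "hnf1a_rna",
    "FOXA2": "foxa2_rna",
    "GLUT1": "rna_glut1",
    "GLUT2": "rna_glut2",
    "MGAT4A": "rna_mgat4a",
    "CTRL": "ctrl_rna",
}


@dataclass(frozen=True)
class SensitivityResult:
    gene: str
    glucose_out: float
    coefficient: float
    step_used: float


def _clamped(pert: PerturbationSpec, gene: str, value: float) -> PerturbationSpec:
    clamp = dict(pert.rna_clamp)
    clamp[gene] = value
    return replace(pert, rna_clamp=clamp)


def sensitivity_coefficient(
    params: NetworkParams,
    perturbation: PerturbationSpec,
    gene: str,
    glucose_out: float,
    rel_step: float = 0.01,
) -> SensitivityResult:
    """Normalized sensitivity of the steady GK rate to one gene's RNA.

    The RNA is clamped at ``(1 +/- rel_step)`` times its steady abundance
    under ``perturbation`` and the perturbed steady states are re-solved;
    normalization by baseline RNA and GK rate makes coefficients unitless
    and directly comparable across genes.
    """
    if gene not in NETWORK_GENES:
        raise KeyError(f"unknown gene {gene!r}; choose from {NETWORK_GENES}")
    if not 0.0 < rel_step <= 0.1:
        raise ValueError("rel_step must be in (0, 0.1]")
    base = steady_state_full(params, perturbation, glucose_out)
    if base.gk_rate <= 0.0:
        raise RuntimeError("baseline GK rate is zero; sensitivity undefined")
    rna0 = base.state[_RNA_STATE_NAME[gene]]
    up = steady_state_full(
        params, _clamped(perturbation, gene, rna0 * (1.0 + rel_step)), glucose_out
    )
    down = steady_state_full(
        params, _clamped(perturbation, gene, rna0 * (1.0 - rel_step)), glucose_out
    )
    coeff = (up.gk_rate - down.gk_rate) / (2.0 * rel_step * base.gk_rate)
    return SensitivityResult(gene, glucose_out, float(coeff), rel_step)


def sensitivity_table(
    params: NetworkParams,
    perturbation: PerturbationSpec,
    genes=("HNF1A", "FOXA2", "MGAT4A", "GLUT1", "GLUT2"),
    glucose_levels=(2.8, 16.8),
    rel_step: float = 0.01,
) -> pd.DataFrame:
    """Cross-product table of sensitivity coefficients (deterministic)."""
    rows = [
        sensitivity_coefficient(params, perturbation, g, go, rel_step)
        for go in glucose_levels
        for g in genes
    ]
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "glucose_mM": [r.glucose_out for r in rows],
            "coefficient": [r.coefficient for r in rows],
            "step": [r.step_used for r in rows],
        }
    )
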