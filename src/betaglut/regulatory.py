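"""Full regulatory model of beta-cell glucose-transporter expression.

Six coupled subsystems feed forward into the reduced transport model:

I/II.  HNF1A and FOXA2 expression (RNA -> cytoplasmic protein) and nuclear
       translocation, with first-order mass-action production, degradation,
       import and export.  Type-2-diabetic and palmitate-treated cells are
       modelled by a single inhibitory factor that scales down nuclear
       import of both factors.
III/IV. Two-layer transcriptional activation of the GLUT1, GLUT2 and
       MGAT4A genes: HNF1A drives histone acetylation at the target
       promoters, and both factors bind the promoters directly; the
       transcription-rate multiplier is acetylation times a weighted sum of
       the two binding occupancies, normalized to 1 at the healthy state.
V.     GNT-4A (MGAT4A product) glycosylates newly made transporters by
       mass action; the kinetic constants are shared between GLUT-1 and
       GLUT-2, so any difference between the transporters is purely
       transcriptional.
VI.    Only glycosylated transporters are retained at the plasma membrane,
       through a Hill-type lectin interaction that competes with
       first-order endocytic turnover.  Soluble glycans (LacNAc and its
       trimer) competitively divide the lectin's ligand and strip
       transporters from the membrane.

Every species is non-dimensionalized to its healthy steady state, so the
healthy fixed point is the all-ones vector and membrane pools read out
directly as the expression fractions epsilon1, epsilon2 of the reduced
model.  The cascade is strictly feed-forward (no retroactivity), so steady
states can be solved module-by-module algebraically; the ODE right-hand
side is retained as an independent route and for time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .core import CellState, ReducedModelParams, reduced_rhs, solve_steady_state

__all__ = [
    "TF_GENES",
    "TARGET_GENES",
    "NETWORK_GENES",
    "GlycanCompetitor",
    "PerturbationSpec",
    "NetworkParams",
    "RegulatoryState",
    "FullSteadyState",
    "promoter_activation",
    "tf_rhs",
    "acetylation_rhs",
    "glycosylation_rhs",
    "membrane_residency_rhs",
    "full_rhs",
    "steady_state_full",
    "integrate_to_steady_state",
    "membrane_glut1_fraction",
]

TF_GENES = ("HNF1A", "FOXA2")
TARGET_GENES = ("GLUT1", "GLUT2", "MGAT4A")
#: CTRL is a transcribed but functionless RNA used as a negative control in
#: sensitivity analyses.
NETWORK_GENES = TF_GENES + TARGET_GENES + ("CTRL",)


def _hill(x: float, k: float, h: float) -> float:
    if x <= 0.0:
        return 0.0
    xh = (x / k) ** h
    return xh / (1.0 + xh)


@dataclass(frozen=True)
class GlycanCompetitor:
    """A soluble glycan competing with transporters for lectin binding."""

    name: str
    strength: float

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("competitor strength must be non-negative")


@dataclass(frozen=True)
class PerturbationSpec:
    """Declarative in-silico intervention on the regulatory network.

    All-neutral settings leave the model bit-identical to baseline.
    ``rna_clamp`` freezes the named RNA species at fixed abundances;
    ``epsilon_override`` bypasses the network entirely and imposes membrane
    fractions on the metabolic module.
    """

    nuclear_exclusion_factor: float = 0.0
    glycan_competitor: GlycanCompetitor | None = None
    rna_clamp: Mapping[str, float] = field(default_factory=dict)
    epsilon_override: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.nuclear_exclusion_factor < 0:
            raise ValueError("nuclear_exclusion_factor must be non-negative")
        for gene, value in self.rna_clamp.items():
            if gene not in NETWORK_GENES:
                raise KeyError(f"unknown gene in rna_clamp: {gene!r}")
            if value < 0:
                raise ValueError(f"clamped RNA abundance must be >= 0 ({gene})")

    @property
    def import_scale(self) -> float:
        """Multiplier on TF nuclear import, 1/(1 + exclusion factor)."""
        return 1.0 / (1.0 + self.nuclear_exclusion_factor)

    @property
    def competitor_strength(self) -> float:
        return self.glycan_competitor.strength if self.glycan_competitor else 0.0


@dataclass(frozen=True)
class NetworkParams:
    """Rate constants of the full model, in min^-1 on normalized abundances.

    Degradation/turnover rates default to 0.1 min^-1; synthesis, import and
    translation constants are derived so that the all-ones state is an
    exact fixed point.  The promoter kinetic orders (`hill_promoter`) and
    the T2D nuclear-exclusion factor are the free parameters fitted by
    ``calibrate_full`` against the printed T2D expression fractions.
    """

    reduced: ReducedModelParams
    k_rna_deg: float = 0.1
    k_prot_deg: float = 0.1
    k_nuc_out: float = 0.1
    k_ac: float = 0.1
    k_deac: float = 0.1
    hill_acetylation: float = 0.3
    hill_promoter: Mapping[str, float] = field(
        default_factory=lambda: {"GLUT1": 0.35, "GLUT2": 0.35, "MGAT4A": 0.35}
    )
    w_hnf1a: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.5 for g in TARGET_GENES}
    )
    w_foxa2: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.5 for g in TARGET_GENES}
    )
    k_glyc: float = 0.1
    k_deg_unglyc: float = 0.1
    k_deg_glyc: float = 0.1
    k_endo: float = 0.1
    lectin_hill: float = 2.0
    lectin_half: float = 1.0
    healthy_glut1_share: float = 0.8  # molecule fraction of membrane GLUT-1
    t2d_exclusion_factor: float = 0.0
    glycan_strengths: Mapping[str, float] = field(default_factory=dict)

    # -- derived constants (healthy fixed point at all-ones) ----------------
    @property
    def k_nuc_in(self) -> float:
        return self.k_nuc_out + self.k_prot_deg

    @property
    def k_translation(self) -> float:
        return self.k_prot_deg + self.k_nuc_in - self.k_nuc_out

    @property
    def k_syn_transporter(self) -> float:
        return self.k_glyc + self.k_deg_unglyc

    @property
    def k_mem_on(self) -> float:
        return self.k_endo / _hill(1.0, self.lectin_half, self.lectin_hill)

    @property
    def acetylation_baseline(self) -> float:
        h0 = self.k_ac * _hill(1.0, 1.0, self.hill_acetylation)
        return h0 / (h0 + self.k_deac)


def promoter_activation(
    nuclear_hnf1a: float,
    nuclear_foxa2: float,
    acetylation: float,
    gene: str,
    params: NetworkParams,
) -> float:
    """Transcription-rate multiplier of one target gene.

    Acetylation (chromatin layer) multiplies an additive weighted sum of
    the two factors' promoter occupancies (binding layer); both layers are
    normalized so the healthy baseline gives exactly 1.
    """
    if min(nuclear_hnf1a, nuclear_foxa2, acetylation) < 0:
        raise ValueError("promoter inputs must be non-negative")
    h = params.hill_promoter[gene]
    wh, wf = params.w_hnf1a[gene], params.w_foxa2[gene]
    occupancy = wh * _hill(nuclear_hnf1a, 1.0, h) + wf * _hill(nuclear_foxa2, 1.0, h)
    baseline = (wh + wf) * _hill(1.0, 1.0, h)
    return (acetylation / params.acetylation_baseline) * occupancy / baseline


def tf_rhs(
    rna: float,
    prot_cyt: float,
    prot_nuc: float,
    params: NetworkParams,
    perturbation: PerturbationSpec,
    rna_clamped: bool = False,
) -> tuple[float, float, float]:
    """Mass-action dynamics of one transcription factor's three pools."""
    if min(rna, prot_cyt, prot_nuc) < 0:
        raise ValueError("TF abundances must be non-negative")
    scale = perturbation.import_scale
    d_rna = 0.0 if rna_clamped else params.k_rna_deg * (1.0 - rna)
    d_cyt = (
        params.k_translation * rna
        - params.k_prot_deg * prot_cyt
        - params.k_nuc_in * scale * prot_cyt
        + params.k_nuc_out * prot_nuc
    )
    d_nuc = (
        params.k_nuc_in * scale * prot_cyt
        - params.k_nuc_out * prot_nuc
        - params.k_prot_deg * prot_nuc
    )
    return d_rna, d_cyt, d_nuc


def acetylation_rhs(
    acetylation: float, nuclear_hnf1a: float, params: NetworkParams
) -> float:
    """HNF1A-driven promoter histone acetylation, bounded in [0, 1]."""
    drive = params.k_ac * _hill(nuclear_hnf1a, 1.0, params.hill_acetylation)
    return drive * (1.0 - acetylation) - params.k_deac * acetylation


def glycosylation_rhs(
    unglycosylated: float,
    glycosylated: float,
    rna: float,
    gnt4a_protein: float,
    params: NetworkParams,
) -> tuple[float, float]:
    """Synthesis, GNT-4A-dependent glycosylation, and degradation of one
    transporter's intracellular pools (constants shared by GLUT-1/GLUT-2)."""
    d_unglyc = (
        params.k_syn_transporter * rna
        - params.k_glyc * gnt4a_protein * unglycosylated
        - params.k_deg_unglyc * unglycosylated
    )
    d_glyc = (
        params.k_glyc * gnt4a_protein * unglycosylated
        - params.k_deg_glyc * glycosylated
    )
    return d_unglyc, d_glyc


def membrane_residency_rhs(
    membrane: float,
    glycosylated: float,
    params: NetworkParams,
    competitor_strength: float = 0.0,
) -> float:
    """Lectin-retained membrane pool vs endocytic turnover.

    A soluble glycan competitor divides the effective glycosylated ligand
    (competitive binding), so only glycosylated transporters ever reach a
    stable membrane residency.
    """
    ligand = glycosylated / (1.0 + competitor_strength)
    return (
        params.k_mem_on * _hill(ligand, params.lectin_half, params.lectin_hill)
        - params.k_endo * membrane
    )


# ---------------------------------------------------------------------------
# Full state vector
# ---------------------------------------------------------------------------

_FIELDS = (
    "hnf1a_rna", "hnf1a_cyt", "hnf1a_nuc",
    "foxa2_rna", "foxa2_cyt", "foxa2_nuc",
    "acet_glut1", "acet_glut2", "acet_mgat4a",
    "rna_glut1", "rna_glut2", "rna_mgat4a",
    "gnt4a_protein",
    "glut1_unglyc", "glut1_glyc", "glut1_mem",
    "glut2_unglyc", "glut2_glyc", "glut2_mem",
    "ctrl_rna",
    "glucose_in", "g6p_pool",
)
_IDX = {name: i for i, name in enumerate(_FIELDS)}
_RNA_INDEX = {
    "HNF1A": _IDX["hnf1a_rna"],
    "FOXA2": _IDX["foxa2_rna"],
    "GLUT1": _IDX["rna_glut1"],
    "GLUT2": _IDX["rna_glut2"],
    "MGAT4A": _IDX["rna_mgat4a"],
    "CTRL": _IDX["ctrl_rna"],
}


@dataclass
class RegulatoryState:
    """Full-model state; every regulatory species normalized to healthy = 1."""

    values: np.ndarray

    @classmethod
    def healthy(cls, params: NetworkParams, glucose_in: float = 0.0) -> "RegulatoryState":
        v = np.ones(len(_FIELDS))
        for g in ("glut1", "glut2", "mgat4a"):
            v[_IDX[f"acet_{g}"]] = params.acetylation_baseline
        v[_IDX["glucose_in"]] = glucose_in
        v[_IDX["g6p_pool"]] = 0.0
        return cls(v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[_IDX[name]])

    def as_dict(self) -> dict[str, float]:
        return {name: float(self.values[i]) for name, i in _IDX.items()}


def _apply_clamps(y: np.ndarray, perturbation: PerturbationSpec) -> np.ndarray:
    if not perturbation.rna_clamp:
        return y
    y = y.copy()
    for gene, value in perturbation.rna_clamp.items():
        y[_RNA_INDEX[gene]] = value
    return y


def full_rhs(
    t: float,
    y: np.ndarray,
    params: NetworkParams,
    perturbation: PerturbationSpec,
    glucose_out: float,
) -> np.ndarray:
    """Right-hand side of the complete 22-species ODE system."""
    y = np.asarray(y, dtype=float)
    if y.shape != (len(_FIELDS),):
        raise ValueError(
            f"state vector must have length {len(_FIELDS)}, got {y.shape}"
        )
    y = _apply_clamps(np.clip(y, 0.0, None), perturbation)
    dy = np.zeros_like(y)

    for tf in ("hnf1a", "foxa2"):
        gene = tf.upper()
        i_rna, i_cyt, i_nuc = _IDX[f"{tf}_rna"], _IDX[f"{tf}_cyt"], _IDX[f"{tf}_nuc"]
        dy[i_rna], dy[i_cyt], dy[i_nuc] = tf_rhs(
            y[i_rna], y[i_cyt], y[i_nuc], params, perturbation,
            rna_clamped=gene in perturbation.rna_clamp,
        )
    n_h, n_f = y[_IDX["hnf1a_nuc"]], y[_IDX["foxa2_nuc"]]

    for gene, tag in (("GLUT1", "glut1"), ("GLUT2", "glut2"), ("MGAT4A", "mgat4a")):
        i_ac, i_rna = _IDX[f"acet_{tag}"], _IDX[f"rna_{tag}"]
        dy[i_ac] = acetylation_rhs(y[i_ac], n_h, params)
        if gene not in perturbation.rna_clamp:
            mult = promoter_activation(n_h, n_f, y[i_ac], gene, params)
            dy[i_rna] = params.k_rna_deg * (mult - y[i_rna])

    dy[_IDX["gnt4a_protein"]] = params.k_prot_deg * (
        y[_IDX["rna_mgat4a"]] - y[_IDX["gnt4a_protein"]]
    )
    if "CTRL" not in perturbation.rna_clamp:
        dy[_IDX["ctrl_rna"]] = params.k_rna_deg * (1.0 - y[_IDX["ctrl_rna"]])

    strength = perturbation.competitor_strength
    gnt = y[_IDX["gnt4a_protein"]]
    for tag in ("glut1", "glut2"):
        i_u, i_g, i_m = _IDX[f"{tag}_unglyc"], _IDX[f"{tag}_glyc"], _IDX[f"{tag}_mem"]
        dy[i_u], dy[i_g] = glycosylation_rhs(
            y[i_u], y[i_g], y[_IDX[f"rna_{tag}"]], gnt, params
        )
        dy[i_m] = membrane_residency_rhs(y[i_m], y[i_g], params, strength)

    if perturbation.epsilon_override is not None:
        e1, e2 = perturbation.epsilon_override
    else:
        e1, e2 = y[_IDX["glut1_mem"]], y[_IDX["glut2_mem"]]
    reduced = params.reduced.with_epsilons(e1, e2)
    d_gi, d_g6p = reduced_rhs(
        CellState(y[_IDX["glucose_in"]], y[_IDX["g6p_pool"]]), reduced, glucose_out
    )
    dy[_IDX["glucose_in"]], dy[_IDX["g6p_pool"]] = d_gi, d_g6p
    return dy


@dataclass(frozen=True)
class FullSteadyState:
    """Steady state of the full model plus derived metabolic read-outs."""

    state: RegulatoryState
    epsilon1: float
    epsilon2: float
    glucose_in: float
    gk_rate: float
    net_flux_glut1: float
    net_flux_glut2: float
    glucose_out: float
    glut1_membrane_fraction: float

    @property
    def total_net_flux(self) -> float:
        return self.net_flux_glut1 + self.net_flux_glut2


def membrane_glut1_fraction(
    epsilon1: float, epsilon2: float, healthy_glut1_share: float = 0.8
) -> float:
    """Molecule fraction of GLUT-1 among membrane transporters.

    The healthy membrane is ``healthy_glut1_share`` GLUT-1 molecules; under
    fractional reductions (epsilon1, epsilon2) the composition follows by
    exact arithmetic.
    """
    num = healthy_glut1_share * epsilon1
    den = num + (1.0 - healthy_glut1_share) * epsilon2
    if den == 0.0:
        return float("nan")
    return num / den


def steady_state_full(
    params: NetworkParams,
    perturbation: PerturbationSpec | None = None,
    glucose_out: float = 16.8,
) -> FullSteadyState:
    """Module-by-module algebraic steady state of the feed-forward cascade.

    Solves TFs, acetylation, target RNAs, GNT-4A, transporter pools and
    finally the metabolic balance, honoring RNA clamps, the nuclear
    exclusion factor, glycan competition and epsilon overrides.
    """
    p = params
    pert = perturbation or PerturbationSpec()
    scale = pert.import_scale
    v = np.ones(len(_FIELDS))

    for tf, gene in (("hnf1a", "HNF1A"), ("foxa2", "FOXA2")):
        rna = pert.rna_clamp.get(gene, 1.0)
        # linear steady state of the cytoplasm/nucleus pair
        a11 = p.k_prot_deg + p.k_nuc_in * scale
        a12 = -p.k_nuc_out
        a21 = -p.k_nuc_in * scale
        a22 = p.k_nuc_out + p.k_prot_deg
        b1 = p.k_translation * rna
        det = a11 * a22 - a12 * a21
        cyt = b1 * a22 / det
        nuc = -b1 * a21 / det
        v[_IDX[f"{tf}_rna"]], v[_IDX[f"{tf}_cyt"]], v[_IDX[f"{tf}_nuc"]] = rna, cyt, nuc

    n_h, n_f = v[_IDX["hnf1a_nuc"]], v[_IDX["foxa2_nuc"]]
    drive = p.k_ac * _hill(n_h, 1.0, p.hill_acetylation)
    acet = drive / (drive + p.k_deac)
    for gene, tag in (("GLUT1", "glut1"), ("GLUT2", "glut2"), ("MGAT4A", "mgat4a")):
        v[_IDX[f"acet_{tag}"]] = acet
        v[_IDX[f"rna_{tag}"]] = pert.rna_clamp.get(
            gene, promoter_activation(n_h, n_f, acet, gene, p)
        )
    v[_IDX["ctrl_rna"]] = pert.rna_clamp.get("CTRL", 1.0)

    gnt = v[_IDX["rna_mgat4a"]]
    v[_IDX["gnt4a_protein"]] = gnt
    strength = pert.competitor_strength
    for tag in ("glut1", "glut2"):
        rna = v[_IDX[f"rna_{tag}"]]
        unglyc = p.k_syn_transporter * rna / (p.k_glyc * gnt + p.k_deg_unglyc)
        glyc = p.k_glyc * gnt * unglyc / p.k_deg_glyc
        mem = (
            p.k_mem_on
            * _hill(glyc / (1.0 + strength), p.lectin_half, p.lectin_hill)
            / p.k_endo
        )
        v[_IDX[f"{tag}_unglyc"]], v[_IDX[f"{tag}_glyc"]], v[_IDX[f"{tag}_mem"]] = (
            unglyc, glyc, mem,
        )

    if pert.epsilon_override is not None:
        e1, e2 = pert.epsilon_override
    else:
        e1, e2 = v[_IDX["glut1_mem"]], v[_IDX["glut2_mem"]]
    metab = solve_steady_state(p.reduced.with_epsilons(e1, e2), glucose_out)
    v[_IDX["glucose_in"]] = metab.glucose_in
    v[_IDX["g6p_pool"]] = 0.0
    return FullSteadyState(
        state=RegulatoryState(v),
        epsilon1=float(e1),
        epsilon2=float(e2),
        glucose_in=metab.glucose_in,
        gk_rate=metab.gk_rate,
        net_flux_glut1=metab.net_flux_glut1,
        net_flux_glut2=metab.net_flux_glut2,
        glucose_out=glucose_out,
        glut1_membrane_fraction=membrane_glut1_fraction(
            e1, e2, p.healthy_glut1_share
        ),
    )


def integrate_to_steady_state(
    params: NetworkParams,
    perturbation: PerturbationSpec | None = None,
    glucose_out: float = 16.8,
    initial: RegulatoryState | None = None,
    deriv_tol: float = 1e-10,
    chunk_min: float = 2000.0,
    max_chunks: int = 40,
) -> RegulatoryState:
    """ODE route to the full steady state (independent of the algebraic one).

    The cumulative G6P pool grows without bound and is excluded from the
    stationarity test.
    """
    pert = perturbation or PerturbationSpec()
    state = initial or RegulatoryState.healthy(params)
    y = _apply_clamps(state.values.copy(), pert)
    t0 = 0.0
    g6p = _IDX["g6p_pool"]
    for _ in range(max_chunks):
        sol = solve_ivp(
            full_rhs,
            (t0, t0 + chunk_min),
            y,
            method="BDF",
            rtol=1e-10,
            atol=1e-12,
            args=(params, pert, glucose_out),
        )
        if not sol.success:
            raise RuntimeError(f"full-model integration failed: {sol.message}")
        y = sol.y[:, -1]
        t0 = float(sol.t[-1])
        dy = full_rhs(t0, y, params, pert, glucose_out)
        dy[g6p] = 0.0
        if np.max(np.abs(dy) / np.maximum(np.abs(y), 1e-3)) < deriv_tol:
            return RegulatoryState(_apply_clamps(np.clip(y, 0.0, None), pert))
    raise RuntimeError("full-model integration did not reach stationarity")
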