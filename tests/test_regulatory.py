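"""Full regulatory network: fixed point, perturbations, monotone responses."""

import numpy as np
import pytest

from betaglut import (
    GlycanCompetitor,
    NetworkParams,
    PerturbationSpec,
    RegulatoryState,
    full_rhs,
    integrate_to_steady_state,
    steady_state_full,
)
from betaglut.regulatory import (
    acetylation_rhs,
    glycosylation_rhs,
    membrane_residency_rhs,
    promoter_activation,
    tf_rhs,
)

NEUTRAL = PerturbationSpec()


def test_healthy_state_is_fixed_point(network):
    state = steady_state_full(network, NEUTRAL).state
    dy = full_rhs(0.0, state.values, network, NEUTRAL, 16.8)
    dy[-1] = 0.0  # cumulative G6P pool grows by construction
    assert np.max(np.abs(dy)) < 1e-10
    # normalization: every RNA is 1 at the healthy reference
    for name in ("hnf1a_rna", "foxa2_rna", "rna_glut1", "rna_glut2", "rna_mgat4a"):
        assert state[name] == pytest.approx(1.0, abs=1e-12)


def test_neutral_perturbation_is_identity(network):
    base = steady_state_full(network, None).state.values
    neutral = steady_state_full(
        network, PerturbationSpec(nuclear_exclusion_factor=0.0, rna_clamp={})
    ).state.values
    assert np.max(np.abs(base - neutral)) <= 1e-12


def test_nuclear_tf_monotone_in_exclusion(network):
    factors = [0.0, 0.5, 2.0, 10.0, 100.0, 1e6]
    nucs = [
        steady_state_full(network, PerturbationSpec(nuclear_exclusion_factor=f)).state[
            "hnf1a_nuc"
        ]
        for f in factors
    ]
    assert nucs[0] == pytest.approx(1.0, abs=1e-12)
    assert all(a > b for a, b in zip(nucs, nucs[1:]))
    assert nucs[-1] < 1e-4  # limit of complete exclusion


def test_tf_rhs_fixed_point_and_domain(network):
    assert tf_rhs(1.0, 1.0, 1.0, network, NEUTRAL) == pytest.approx((0.0, 0.0, 0.0))
    with pytest.raises(ValueError):
        tf_rhs(-0.1, 1.0, 1.0, network, NEUTRAL)


def test_promoter_activation_limits(network):
    a0 = network.acetylation_baseline
    assert promoter_activation(0.0, 0.0, a0, "GLUT1", network) == 0.0
    assert promoter_activation(1.0, 1.0, a0, "GLUT1", network) == pytest.approx(1.0)


def test_hnf1a_outranks_foxa2_on_promoters(network):
    """Halving nuclear HNF1A (with acetylation responding) hits transcription
    harder than halving FOXA2, because HNF1A acts on both layers."""

    def steady_multiplier(n_h, n_f):
        drive = network.k_ac * (n_h ** network.hill_acetylation) / (
            1 + n_h ** network.hill_acetylation
        )
        acet = drive / (drive + network.k_deac)
        return promoter_activation(n_h, n_f, acet, "GLUT1", network)

    assert steady_multiplier(0.5, 1.0) < steady_multiplier(1.0, 0.5)


def test_acetylation_steady_states(network):
    # no nuclear HNF1A -> acetylation decays to zero
    assert acetylation_rhs(0.0, 0.0, network) == 0.0
    assert acetylation_rhs(0.3, 0.0, network) < 0
    # healthy baseline is a fixed point
    a0 = network.acetylation_baseline
    assert acetylation_rhs(a0, 1.0, network) == pytest.approx(0.0, abs=1e-15)
    # steady acetylation increases with nuclear HNF1A
    def steady(n):
        drive = network.k_ac * (n ** network.hill_acetylation) / (
            1 + n ** network.hill_acetylation
        )
        return drive / (drive + network.k_deac)

    grid = np.linspace(0, 2, 15)
    assert np.all(np.diff([steady(n) for n in grid]) > 0)


def test_glycosylation_requires_gnt4a(network):
    # baseline fixed point
    assert glycosylation_rhs(1.0, 1.0, 1.0, 1.0, network) == pytest.approx((0.0, 0.0))
    # without the enzyme the glycosylated pool only decays
    _, d_glyc = glycosylation_rhs(1.0, 0.5, 1.0, 0.0, network)
    assert d_glyc < 0
    # steady glycosylated fraction grows with enzyme abundance
    fracs = []
    for gnt in np.linspace(0, 2, 9):
        u = network.k_syn_transporter / (network.k_glyc * gnt + network.k_deg_unglyc)
        fracs.append(network.k_glyc * gnt * u / network.k_deg_glyc)
    assert np.all(np.diff(fracs) > 0)


def test_membrane_residency_competitor_limits(network):
    # baseline fixed point
    assert membrane_residency_rhs(1.0, 1.0, network, 0.0) == pytest.approx(0.0)
    # infinite competitor strips the membrane pool
    assert membrane_residency_rhs(0.0, 1.0, network, 1e12) == pytest.approx(
        0.0, abs=1e-9
    )
    strengths = [0.0, 0.2, 0.5, 1.0, 5.0]
    mems = [
        steady_state_full(
            network, PerturbationSpec(glycan_competitor=GlycanCompetitor("x", s))
        ).epsilon1
        for s in strengths
    ]
    assert all(a > b for a, b in zip(mems, mems[1:]))


def test_nuclear_exclusion_alone_reproduces_all_t2d_alterations(network, t2d):
    """One inhibitory factor on TF translocation lowers, in one stroke,
    nuclear TFs, target RNAs, membrane transporters and glucose uptake."""
    base = steady_state_full(network, None)
    sick = steady_state_full(network, t2d)
    for name in ("hnf1a_nuc", "foxa2_nuc", "rna_glut1", "rna_glut2", "rna_mgat4a",
                 "glut1_mem", "glut2_mem"):
        assert sick.state[name] < base.state[name]
    assert sick.total_net_flux < base.total_net_flux
    assert sick.gk_rate < base.gk_rate
    assert sick.glucose_in < base.glucose_in


def test_mgat4a_clamp_abolishes_membrane_transporters(network):
    ss = steady_state_full(network, PerturbationSpec(rna_clamp={"MGAT4A": 0.0}))
    assert ss.epsilon1 == pytest.approx(0.0, abs=1e-12)
    assert ss.epsilon2 == pytest.approx(0.0, abs=1e-12)
    # GLUT RNAs are untouched: the block is purely post-translational
    assert ss.state["rna_glut1"] == pytest.approx(1.0, abs=1e-12)


def test_epsilon_override_bypasses_network(network):
    ss = steady_state_full(
        network, PerturbationSpec(epsilon_override=(0.14, 0.05))
    )
    assert ss.epsilon1 == 0.14 and ss.epsilon2 == 0.05
    assert ss.state["glut1_mem"] == pytest.approx(1.0)  # network untouched


def test_glycan_uptake_ordering_at_10mM(network):
    """Uptake at 10 mM: healthy > LacNAc > (LacNAc)3 > T2D."""
    def uptake(pert):
        return steady_state_full(network, pert, glucose_out=10.0).total_net_flux

    healthy = uptake(None)
    lacnac = uptake(PerturbationSpec(epsilon_override=(0.75, 0.80)))
    lacnac3 = uptake(PerturbationSpec(epsilon_override=(0.57, 0.48)))
    t2d = uptake(PerturbationSpec(epsilon_override=(0.14, 0.05)))
    assert healthy > lacnac > lacnac3 > t2d


def test_algebraic_steady_state_matches_ode(network, t2d):
    """Feed-forward algebraic solution equals long-time ODE integration."""
    for pert in (None, t2d):
        alg = steady_state_full(network, pert).state.values
        ode = integrate_to_steady_state(network, pert).values
        rel = np.abs(ode[:-1] - alg[:-1]) / np.maximum(np.abs(alg[:-1]), 1e-9)
        assert np.max(rel) < 1e-6


def test_full_rhs_rejects_bad_state(network):
    with pytest.raises(ValueError):
        full_rhs(0.0, np.ones(5), network, NEUTRAL, 16.8)


def test_monotone_dose_response_in_exclusion(network):
    factors = np.linspace(0, 40, 9)
    eps1, eps2, rates = [], [], []
    for f in factors:
        ss = steady_state_full(network, PerturbationSpec(nuclear_exclusion_factor=f))
        eps1.append(ss.epsilon1)
        eps2.append(ss.epsilon2)
        rates.append(ss.gk_rate)
    assert np.all(np.diff(eps1) <= 0)
    assert np.all(np.diff(eps2) <= 0)
    assert np.all(np.diff(rates) <= 0)
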