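"""Reduced transport/phosphorylation model: kinetics, steady states, excursions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betaglut import (
    CellState,
    GKKinetics,
    TransporterKinetics,
    gk_rate,
    mm_flux,
    net_transport_flux,
    reduced_rhs,
    simulate_excursion,
    solve_steady_state,
    steady_state_by_integration,
)
from betaglut.scenarios import generate_profile


@pytest.mark.parametrize(
    "vmax,km,conc,expected",
    [
        (1.0, 17.0, 0.0, 0.0),  # zero substrate
        (1.0, 17.0, 17.0, 0.5),  # half-saturation identity
        (1.588, 17.0, 16.8, 1.588 * 16.8 / 33.8),  # direct arithmetic
    ],
)
def test_mm_flux_values(vmax, km, conc, expected):
    assert mm_flux(vmax, km, conc) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [dict(km=-1.0, conc=1.0), dict(km=0.0, conc=1.0),
                                 dict(km=3.0, conc=-0.1)])
def test_mm_flux_domain_errors(bad):
    with pytest.raises(ValueError):
        mm_flux(1.0, bad["km"], bad["conc"])


def test_mm_flux_monotone_saturating():
    grid = np.linspace(0, 500, 200)
    vals = [mm_flux(2.0, 17.0, c) for c in grid]
    assert np.all(np.diff(vals) > 0)
    assert vals[-1] < 2.0


def test_gk_rate_half_saturation_and_zero():
    gk = GKKinetics(8.0, 1.7, 0.34)
    assert gk_rate(gk, 8.0) == pytest.approx(0.17, rel=1e-12)
    assert gk_rate(gk, 0.0) == 0.0
    with pytest.raises(ValueError):
        gk_rate(gk, -1.0)


def test_gk_rate_calibrated_threshold_point():
    # arithmetic oracle: 0.1696 * 6.5^1.7 / (8^1.7 + 6.5^1.7)
    gk = GKKinetics(8.0, 1.7, 0.1696)
    oracle = 0.1696 * 6.5**1.7 / (8.0**1.7 + 6.5**1.7)
    assert gk_rate(gk, 6.5) == pytest.approx(oracle, rel=1e-12)
    assert gk_rate(gk, 6.5) == pytest.approx(0.0700, abs=5e-4)


@given(
    km=st.floats(0.5, 50),
    vmax=st.floats(0, 5),
    eps=st.floats(0, 3),
    conc=st.floats(0, 30),
)
@settings(max_examples=50, derandomize=True)
def test_net_flux_zero_at_equilibrium(km, vmax, eps, conc):
    t = TransporterKinetics("GLUT2", km, vmax, eps)
    assert net_transport_flux(t, conc, conc) == 0.0


def test_net_flux_threshold_scenario_matches_arithmetic():
    glut2 = TransporterKinetics("GLUT2", 17.0, 1.588, 0.2)
    oracle = 0.2 * 1.588 * (16.8 / 33.8 - 6.5 / 23.5)
    assert net_transport_flux(glut2, 16.8, 6.5) == pytest.approx(oracle, rel=1e-12)
    assert net_transport_flux(glut2, 16.8, 6.5) == pytest.approx(0.0700, abs=2e-4)


def test_net_flux_zero_transporter():
    t = TransporterKinetics("GLUT1", 3.0, 0.47, 0.0)
    assert net_transport_flux(t, 16.8, 1.0) == 0.0


def test_reduced_rhs_signs(params):
    ss = solve_steady_state(params, 16.8)
    d_gi, d_g6p = reduced_rhs(CellState(ss.glucose_in), params, 16.8)
    assert d_gi == pytest.approx(0.0, abs=1e-9)
    assert d_g6p > 0
    # no transporters: pure consumption
    starved = params.with_epsilons(0.0, 0.0)
    d_gi, _ = reduced_rhs(CellState(5.0), starved, 16.8)
    assert d_gi < 0
    # healthy cell at low internal glucose takes glucose up
    d_gi, _ = reduced_rhs(CellState(2.0), params, 16.8)
    assert d_gi > 0


def test_steady_state_degenerate_no_transporters(params):
    ss = solve_steady_state(params.with_epsilons(0.0, 0.0), 16.8)
    assert ss.glucose_in == 0.0 and ss.gk_rate == 0.0


def test_steady_state_threshold_and_healthy_anchors(params):
    thr = solve_steady_state(params.with_epsilons(0.0, 0.2), 16.8)
    assert thr.glucose_in == pytest.approx(6.5, abs=1e-6)
    assert thr.gk_rate == pytest.approx(0.07, abs=1e-6)
    healthy = solve_steady_state(params, 16.8)
    assert healthy.gk_rate == pytest.approx(0.12, rel=0.05)


@given(
    e1=st.floats(0.01, 2.0),
    e2=st.floats(0.01, 2.0),
    go=st.floats(1.0, 25.0),
)
@settings(max_examples=40, derandomize=True, deadline=None)
def test_steady_state_bounds(params, e1, e2, go):
    """Consumption keeps the steady cell strictly below diffusive equilibrium."""
    ss = solve_steady_state(params.with_epsilons(e1, e2), go)
    assert 0.0 < ss.glucose_in < go
    assert ss.gk_rate == pytest.approx(ss.total_net_flux, rel=1e-8)


def test_steady_state_monotone_in_expression_and_glucose(params):
    rates = [
        solve_steady_state(params.with_epsilons(e1, 0.3), 16.8).gk_rate
        for e1 in np.linspace(0, 1, 9)
    ]
    assert np.all(np.diff(rates) >= 0)
    rates = [
        solve_steady_state(params.with_epsilons(0.3, e2), 16.8).gk_rate
        for e2 in np.linspace(0, 1, 9)
    ]
    assert np.all(np.diff(rates) >= 0)
    rates = [
        solve_steady_state(params, go).gk_rate for go in np.linspace(1, 25, 9)
    ]
    assert np.all(np.diff(rates) >= 0)


def test_steady_state_volume_invariant(calibrated):
    base = calibrated.to_reduced_params(volume_per_1e5_cells=1e-8)
    ref = solve_steady_state(base, 16.8)
    for vol in (1e-7, 1e-6):
        other = solve_steady_state(
            calibrated.to_reduced_params(volume_per_1e5_cells=vol), 16.8
        )
        assert other.glucose_in == pytest.approx(ref.glucose_in, rel=1e-9)
        assert other.gk_rate == pytest.approx(ref.gk_rate, rel=1e-9)


def test_integration_agrees_with_root_solver(params):
    for e1, e2, go in [(1, 1, 16.8), (0.14, 0.05, 16.8), (0, 0.2, 16.8), (0.5, 0.5, 5.0)]:
        p = params.with_epsilons(e1, e2)
        assert steady_state_by_integration(p, go).glucose_in == pytest.approx(
            solve_steady_state(p, go).glucose_in, abs=1e-6
        )


def test_excursion_flat_at_rest(params):
    profile = generate_profile("constant", [2.8])
    df = simulate_excursion(params, profile, 60.0)
    assert df["glucose_in_mM"].std() < 1e-6
    assert df["net_flux_glut1"].abs().max() < 1e-8 + df["net_flux_glut1"].abs().min() * 1.01


def test_excursion_step_settles_at_new_steady_state(params):
    profile = generate_profile("step", [2.8, 16.8], [10.0])
    df = simulate_excursion(params, profile, 400.0)
    target = solve_steady_state(params, 16.8).glucose_in
    assert df["glucose_in_mM"].iloc[-1] == pytest.approx(target, abs=1e-4)
    assert target == pytest.approx(13.0, abs=0.01)
    # g6p pool is cumulative
    assert (np.diff(df["g6p_mM"]) >= -1e-12).all()
    # net flux rises after the step then relaxes toward a lower steady level
    post = df[df["time_min"] > 10.0]
    peak = post["net_flux_glut2"].max()
    assert peak > post["net_flux_glut2"].iloc[-1] > 0


def test_excursion_t2d_below_healthy(params):
    profile = generate_profile("step", [2.8, 16.8], [10.0])
    healthy = simulate_excursion(params, profile, 300.0)
    t2d = simulate_excursion(params.with_epsilons(0.14, 0.05), profile, 300.0)
    assert t2d["glucose_in_mM"].iloc[-1] < healthy["glucose_in_mM"].iloc[-1]
    assert t2d["gk_rate"].iloc[-1] < healthy["gk_rate"].iloc[-1]
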