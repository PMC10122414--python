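"""Slab biosphere: flux laws, closed-form steady states, conservation."""

import numpy as np
import pytest

from erwbox.slab import (SlabParams, SlabState, integrate_offline, litterfall,
                         npp, slab_step, soil_respiration, steady_state,
                         turnover_time)


def test_npp_reference_and_limits():
    p = SlabParams(n0=50.0, b=0.6)
    assert float(npp(p.c0, p)) == pytest.approx(50.0)
    assert float(npp(2 * p.c0, p)) == pytest.approx(50.0 * (1 + 0.6 * np.log(2.0)))
    p0 = SlabParams(n0=50.0, b=0.0)
    for c in (100.0, 278.0, 900.0):
        assert float(npp(c, p0)) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        npp(-1.0, p)


def test_npp_clipped_at_zero():
    p = SlabParams(n0=50.0, b=1.0)
    assert float(npp(1.0, p)) == 0.0  # ln(1/278) drives N negative


def test_litterfall_limits_and_steady_state():
    p = SlabParams(n0=50.0, lambda_veg=0.002, lambda_0=10.0)
    assert float(litterfall(0.0, p)) == 0.0
    p_fixed = SlabParams(lambda_veg=0.0, lambda_0=10.0)
    assert float(litterfall(123.0, p_fixed)) == pytest.approx(12.3)
    v_star, _ = steady_state(p)
    assert float(v_star) == pytest.approx(500.0 / 0.9)  # N0*L0/(1 - N0*Lveg)


def test_soil_respiration_q10():
    p = SlabParams(gamma=0.03, q10=2.0)
    assert float(soil_respiration(1500.0, p.t0, p)) == pytest.approx(45.0)
    assert float(soil_respiration(1500.0, p.t0 + 10.0, p)) == pytest.approx(90.0)
    _, s_star = steady_state(SlabParams(n0=50.0, gamma=0.025))
    assert float(s_star) == pytest.approx(2000.0)  # N0/Gamma


def test_steady_states_recovered_by_integration():
    """Integrating from arbitrary positive pools at (C0, T0) converges to
    the closed-form fixed point to 1e-6 relative."""
    p = SlabParams(n0=55.0, b=0.5, lambda_veg=0.003, lambda_0=12.0,
                   gamma=0.04, q10=2.5)
    v_star, s_star = steady_state(p)
    state = SlabState(v=np.array([10.0]), s=np.array([5000.0]))
    for _ in range(20000):  # 2000 yr at dt = 0.1
        state, _ = slab_step(state, p.c0, p.t0, p, 0.1)
    assert float(state.v[0]) == pytest.approx(float(v_star), rel=1e-6)
    assert float(state.s[0]) == pytest.approx(float(s_star), rel=1e-6)


def test_land_carbon_conservation():
    """Delta(V + S) over any interval equals -integral of J_lnd-air exactly."""
    p = SlabParams()
    state = SlabState(v=np.array([450.0]), s=np.array([1400.0]))
    rng = np.random.default_rng(0)
    total_flux = 0.0
    v0, s0 = float(state.v[0]), float(state.s[0])
    for _ in range(500):
        c = rng.uniform(280, 800)
        t = rng.uniform(-1, 6)
        state, j = slab_step(state, c, t, p, 0.1)
        total_flux += float(j[0]) * 0.1
    assert (float(state.v[0]) + float(state.s[0])) - (v0 + s0) \
        == pytest.approx(-total_flux, abs=1e-9)


def test_step_response_signs():
    """CO2 step -> initial land uptake; warming step -> initial soil release."""
    p = SlabParams()
    v_star, s_star = steady_state(p)
    eq = SlabState(v=np.asarray(v_star), s=np.asarray(s_star))
    _, j_eq = slab_step(eq, p.c0, p.t0, p, 0.01)
    assert abs(float(j_eq)) < 1e-8
    _, j_co2 = slab_step(eq, 2 * p.c0, p.t0, p, 0.01)
    assert float(j_co2) < 0  # uptake
    _, j_warm = slab_step(eq, p.c0, p.t0 + 3.0, p, 0.01)
    assert float(j_warm) > 0  # soil release


def test_parameter_validation():
    with pytest.raises(ValueError):
        SlabParams(n0=-1.0)
    with pytest.raises(ValueError):
        SlabParams(n0=200.0, lambda_veg=0.01)  # N0*Lveg >= 1


def test_offline_integration_shapes_and_turnover():
    p = SlabParams(n0=np.array([50.0, 60.0]), b=np.array([0.5, 0.7]))
    years = np.arange(2000.0, 2021.0)
    co2 = np.linspace(370, 412, years.size)
    t_land = np.linspace(0.6, 1.2, years.size)
    out = integrate_offline(p, years, co2, t_land)
    assert out["v"].shape == (2, years.size)
    np.testing.assert_allclose(out["turnover"][:, -1],
                               turnover_time(out["v"][:, -1], p))
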