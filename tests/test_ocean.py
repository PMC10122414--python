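"""Box-ocean components: transport, biological pump, burial, gas exchange."""

import numpy as np
import pytest

from erwbox.carbonate import solve_speciation
from erwbox.constants import MOL_PER_GTC, SV_TO_M3_PER_YEAR, OCEAN_VOLUME
from erwbox.fixtures import two_box_setup
from erwbox.ocean import (BioPumpConfig, GasExchangeConfig, OceanState,
                          SedimentConfig, biological_pump_step, burial_step,
                          default_circulation, default_geometry, gas_exchange,
                          transport_stability_bound, transport_step)


@pytest.fixture
def geometry():
    return default_geometry()


@pytest.fixture
def circulation():
    return default_circulation()


def uniform_state(geometry, dic=2250e-6, alk=2400e-6, po4=2.15e-6):
    m = geometry.mass
    return OceanState(dic=dic * m, alk=alk * m, po4=po4 * m)


def test_geometry_invariants(geometry):
    assert abs(geometry.volume.sum() / OCEAN_VOLUME - 1) < 0.1
    assert geometry.area[geometry.surface].sum() == pytest.approx(3.61e14, rel=0.02)
    assert np.all(geometry.volume > 0)


def test_uniform_concentration_is_transport_fixed_point(geometry, circulation):
    state = uniform_state(geometry)
    new = transport_step(state, geometry, circulation, 0.1)
    np.testing.assert_allclose(new.dic / geometry.mass, state.dic / geometry.mass,
                               rtol=1e-13)


def test_transport_conserves_tracers(geometry, circulation):
    rng = np.random.default_rng(5)
    m = geometry.mass
    state = OceanState(dic=rng.uniform(1900e-6, 2400e-6, 4) * m,
                       alk=rng.uniform(2200e-6, 2500e-6, 4) * m,
                       po4=rng.uniform(0.1e-6, 3e-6, 4) * m)
    total0 = (state.dic.sum(), state.alk.sum(), state.po4.sum())
    for _ in range(200):
        state = transport_step(state, geometry, circulation, 0.1)
    for before, after in zip(total0, (state.dic.sum(), state.alk.sum(), state.po4.sum())):
        assert after == pytest.approx(before, rel=1e-12)
    assert np.all(state.dic > 0)


def test_transport_dt_above_stability_bound_raises(geometry, circulation):
    bound = transport_stability_bound(geometry, circulation)
    with pytest.raises(ValueError, match="stability bound"):
        transport_step(uniform_state(geometry), geometry, circulation, 2 * bound)


def test_two_box_exchange_matches_analytic_exponential():
    """Pure mixing between two boxes: the concentration difference decays
    as exp(-q (1/V1 + 1/V2) t) — closed form of the 2x2 linear system."""
    geometry, circulation = two_box_setup(exchange_sv=20.0)
    m = geometry.mass
    c = np.array([2400e-6, 2200e-6])
    state = OceanState(dic=c * m, alk=2400e-6 * m, po4=2e-6 * m)
    q = 20.0 * SV_TO_M3_PER_YEAR
    rate = q * (1.0 / geometry.volume[0] + 1.0 / geometry.volume[1])
    dt, n = 0.05, 2000  # 100 yr
    for _ in range(n):
        state = transport_step(state, geometry, circulation, dt)
    conc = state.dic / m
    d0 = c[0] - c[1]
    d_expected = d0 * np.exp(-rate * n * dt)
    assert conc[0] - conc[1] == pytest.approx(d_expected, rel=5e-3)


def test_bio_pump_trivial_cases(geometry):
    state = uniform_state(geometry)
    no_rain = BioPumpConfig(rain_ratio=0.0)
    new, caco3 = biological_pump_step(state.copy(), geometry, no_rain, 0.1)
    np.testing.assert_allclose(new.alk, state.alk)  # no CaCO3, no ALK change
    assert float(np.asarray(caco3)) == 0.0

    empty = uniform_state(geometry, po4=0.0)
    new, caco3 = biological_pump_step(empty.copy(), geometry, BioPumpConfig(), 0.1)
    np.testing.assert_allclose(new.dic, empty.dic)
    assert float(np.asarray(caco3)) == 0.0


def test_bio_pump_conserves_carbon_and_phosphate(geometry):
    state = uniform_state(geometry)
    new, _ = biological_pump_step(state, geometry, BioPumpConfig(), 0.1)
    assert new.dic.sum() == pytest.approx(state.dic.sum(), rel=1e-12)
    assert new.po4.sum() == pytest.approx(state.po4.sum(), rel=1e-12)
    assert np.all(new.po4 >= 0)


def test_spun_state_has_observed_vertical_dic_gradient(world, spun):
    """Steady circulation + pump produce surface DIC below deep DIC."""
    conc = spun.ocean.dic / world.config.geometry.mass
    assert conc[0] < conc[3]
    assert conc[1] < conc[3]
    # and a surface-depleted nutrient field
    po4 = spun.ocean.po4 / world.config.geometry.mass
    assert po4[0] < po4[3]


def test_burial_zero_when_undersaturated(geometry):
    state = uniform_state(geometry, dic=2400e-6, alk=2380e-6)  # deep: low CO3
    temps = geometry.temperatures(0.0)
    sed = SedimentConfig(sediment_pressure_bar=600.0)
    cs = solve_speciation(2400e-6, 2380e-6, temps[3], geometry.salinity, 600.0)
    assert float(cs.omega_cal) < 1.0
    _, buried, _ = burial_step(state, geometry, sed, temps, 0.1)
    assert float(np.asarray(buried)) == 0.0


def test_burial_balances_weathering_at_spinup(world, spun):
    """Open-system steady state: |weathering - burial| / weathering < 1e-3."""
    cfg = world.config
    temps = cfg.geometry.temperatures(0.0)
    _, buried, _ = burial_step(spun.ocean, cfg.geometry, cfg.sediment, temps, 1.0)
    burial_rate = float(np.asarray(buried))
    assert abs(spun.weathering_mol_per_yr - burial_rate) / spun.weathering_mol_per_yr < 1e-3
    # magnitude plausible for deep-sea CaCO3 burial
    assert 0.05 < burial_rate / MOL_PER_GTC < 0.4


def test_gas_exchange_zero_at_equilibrium_and_linear():
    geometry, _ = two_box_setup()
    state = OceanState(dic=2050e-6 * geometry.mass, alk=2350e-6 * geometry.mass,
                       po4=2e-6 * geometry.mass)
    temps = geometry.temperatures(0.0)
    gas = GasExchangeConfig()
    pco2_oc = float(solve_speciation(2050e-6, 2350e-6, temps[0], geometry.salinity).pco2)
    _, f0, _ = gas_exchange(state.copy(), geometry, gas, pco2_oc, temps, 1e-6)
    assert float(np.asarray(f0)) == pytest.approx(0.0, abs=1e-3)
    # doubling the disequilibrium doubles the instantaneous flux (linearity)
    _, f1, _ = gas_exchange(state.copy(), geometry, gas, pco2_oc - 10.0, temps, 1e-6)
    _, f2, _ = gas_exchange(state.copy(), geometry, gas, pco2_oc - 20.0, temps, 1e-6)
    assert float(np.asarray(f2)) == pytest.approx(2 * float(np.asarray(f1)), rel=1e-9)


def test_perturbed_mixed_layer_relaxes_exponentially():
    """A surface box perturbed by +100 umol/kg DIC at fixed ALK relaxes
    monotonically toward equilibrium at the linearized e-folding rate."""
    geometry, _ = two_box_setup()
    gas = GasExchangeConfig()
    temps = geometry.temperatures(0.0)
    m = geometry.mass
    alk = 2350e-6
    dic_eq = 2050e-6
    atm = float(solve_speciation(dic_eq, alk, temps[0], geometry.salinity).pco2)
    state = OceanState(dic=np.array([dic_eq + 100e-6, 2250e-6]) * m,
                       alk=alk * m, po4=2e-6 * m)
    # linearized relaxation rate: kw*K0*rho*area*(dpCO2/dDIC)/mass
    eps = 1e-6
    dpdd = (float(solve_speciation(dic_eq + 100e-6 + eps, alk, temps[0],
                                   geometry.salinity).pco2)
            - float(solve_speciation(dic_eq + 100e-6 - eps, alk, temps[0],
                                     geometry.salinity).pco2)) / (2 * eps)
    from erwbox.carbonate import equilibrium_constants
    from erwbox.constants import SEAWATER_DENSITY
    k0 = float(equilibrium_constants(temps[0], geometry.salinity).k0)
    rate = (gas.piston_velocity_m_per_yr * k0 * SEAWATER_DENSITY
            * geometry.area[0] * dpdd * 1e-6) / m[0]
    dt = 0.02
    excess = [state.dic[0] / m[0] - dic_eq]
    for _ in range(100):  # 2 yr
        state, _, _ = gas_exchange(state, geometry, gas, atm, temps, dt)
        excess.append(state.dic[0] / m[0] - dic_eq)
    excess = np.array(excess)
    assert np.all(np.diff(excess) < 0)  # monotone relaxation
    measured_rate = -np.log(excess[25] / excess[0]) / (25 * dt)
    assert measured_rate == pytest.approx(rate, rel=0.3)
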