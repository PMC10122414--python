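"""Carbonate-system solver: oracle comparison, invariants, limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erwbox.carbonate import (CarbonateError, calcium_from_salinity,
                              equilibrium_constants, saturation_state,
                              solve_speciation)


def bisection_oracle(dic, alk, temperature, salinity, pressure=0.0, n_iter=80):
    """Independent solver: plain bisection on total-scale pH over [2, 12],
    evaluating the alkalinity residual directly (no Newton machinery)."""
    k = equilibrium_constants(temperature, salinity, pressure)
    lo, hi = 2.0, 12.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        h = 10.0 ** (-mid)
        denom = h * h + k.k1 * h + k.k1 * k.k2
        hco3 = dic * k.k1 * h / denom
        co3 = dic * k.k1 * k.k2 / denom
        ta = hco3 + 2 * co3 + k.bt * k.kb / (k.kb + h) + k.kw / h - h
        if ta > alk:  # TA increases with pH, so the root lies below mid
            hi = mid
        else:
            lo = mid
    ph = 0.5 * (lo + hi)
    h = 10.0 ** (-ph)
    denom = h * h + k.k1 * h + k.k1 * k.k2
    hco3 = dic * k.k1 * h / denom
    co3 = dic * k.k1 * k.k2 / denom
    pco2 = (dic - hco3 - co3) / k.k0 * 1e6
    return ph, pco2, co3


def random_state_grid(n=1000, seed=7):
    rng = np.random.default_rng(seed)
    dic = rng.uniform(1800e-6, 2400e-6, n)
    alk = dic + rng.uniform(100e-6, 450e-6, n)  # realistic ALK-DIC offsets
    t = rng.uniform(-1.0, 30.0, n)
    s = rng.uniform(31.0, 37.0, n)
    p = rng.choice([0.0, 100.0, 300.0], n)
    return dic, alk, t, s, p


def test_solver_matches_bisection_oracle_on_grid():
    """pCO2 agrees with the independent bisection solve to 0.1% over a
    1000-point grid spanning open-ocean conditions."""
    dic, alk, t, s, p = random_state_grid()
    cs = solve_speciation(dic, alk, t, s, p)
    for i in range(dic.size):
        ph_o, pco2_o, co3_o = bisection_oracle(dic[i], alk[i], t[i], s[i], p[i])
        assert cs.pco2[i] == pytest.approx(pco2_o, rel=1e-3)
        assert cs.ph[i] == pytest.approx(ph_o, abs=1e-6)


def test_reference_surface_state_against_oracle():
    """The canonical surface state (DIC 2050, ALK 2350 umol/kg, 15C, S 35)."""
    cs = solve_speciation(2050e-6, 2350e-6, 15.0, 35.0)
    _, pco2_o, _ = bisection_oracle(2050e-6, 2350e-6, 15.0, 35.0)
    assert float(cs.pco2) == pytest.approx(pco2_o, rel=1e-3)
    # plausibility: a slightly cool surface ocean is near atmospheric pCO2
    assert 150 < float(cs.pco2) < 500
    assert 7.9 < float(cs.ph) < 8.4


def test_zero_dic_limit():
    cs = solve_speciation(0.0, 500e-6, 15.0, 35.0)
    assert float(cs.pco2) == 0.0
    assert float(cs.co3) == 0.0


def test_dic_mass_balance_and_alkalinity_roundtrip():
    dic, alk, t, s, p = random_state_grid(200, seed=11)
    cs = solve_speciation(dic, alk, t, s, p)
    np.testing.assert_allclose(cs.co2aq + cs.hco3 + cs.co3, dic, rtol=1e-10)
    np.testing.assert_allclose(cs.recompute_alkalinity(), alk, rtol=1e-8)


def test_pco2_monotonic_in_dic_and_alk():
    """dpCO2/dDIC > 0 at fixed ALK; dpCO2/dALK < 0 at fixed DIC."""
    alk = 2350e-6
    dic_grid = np.linspace(1850e-6, 2330e-6, 40)
    pco2 = solve_speciation(dic_grid, alk, 18.0, 35.0).pco2
    assert np.all(np.diff(pco2) > 0)
    dic = 2100e-6
    alk_grid = np.linspace(2150e-6, 2600e-6, 40)
    pco2 = solve_speciation(dic, alk_grid, 18.0, 35.0).pco2
    assert np.all(np.diff(pco2) < 0)


def test_carbonate_dissolution_lowers_pco2():
    """Adding 2 eq ALK + 1 mol DIC per mol (dissolving CaCO3 into seawater)
    lowers pCO2."""
    base = solve_speciation(2100e-6, 2350e-6, 18.0, 35.0)
    added = solve_speciation(2100e-6 + 50e-6, 2350e-6 + 100e-6, 18.0, 35.0)
    assert float(added.pco2) < float(base.pco2)


def test_omega_ratio_consistency():
    """omega_cal / omega_arg equals Ksp_arag / Ksp_cal exactly."""
    dic, alk, t, s, p = random_state_grid(50, seed=3)
    cs = solve_speciation(dic, alk, t, s, p)
    k = equilibrium_constants(t, s, p)
    np.testing.assert_allclose(cs.omega_cal / cs.omega_arg, k.ksp_arag / k.ksp_cal,
                               rtol=1e-12)


def test_saturation_state_definition():
    assert saturation_state(0.0, 0.0103, 25.0, 35.0) == 0.0
    k = equilibrium_constants(25.0, 35.0)
    co3_at_sat = k.ksp_arag / 0.0103
    assert saturation_state(co3_at_sat, 0.0103, 25.0, 35.0, mineral="aragonite") \
        == pytest.approx(1.0, rel=1e-12)
    # independent check value: Mucci (1983) log10 Ksp_arag(S=35, 25C) = -6.1883
    omega = saturation_state(200e-6, 10.28e-3, 25.0, 35.0, mineral="aragonite")
    assert float(omega) == pytest.approx(200e-6 * 10.28e-3 / 10 ** -6.1883, rel=5e-3)


def test_calcium_conservative_with_salinity():
    assert calcium_from_salinity(35.0) == pytest.approx(0.01028)
    assert calcium_from_salinity(17.5) == pytest.approx(0.00514)


@pytest.mark.parametrize("kwargs", [
    dict(dic=-1e-6, alk=2300e-6, temperature=15.0, salinity=35.0),
    dict(dic=2000e-6, alk=2300e-6, temperature=15.0, salinity=55.0),
    dict(dic=2000e-6, alk=2300e-6, temperature=45.0, salinity=35.0),
    dict(dic=2000e-6, alk=-0.5, temperature=15.0, salinity=35.0),  # not bracketed
])
def test_unphysical_inputs_raise(kwargs):
    with pytest.raises(CarbonateError):
        solve_speciation(**kwargs)


def test_unknown_mineral_raises():
    with pytest.raises(CarbonateError):
        saturation_state(200e-6, 0.0103, 25.0, 35.0, mineral="vaterite")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    dic=st.floats(500e-6, 3000e-6),
    offset=st.floats(50e-6, 600e-6),
    t=st.floats(-1.5, 35.0),
    s=st.floats(20.0, 40.0),
)
def test_solution_satisfies_alkalinity_balance(dic, offset, t, s):
    """Property: at the solution, carbonate + borate + water alkalinity
    reproduces the input alkalinity and the species sum to DIC."""
    alk = dic + offset
    cs = solve_speciation(dic, alk, t, s)
    assert float(cs.recompute_alkalinity()) == pytest.approx(alk, rel=1e-8)
    assert float(cs.co2aq + cs.hco3 + cs.co3) == pytest.approx(dic, rel=1e-10)
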