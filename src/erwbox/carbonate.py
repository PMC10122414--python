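"""Seawater inorganic carbon system.

Solves the CO2 system from dissolved inorganic carbon (DIC) and total
alkalinity, returning pCO2, pH (total scale), carbonate ion, and
carbonate-mineral saturation states.

The alkalinity balance includes the carbonate, borate, and water
contributions:

    TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]

Phosphate and silicate alkalinity are omitted; at open-ocean
concentrations their contribution is below one percent of TA and far
below the precision relevant to the box-model application.

Equilibrium-constant formulations (selectable through
:func:`equilibrium_constants`, default set ``"lueker2000"``):

* K0   — Weiss (1974) CO2 solubility
* K1,K2 — Lueker, Dickson & Keeling (2000), total pH scale
* KB   — Dickson (1990)
* Kw   — Millero (1995), DOE handbook form
* Ksp  — Mucci (1983) for calcite and aragonite
* Pressure corrections — Millero (1995) molal-volume form

All constants are on the total hydrogen-ion scale, in mol/kg-seawater,
so no pH-scale conversions are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CarbonateState",
    "CarbonateError",
    "EquilibriumConstants",
    "equilibrium_constants",
    "solve_speciation",
    "saturation_state",
    "calcium_from_salinity",
    "alkalinity_residual",
]

R_GAS_CM3_BAR = 83.14472  # cm^3 bar / (mol K)

PH_LO, PH_HI = 2.0, 12.0


class CarbonateError(ValueError):
    """Raised when the carbonate-system solve cannot converge.

    Carries the offending inputs so failures deep inside a long
    integration are diagnosable.
    """

    def __init__(self, message, **inputs):
        self.inputs = inputs
        detail = ", ".join(f"{k}={v!r}" for k, v in inputs.items())
        super().__init__(f"{message} [{detail}]" if detail else message)


def calcium_from_salinity(salinity):
    """Conservative seawater calcium, mol/kg: Ca = 0.01028 * S / 35."""
    return 0.01028 * np.asarray(salinity, dtype=float) / 35.0


def total_boron(salinity):
    """Total boron (Uppstrom 1974), mol/kg: 0.000416 * S / 35."""
    return 0.000416 * np.asarray(salinity, dtype=float) / 35.0


@dataclass
class EquilibriumConstants:
    """Thermodynamic constants of the CO2 system at given T, S, P."""

    k0: np.ndarray  # mol/kg/atm
    k1: np.ndarray
    k2: np.ndarray
    kb: np.ndarray
    kw: np.ndarray
    ksp_cal: np.ndarray  # mol^2/kg^2
    ksp_arag: np.ndarray
    bt: np.ndarray  # total boron, mol/kg
    formulation: str = "lueker2000"


def _pressure_factor(a0, a1, a2, b0, b1, tc, tk, p_bar):
    """ln(K_P/K_0) from the Millero (1995) molal volume/compressibility fit."""
    dv = a0 + a1 * tc + a2 * tc * tc
    dk = (b0 + b1 * tc) * 1.0e-3
    return (-dv + 0.5 * dk * p_bar) * p_bar / (R_GAS_CM3_BAR * tk)


def equilibrium_constants(temperature, salinity, pressure=0.0, formulation="lueker2000"):
    """Evaluate the equilibrium-constant set at T (degC), S, P (bar).

    ``formulation`` selects the K1/K2 fit; only ``"lueker2000"`` ships,
    but the key is threaded through configs so an alternative set can be
    registered without touching callers.
    """
    if formulation != "lueker2000":
        raise CarbonateError("unknown constant formulation", formulation=formulation)
    tc = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    p = np.asarray(pressure, dtype=float)
    tk = tc + 273.15
    sqrt_s = np.sqrt(s)

    # Weiss 1974, mol/kg/atm (pressure-independent at box-model accuracy)
    ln_k0 = (
        -60.2409
        + 93.4517 * (100.0 / tk)
        + 23.3585 * np.log(tk / 100.0)
        + s * (0.023517 - 0.023656 * (tk / 100.0) + 0.0047036 * (tk / 100.0) ** 2)
    )
    k0 = np.exp(ln_k0)

    # Lueker et al. 2000, total scale
    pk1 = 3633.86 / tk - 61.2172 + 9.67770 * np.log(tk) - 0.011555 * s + 0.0001152 * s * s
    pk2 = 471.78 / tk + 25.9290 - 3.16967 * np.log(tk) - 0.01781 * s + 0.0001122 * s * s
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # Dickson 1990
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s * sqrt_s - 0.0996 * s * s) / tk
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * s
        - (24.4344 + 25.085 * sqrt_s + 0.2474 * s) * np.log(tk)
        + 0.053105 * sqrt_s * tk
    )
    kb = np.exp(ln_kb)

    # Millero 1995 (DOE handbook)
    ln_kw = (
        148.9652
        - 13847.26 / tk
        - 23.6521 * np.log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * np.log(tk)) * sqrt_s
        - 0.01615 * s
    )
    kw = np.exp(ln_kw)

    # Mucci 1983
    log_ksp_cal = (
        -171.9065
        - 0.077993 * tk
        + 2839.319 / tk
        + 71.595 * np.log10(tk)
        + (-0.77712 + 0.0028426 * tk + 178.34 / tk) * sqrt_s
        - 0.07711 * s
        + 0.0041249 * s * sqrt_s
    )
    log_ksp_arag = (
        -171.945
        - 0.077993 * tk
        + 2903.293 / tk
        + 71.595 * np.log10(tk)
        + (-0.068393 + 0.0017276 * tk + 88.135 / tk) * sqrt_s
        - 0.10018 * s
        + 0.0059415 * s * sqrt_s
    )
    ksp_cal = 10.0 ** log_ksp_cal
    ksp_arag = 10.0 ** log_ksp_arag

    if np.any(p > 0):
        k1 = k1 * np.exp(_pressure_factor(-25.50, 0.1271, 0.0, -3.08, 0.0877, tc, tk, p))
        k2 = k2 * np.exp(_pressure_factor(-15.82, -0.0219, 0.0, 1.13, -0.1475, tc, tk, p))
        kb = kb * np.exp(_pressure_factor(-29.48, 0.1622, -2.608e-3, -2.84, 0.0, tc, tk, p))
        kw = kw * np.exp(_pressure_factor(-20.02, 0.1119, -1.409e-3, -5.13, 0.0794, tc, tk, p))
        ksp_cal = ksp_cal * np.exp(_pressure_factor(-48.76, 0.5304, 0.0, -11.76, 0.3692, tc, tk, p))
        ksp_arag = ksp_arag * np.exp(_pressure_factor(-46.00, 0.5304, 0.0, -11.76, 0.3692, tc, tk, p))

    return EquilibriumConstants(
        k0=k0, k1=k1, k2=k2, kb=kb, kw=kw,
        ksp_cal=ksp_cal, ksp_arag=ksp_arag,
        bt=total_boron(s), formulation=formulation,
    )


@dataclass
class CarbonateState:
    """Full CO2-system speciation at given DIC and alkalinity.

    Inputs are mol/kg (DIC), mol-eq/kg (alkalinity), degC, practical
    salinity, bar; outputs are total-scale pH, pCO2 (uatm), species
    concentrations (mol/kg) and the calcite/aragonite saturation states.
    """

    dic: np.ndarray
    alk: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    pressure: np.ndarray
    ph: np.ndarray = field(default=None)
    pco2: np.ndarray = field(default=None)
    co2aq: np.ndarray = field(default=None)
    hco3: np.ndarray = field(default=None)
    co3: np.ndarray = field(default=None)
    omega_cal: np.ndarray = field(default=None)
    omega_arg: np.ndarray = field(default=None)

    def recompute_alkalinity(self, constants=None):
        """Alkalinity implied by the solved pH (round-trip diagnostic)."""
        if constants is None:
            constants = equilibrium_constants(self.temperature, self.salinity, self.pressure)
        h = 10.0 ** (-self.ph)
        return _alk_of_h(h, self.dic, constants)[0]


def _alk_of_h(h, dic, k):
    """Alkalinity and carbonate species at hydrogen-ion concentration h."""
    denom = h * h + k.k1 * h + k.k1 * k.k2
    hco3 = dic * k.k1 * h / denom
    co3 = dic * k.k1 * k.k2 / denom
    borate = k.bt * k.kb / (k.kb + h)
    alk = hco3 + 2.0 * co3 + borate + k.kw / h - h
    return alk, hco3, co3


def alkalinity_residual(ph, dic, alk, constants):
    """TA(pH; DIC) - TA. Root in pH defines the speciation solution."""
    h = 10.0 ** (-np.asarray(ph, dtype=float))
    return _alk_of_h(h, np.asarray(dic, dtype=float), constants)[0] - alk


def _dalk_dh(h, dic, k):
    denom = h * h + k.k1 * h + k.k1 * k.k2
    dhco3 = dic * k.k1 * (k.k1 * k.k2 - h * h) / denom**2
    dco3 = -dic * k.k1 * k.k2 * (2.0 * h + k.k1) / denom**2
    dborate = -k.bt * k.kb / (k.kb + h) ** 2
    return dhco3 + 2.0 * dco3 + dborate - k.kw / h**2 - 1.0


def solve_speciation(
    dic,
    alk,
    temperature,
    salinity,
    pressure=0.0,
    *,
    constants=None,
    ph_guess=None,
    ph_tol=1.0e-10,
    max_iter=50,
    formulation="lueker2000",
):
    """Solve the seawater CO2 system for given DIC and total alkalinity.

    Parameters are broadcast against each other; DIC/ALK in mol/kg and
    mol-eq/kg. Returns a :class:`CarbonateState`. The solve is a
    safeguarded Newton iteration on pH within the bracket [2, 12]
    (falling back to bisection steps whenever Newton leaves the
    bracket), converged to ``ph_tol`` pH units — well inside the 1e-8
    contract. Deterministic for fixed inputs.

    Raises
    ------
    CarbonateError
        If inputs are unphysical or the root is not bracketed by
        pH in [2, 12] (alkalinity outside the representable range).
    """
    dic, alk, temperature, salinity, pressure = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (dic, alk, temperature, salinity, pressure))
    )
    dic = dic.copy()
    if np.any(dic < 0):
        raise CarbonateError("DIC must be non-negative", dic=dic[dic < 0][:5])
    if np.any((salinity <= 0) | (salinity >= 50)):
        raise CarbonateError("salinity outside (0, 50)", salinity=np.unique(salinity)[:5])
    if np.any((temperature < -2) | (temperature > 40)):
        raise CarbonateError(
            "temperature outside [-2, 40] degC", temperature=np.unique(temperature)[:5]
        )
    if constants is None:
        constants = equilibrium_constants(temperature, salinity, pressure, formulation)
    k = constants

    h_lo = np.full(dic.shape, 10.0**-PH_HI)
    h_hi = np.full(dic.shape, 10.0**-PH_LO)
    r_lo = _alk_of_h(h_lo, dic, k)[0] - alk  # TA(h) decreasing in h: r_lo > 0 expected
    r_hi = _alk_of_h(h_hi, dic, k)[0] - alk
    bad = (r_lo < 0) | (r_hi > 0)
    if np.any(bad):
        raise CarbonateError(
            "alkalinity not bracketed by pH in [2, 12]; inputs outside physical range",
            dic=dic[bad][:5], alk=alk[bad][:5],
        )

    if ph_guess is None:
        h = np.full(dic.shape, 10.0**-8.0)
    else:
        h = 10.0 ** (-np.clip(np.broadcast_to(np.asarray(ph_guess, float), dic.shape), PH_LO, PH_HI))
        h = h.copy()

    converged = np.zeros(dic.shape, dtype=bool)
    for _ in range(max_iter):
        r = _alk_of_h(h, dic, k)[0] - alk
        # maintain the bracket (r decreasing in h)
        shrink_lo = r > 0
        h_lo = np.where(shrink_lo, h, h_lo)
        h_hi = np.where(~shrink_lo, h, h_hi)
        dr = _dalk_dh(h, dic, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            h_new = h - r / dr
        outside = ~np.isfinite(h_new) | (h_new <= h_lo) | (h_new >= h_hi)
        h_new = np.where(outside, np.sqrt(h_lo * h_hi), h_new)  # bisect in log space
        converged = np.abs(np.log10(h_new) - np.log10(h)) < ph_tol
        h = h_new
        if converged.all():
            break
    if not converged.all():
        idx = np.nonzero(~converged)
        raise CarbonateError(
            "pH iteration failed to converge",
            dic=dic[idx][:5], alk=alk[idx][:5],
            temperature=temperature[idx][:5],
        )

    _, hco3, co3 = _alk_of_h(h, dic, k)
    co2aq = dic - hco3 - co3
    # guard tiny negative round-off in the CO2* residual
    co2aq = np.where(np.abs(co2aq) < 1e-25, 0.0, co2aq)
    pco2 = co2aq / k.k0 * 1.0e6  # uatm
    ca = calcium_from_salinity(salinity)
    return CarbonateState(
        dic=dic, alk=alk, temperature=temperature, salinity=salinity,
        pressure=pressure, ph=-np.log10(h), pco2=pco2, co2aq=co2aq,
        hco3=hco3, co3=co3,
        omega_cal=ca * co3 / k.ksp_cal,
        omega_arg=ca * co3 / k.ksp_arag,
    )


def saturation_state(co3, calcium, temperature, salinity, pressure=0.0, mineral="aragonite"):
    """Omega = [Ca++][CO3--]/Ksp for calcite or aragonite.

    co3 and calcium in mol/kg; returns the dimensionless saturation
    state (0 iff co3 = 0).
    """
    co3 = np.asarray(co3, dtype=float)
    calcium = np.asarray(calcium, dtype=float)
    if np.any(co3 < 0):
        raise CarbonateError("carbonate ion must be non-negative", co3=co3)
    if np.any(calcium <= 0):
        raise CarbonateError("calcium must be positive", calcium=calcium)
    k = equilibrium_constants(temperature, salinity, pressure)
    if mineral == "aragonite":
        ksp = k.ksp_arag
    elif mineral == "calcite":
        ksp = k.ksp_cal
    else:
        raise CarbonateError("unknown mineral", mineral=mineral)
    return calcium * co3 / ksp
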