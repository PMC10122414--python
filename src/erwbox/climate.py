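"""Simple global climate response.

Radiative forcing uses the standard simplified expressions: logarithmic
in CO2 and the Myhre et al. (1998) square-root fits with band overlap
for CH4 and N2O. The temperature response is the two-layer energy
balance model (mixed layer + deep ocean), which reproduces both the
fast decadal adjustment and the slow centennial warming tail.

State and forcing are plain arrays so an ensemble of climates (one per
slab-biosphere member, each with its own CO2 trajectory) integrates
vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClimateParams", "TwoLayerState", "radiative_forcing", "climate_step"]


@dataclass
class ClimateParams:
    """Two-layer energy-balance parameters (Geoffroy et al. 2013 medians).

    lambda_ : climate feedback, W m-2 K-1 (ECS = F_2x / lambda_)
    gamma   : mixed-layer/deep heat exchange, W m-2 K-1
    c_mix   : mixed-layer heat capacity, W yr m-2 K-1
    c_deep  : deep-ocean heat capacity, W yr m-2 K-1
    land_amplification : land anomaly / global anomaly
    """

    lambda_: float = 1.13
    gamma: float = 0.73
    c_mix: float = 7.3
    c_deep: float = 106.0
    land_amplification: float = 1.4
    co2_forcing_coeff: float = 5.35  # W/m2 per e-fold of CO2
    co2_ref_ppm: float = 278.0
    ch4_ref_ppb: float = 722.0
    n2o_ref_ppb: float = 273.0

    @property
    def f2x(self):
        """Forcing of doubled CO2, W/m2."""
        return self.co2_forcing_coeff * np.log(2.0)

    @property
    def ecs(self):
        """Equilibrium climate sensitivity, K."""
        return self.f2x / self.lambda_


def _overlap(m, n):
    return 0.47 * np.log(1.0 + 2.01e-5 * (m * n) ** 0.75 + 5.31e-15 * m * (m * n) ** 1.52)


def radiative_forcing(co2_ppm, ch4_ppb=None, n2o_ppb=None, params=None):
    """Total radiative forcing (W/m2) relative to the reference state."""
    p = params or ClimateParams()
    co2_ppm = np.asarray(co2_ppm, dtype=float)
    f = p.co2_forcing_coeff * np.log(co2_ppm / p.co2_ref_ppm)
    m0, n0 = p.ch4_ref_ppb, p.n2o_ref_ppb
    if ch4_ppb is not None:
        m = np.asarray(ch4_ppb, dtype=float)
        f = f + 0.036 * (np.sqrt(m) - np.sqrt(m0)) - (_overlap(m, n0) - _overlap(m0, n0))
    if n2o_ppb is not None:
        n = np.asarray(n2o_ppb, dtype=float)
        f = f + 0.12 * (np.sqrt(n) - np.sqrt(n0)) - (_overlap(m0, n) - _overlap(m0, n0))
    return f


@dataclass
class TwoLayerState:
    """Global-mean temperature anomalies (K) of the two layers."""

    t_mix: np.ndarray
    t_deep: np.ndarray

    @classmethod
    def zeros(cls, shape=()):
        return cls(t_mix=np.zeros(shape), t_deep=np.zeros(shape))

    def land_anomaly(self, params):
        return params.land_amplification * self.t_mix


def climate_step(state, forcing, params, dt):
    """Advance the two-layer model by dt years (explicit Euler).

    The shortest internal timescale is c_mix/(lambda_+gamma) ~ 4 yr, so
    the dt <= 0.1 yr used by the carbon model is deeply stable.
    Returns a new TwoLayerState; deterministic.
    """
    t, td = state.t_mix, state.t_deep
    dtdt = (forcing - params.lambda_ * t - params.gamma * (t - td)) / params.c_mix
    dtddt = params.gamma * (t - td) / params.c_deep
    return TwoLayerState(t_mix=t + dt * dtdt, t_deep=td + dt * dtddt)
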