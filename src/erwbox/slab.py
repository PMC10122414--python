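"""Slab terrestrial biosphere: global vegetation and soil carbon pools.

Two globally aggregated pools respond to atmospheric pCO2 and land
temperature:

    dV/dt = N - L        (vegetation, GtC)
    dS/dt = L - R        (soil, GtC)

with net primary production N = N0 [1 + B ln(C/C0)], litterfall
L = V / (Lambda_veg V + Lambda_0), and soil respiration
R = Gamma S Q10^((T - T0)/10).

C0 and T0 anchor the preindustrial reference: C0 defaults to 278 ppm
and T0 to the preindustrial global-mean land temperature, carried here
as an anomaly of zero (temperatures passed in are land-temperature
anomalies relative to preindustrial). At (C0, T0) the model has the
closed-form steady state

    V* = N0 Lambda_0 / (1 - N0 Lambda_veg),    S* = N0 / Gamma,

which requires N0 Lambda_veg < 1.

All parameter fields accept arrays, so an ensemble of slabs integrates
vectorized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SlabParams", "SlabState", "npp", "litterfall", "soil_respiration",
           "steady_state", "slab_step", "integrate_offline"]

PARAM_NAMES = ("n0", "b", "lambda_veg", "lambda_0", "gamma", "q10")


@dataclass
class SlabParams:
    """The six slab-biosphere parameters plus the (C0, T0) reference.

    n0         : reference NPP at C0, GtC/yr
    b          : CO2 fertilization (growth) parameter, dimensionless
    lambda_veg : vegetation-dependent turnover term, yr/GtC
    lambda_0   : baseline vegetation turnover time, yr
    gamma      : soil turnover rate at T0, 1/yr
    q10        : soil-respiration temperature sensitivity
    c0         : reference pCO2, ppm
    t0         : reference land temperature (anomaly convention: 0)
    """

    n0: np.ndarray = 50.0
    b: np.ndarray = 0.6
    lambda_veg: np.ndarray = 0.002
    lambda_0: np.ndarray = 10.0
    gamma: np.ndarray = 0.033
    q10: np.ndarray = 2.0
    c0: float = 278.0
    t0: float = 0.0

    def __post_init__(self):
        for name in PARAM_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self):
        checks = {
            "n0 > 0": np.all(self.n0 > 0),
            "lambda_0 > 0": np.all(self.lambda_0 > 0),
            "gamma > 0": np.all(self.gamma > 0),
            "q10 > 0": np.all(self.q10 > 0),
            "lambda_veg >= 0": np.all(self.lambda_veg >= 0),
            "n0*lambda_veg < 1": np.all(self.n0 * self.lambda_veg < 1),
        }
        failed = [k for k, ok in checks.items() if not ok]
        if failed:
            raise ValueError(f"invalid slab parameters: {failed}")

    @property
    def shape(self):
        return np.broadcast_shapes(*(getattr(self, n).shape for n in PARAM_NAMES))

    def __len__(self):
        shape = self.shape
        return shape[0] if shape else 1

    def subset(self, index):
        """Select ensemble members by boolean mask or index array."""
        kw = {n: np.broadcast_to(getattr(self, n), self.shape)[index] for n in PARAM_NAMES}
        return SlabParams(c0=self.c0, t0=self.t0, **kw)

    def to_dataframe(self):
        import pandas as pd

        shape = self.shape
        return pd.DataFrame(
            {n: np.broadcast_to(getattr(self, n), shape).ravel() for n in PARAM_NAMES}
        )

    @classmethod
    def from_dataframe(cls, df, c0=278.0, t0=0.0):
        return cls(c0=c0, t0=t0, **{n: df[n].to_numpy() for n in PARAM_NAMES})


@dataclass
class SlabState:
    """Vegetation and soil carbon pools (GtC) with diagnostic fluxes."""

    v: np.ndarray
    s: np.ndarray
    n: np.ndarray = field(default=None)  # NPP, GtC/yr
    l: np.ndarray = field(default=None)  # litterfall, GtC/yr
    r: np.ndarray = field(default=None)  # soil respiration, GtC/yr


def npp(c, params):
    """Net primary production N = N0 [1 + B ln(C/C0)], GtC/yr.

    Clipped at zero (with a log record) if low pCO2 drives the
    logarithm negative enough to make N < 0.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("atmospheric pCO2 must be positive")
    n = params.n0 * (1.0 + params.b * np.log(c / params.c0))
    if np.any(n < 0):
        logger.warning("NPP clipped at zero for %d member(s)", int(np.sum(n < 0)))
        n = np.clip(n, 0.0, None)
    return n


def litterfall(v, params):
    """Litterfall L = V / (Lambda_veg V + Lambda_0), GtC/yr."""
    v = np.asarray(v, dtype=float)
    return v / (params.lambda_veg * v + params.lambda_0)


def turnover_time(v, params):
    """Vegetation turnover time Lambda_veg V + Lambda_0, yr."""
    return params.lambda_veg * np.asarray(v, dtype=float) + params.lambda_0


def soil_respiration(s, t, params):
    """Soil respiration R = Gamma S Q10^((T - T0)/10), GtC/yr."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    return params.gamma * s * params.q10 ** ((t - params.t0) / 10.0)


def steady_state(params):
    """Closed-form steady state at (C0, T0): (V*, S*)."""
    v_star = params.n0 * params.lambda_0 / (1.0 - params.n0 * params.lambda_veg)
    s_star = params.n0 / params.gamma
    return v_star, s_star


def _derivs(v, s, c, t, params):
    n = npp(c, params)
    l = litterfall(v, params)
    r = soil_respiration(s, t, params)
    return n - l, l - r


def slab_step(state, c, t_land, params, dt):
    """One RK4 step of the two-pool ODEs with C and T frozen over dt.

    Returns (new_state, j_lnd_air) where j_lnd_air is the net
    land-to-atmosphere carbon flux in GtC/yr over the step, defined
    exactly as -(dV + dS)/dt so land-atmosphere exchange is
    conservative regardless of integrator error. Pools are clipped at
    zero (logged) in pathological parameter corners; the step is
    stable for dt <= 0.1 yr across the sampled parameter space (the
    fastest intrinsic timescale is the vegetation turnover, >= a few
    years).
    """
    v, s = state.v, state.s
    k1v, k1s = _derivs(v, s, c, t_land, params)
    k2v, k2s = _derivs(v + 0.5 * dt * k1v, s + 0.5 * dt * k1s, c, t_land, params)
    k3v, k3s = _derivs(v + 0.5 * dt * k2v, s + 0.5 * dt * k2s, c, t_land, params)
    k4v, k4s = _derivs(v + dt * k3v, s + dt * k3s, c, t_land, params)
    v_new = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    s_new = s + dt / 6.0 * (k1s + 2 * k2s + 2 * k3s + k4s)
    if np.any(v_new < 0) or np.any(s_new < 0):
        logger.warning("slab pool clipped at zero")
        v_new = np.clip(v_new, 0.0, None)
        s_new = np.clip(s_new, 0.0, None)
    j_lnd_air = -((v_new - v) + (s_new - s)) / dt  # GtC/yr, positive into atmosphere
    n = npp(c, params)
    l = litterfall(v_new, params)
    r = soil_respiration(s_new, t_land, params)
    return SlabState(v=v_new, s=s_new, n=n, l=l, r=r), j_lnd_air


def integrate_offline(params, years, co2_ppm, t_land, dt=0.1, state0=None):
    """Drive the slab standalone with prescribed pCO2 and land temperature.

    ``years`` is an annual axis; ``co2_ppm`` and ``t_land`` are series
    on that axis (linearly interpolated to the sub-annual grid). Returns
    a dict of annual series (v, s, n, l, r, turnover), each shaped
    (len(params), n_years) — the workhorse of ensemble filtering.
    """
    years = np.asarray(years, dtype=float)
    n_mem = len(params)
    if state0 is None:
        v_star, s_star = steady_state(params)
        v = np.broadcast_to(v_star, (n_mem,)).astype(float).copy()
        s = np.broadcast_to(s_star, (n_mem,)).astype(float).copy()
    else:
        v, s = state0.v.copy(), state0.s.copy()
    state = SlabState(v=v, s=s)
    steps = max(1, round(1.0 / dt))
    out = {k: np.empty((n_mem, years.size)) for k in ("v", "s", "n", "l", "r", "turnover")}

    def record(i):
        out["v"][:, i] = state.v
        out["s"][:, i] = state.s
        out["n"][:, i] = npp(co2_ppm[i], params)
        out["l"][:, i] = litterfall(state.v, params)
        out["r"][:, i] = soil_respiration(state.s, t_land[i], params)
        out["turnover"][:, i] = turnover_time(state.v, params)

    record(0)
    for i in range(years.size - 1):
        c0_, c1 = co2_ppm[i], co2_ppm[i + 1]
        t0_, t1 = t_land[i], t_land[i + 1]
        for j in range(steps):
            f = (j + 0.5) / steps
            c = c0_ + f * (c1 - c0_)
            t = t0_ + f * (t1 - t0_)
            state, _ = slab_step(state, c, t, params, dt)
        record(i + 1)
    return out
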