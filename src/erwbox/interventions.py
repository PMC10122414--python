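"""CDR intervention modes: baseline mitigation and enhanced rock weathering.

Two end-member intervention styles are applied on top of an
emission-driven control run:

* ``baseline`` — the deployment rate is subtracted from the control
  emission trajectory from the start year onward (direct air capture
  with permanent storage, or equivalently extra mitigation). The
  captured carbon leaves the surface system instantly and permanently.

* ``erw`` — the same rate of CO2 is captured from the atmosphere but
  redelivered to the surface ocean as dissolved inorganic carbon and
  alkalinity at the feedstock stoichiometry, i.e. repartitioned into a
  non-radiative but potentially labile surface carbon pool.

Feedstock stoichiometries follow the idealized weathering reactions

    CaSiO3 + 2 CO2 + 3 H2O -> Ca++ + 2 HCO3- + H4SiO4   (silicate)
    CaCO3  +   CO2 +   H2O -> Ca++ + 2 HCO3-            (carbonate)

so per mol of CO2 captured, silicate delivers 1 mol DIC + 1 eq ALK and
carbonate delivers 2 mol DIC + 2 eq ALK, of which 1 mol DIC is
rock-derived carbon (tagged so conservation audits close).

Feedstock dissolution and riverine delivery are instantaneous; the
reduced model has no coastline, so "river routing" collapses to
configurable per-surface-box weights (default: all to the low-latitude
surface box).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np

from . import constants as const

__all__ = ["FeedstockStoichiometry", "FEEDSTOCKS", "Intervention", "erw_fluxes",
           "apply_baseline", "run_experiment", "intervention_rates"]

STANDARD_RATES = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class FeedstockStoichiometry:
    """Delivery per mol of CO2 captured from the atmosphere."""

    dic_per_co2: float
    alk_per_co2: float
    rock_dic_per_co2: float  # rock-derived fraction of the delivered DIC


FEEDSTOCKS = {
    "silicate": FeedstockStoichiometry(1.0, 1.0, 0.0),
    "carbonate": FeedstockStoichiometry(2.0, 2.0, 1.0),
    "none": FeedstockStoichiometry(0.0, 0.0, 0.0),
}


@dataclass
class Intervention:
    """A CDR deployment: mode, feedstock, rate, start year.

    ``rate_gtco2`` is a constant (GtCO2/yr) or a callable of time
    returning the rate. The 0.5-40 GtCO2/yr range of the standard
    experiments is advisory, not enforced.
    """

    mode: str = "erw"  # "baseline" | "erw"
    feedstock: str = "silicate"
    rate_gtco2: object = 10.0
    start_year: float = 2030.0

    def __post_init__(self):
        if self.mode not in ("baseline", "erw"):
            raise ValueError(f"unknown intervention mode {self.mode!r}")
        if self.feedstock not in FEEDSTOCKS:
            raise ValueError(f"unknown feedstock {self.feedstock!r}")
        if not callable(self.rate_gtco2) and self.rate_gtco2 < 0:
            raise ValueError("deployment rate must be non-negative")

    def rate_at(self, t):
        t = np.asarray(t, dtype=float)
        r = self.rate_gtco2(t) if callable(self.rate_gtco2) else \
            np.full(t.shape, float(self.rate_gtco2))
        return np.where(t >= self.start_year, r, 0.0)

    def describe(self):
        rate = "callable" if callable(self.rate_gtco2) else self.rate_gtco2
        return {"mode": self.mode, "feedstock": self.feedstock,
                "rate_gtco2": rate, "start_year": self.start_year}


def erw_fluxes(rate_gtco2, feedstock):
    """Instantaneous ERW fluxes for a capture rate (GtCO2/yr).

    Returns (atm_removal_gtco2, dic_input_mol_per_yr,
    alk_input_mol_per_yr, rock_dic_mol_per_yr).
    """
    if feedstock not in FEEDSTOCKS:
        raise ValueError(f"unknown feedstock {feedstock!r}")
    st = FEEDSTOCKS[feedstock]
    mol_co2 = np.asarray(rate_gtco2, dtype=float) * const.MOL_PER_GTCO2
    return (np.asarray(rate_gtco2, dtype=float),
            st.dic_per_co2 * mol_co2,
            st.alk_per_co2 * mol_co2,
            st.rock_dic_per_co2 * mol_co2)


def intervention_rates(intervention, t_grid):
    """Step-grid flux series (mol/yr) consumed by the world integrator.

    Baseline interventions act through the emission trajectory, not
    through ocean delivery, so they produce all-zero series here.
    """
    if intervention.mode == "baseline":
        z = np.zeros(np.asarray(t_grid).shape)
        return SimpleNamespace(atm_removal_mol=z, dic_mol=z, alk_mol=z, rock_dic_mol=z)
    rate = intervention.rate_at(t_grid)
    _, dic, alk, rock = erw_fluxes(rate, intervention.feedstock)
    return SimpleNamespace(
        atm_removal_mol=rate * const.MOL_PER_GTCO2,
        dic_mol=dic, alk_mol=alk, rock_dic_mol=rock,
    )


def apply_baseline(control_emissions, intervention):
    """Control emissions minus the deployment rate from the start year.

    Emissions may go negative (net removal); that is allowed and is the
    point of the baseline mode.
    """
    if intervention.mode != "baseline":
        raise ValueError("apply_baseline requires a baseline-mode intervention")
    return control_emissions.perturbed(lambda t: -intervention.rate_at(t))


def run_experiment(world, state, pathway, control_emissions, intervention,
                   slab_params=None, end_year=2100):
    """Branch an intervention run from the spun-up state.

    ``intervention=None`` reproduces the control run. The returned
    ledger carries the intervention description in its metadata and,
    for baseline runs, the deployment rate on ``j_cdr`` (the mitigation
    is implemented through the emission trajectory, but Eq-3-style
    accounting needs J_CDR on the ledger).
    """
    meta = {"scenario": pathway.label, "end_year": end_year}
    emissions = control_emissions
    iv_for_run = None
    if intervention is not None:
        meta.update(intervention.describe())
        if intervention.mode == "baseline":
            emissions = apply_baseline(control_emissions, intervention)
        else:
            iv_for_run = intervention
    else:
        meta.update({"mode": "control", "feedstock": "none", "rate_gtco2": 0.0})
    led = world.run(state, pathway, mode="emission", emissions=emissions,
                    intervention=iv_for_run, slab_params=slab_params,
                    end_year=end_year, meta=meta)
    if intervention is not None and intervention.mode == "baseline":
        led.j_cdr = np.broadcast_to(
            intervention.rate_at(led.years + 0.5), led.emissions.shape).copy()
    return led
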