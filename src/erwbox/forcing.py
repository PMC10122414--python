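"""Idealized greenhouse-gas concentration pathways and emission inversion.

Pathways are annual CO2/CH4/N2O series over 1765-2300 built by
monotone (PCHIP) interpolation through a small set of anchor points.
Three shipped pathway families emulate the shape of the standard
low / middle / high concentration scenarios (peak-and-decline toward
~420 ppm, stabilization near ~540 ppm, rise to ~940 ppm by 2100 with
stabilization by 2250); the anchors are idealized approximations, and
real concentration tables can be supplied through :func:`read_pathway_csv`.

CH4 and N2O are always imposed; CO2 is imposed only in "prescribed"
runs used to diagnose the emission trajectory that an emission-driven
run then consumes (see :meth:`erwbox.world.World.run`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ConcentrationPathway", "EmissionTrajectory", "synthesize_pathway",
    "standard_pathway", "read_pathway_csv", "diagnose_emissions",
]

START_YEAR = 1765
END_YEAR = 2300

# Shared idealized historical anchors (year, ppm / ppb)
_HIST_CO2 = [(1765, 278.0), (1800, 283.0), (1850, 285.0), (1900, 296.0),
             (1950, 311.0), (1975, 331.0), (2000, 369.0), (2010, 390.0), (2020, 412.0)]
_HIST_CH4 = [(1765, 722.0), (1850, 800.0), (1900, 925.0), (1950, 1147.0),
             (2000, 1751.0), (2020, 1880.0)]
_HIST_N2O = [(1765, 273.0), (1900, 280.0), (1950, 290.0), (2000, 316.0), (2020, 333.0)]

_SCENARIO_ANCHORS = {
    "low": {
        "co2": _HIST_CO2 + [(2035, 437.0), (2050, 450.0), (2070, 440.0),
                            (2100, 421.0), (2200, 380.0), (2300, 360.0)],
        "ch4": _HIST_CH4 + [(2050, 1500.0), (2100, 1250.0), (2300, 1250.0)],
        "n2o": _HIST_N2O + [(2100, 344.0), (2300, 340.0)],
    },
    "mid": {
        "co2": _HIST_CO2 + [(2035, 440.0), (2060, 483.0), (2080, 515.0),
                            (2100, 538.0), (2150, 543.0), (2300, 543.0)],
        "ch4": _HIST_CH4 + [(2050, 1800.0), (2100, 1576.0), (2300, 1576.0)],
        "n2o": _HIST_N2O + [(2100, 372.0), (2300, 372.0)],
    },
    "high": {
        "co2": _HIST_CO2 + [(2035, 450.0), (2050, 505.0), (2075, 670.0),
                            (2100, 936.0), (2150, 1430.0), (2200, 1800.0),
                            (2250, 1960.0), (2300, 1962.0)],
        "ch4": _HIST_CH4 + [(2050, 2740.0), (2100, 3751.0), (2150, 3100.0), (2300, 3100.0)],
        "n2o": _HIST_N2O + [(2100, 435.0), (2200, 525.0), (2300, 525.0)],
    },
}


@dataclass
class ConcentrationPathway:
    """Annual greenhouse-gas concentration trajectory, 1765-2300."""

    years: np.ndarray
    co2: np.ndarray  # ppm
    ch4: np.ndarray  # ppb
    n2o: np.ndarray  # ppb
    label: str = ""

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        for name in ("co2", "ch4", "n2o"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("pathway time axis must be strictly increasing")
        for name in ("co2", "ch4", "n2o"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} concentrations must be positive")

    def co2_interpolator(self):
        return PchipInterpolator(self.years, self.co2)

    def at(self, year):
        """Linear interpolation of all three gases at (array of) years."""
        year = np.asarray(year, dtype=float)
        return tuple(np.interp(year, self.years, g) for g in (self.co2, self.ch4, self.n2o))

    def truncate(self, end_year):
        m = self.years <= end_year
        return ConcentrationPathway(self.years[m], self.co2[m], self.ch4[m], self.n2o[m], self.label)

    def to_csv(self, path):
        pd.DataFrame({"year": self.years.astype(int), "co2_ppm": self.co2,
                      "ch4_ppb": self.ch4, "n2o_ppb": self.n2o}).to_csv(path, index=False)


def read_pathway_csv(path, label=None):
    """Read a pathway from CSV with columns year, co2_ppm, ch4_ppb, n2o_ppb."""
    df = pd.read_csv(path)
    return ConcentrationPathway(
        df["year"].to_numpy(), df["co2_ppm"].to_numpy(),
        df["ch4_ppb"].to_numpy(), df["n2o_ppb"].to_numpy(),
        label=label or str(path),
    )


def _interp_anchors(anchors, years):
    a = np.asarray(anchors, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a[:, 1] <= 0):
        raise ValueError("anchors must be finite and positive")
    if np.any(np.diff(a[:, 0]) <= 0):
        raise ValueError("anchor years must be strictly increasing")
    if a.shape[0] == 1:
        return np.full(years.shape, a[0, 1])
    out = PchipInterpolator(a[:, 0], a[:, 1])(np.clip(years, a[0, 0], a[-1, 0]))
    return out


def synthesize_pathway(co2_anchors, ch4_anchors=None, n2o_anchors=None, label="",
                       start_year=START_YEAR, end_year=END_YEAR):
    """Build an annual pathway by monotone cubic interpolation through anchors.

    ``co2_anchors`` is a sequence of (year, ppm) control points; CH4 and
    N2O anchors default to constant preindustrial values. The series
    passes through every anchor exactly and preserves monotone segments
    between monotone anchors (PCHIP property); years outside the anchor
    span are held at the nearest anchor value.
    """
    years = np.arange(start_year, end_year + 1, dtype=float)
    co2 = _interp_anchors(co2_anchors, years)
    ch4 = _interp_anchors(ch4_anchors if ch4_anchors is not None else [(start_year, 722.0)], years)
    n2o = _interp_anchors(n2o_anchors if n2o_anchors is not None else [(start_year, 273.0)], years)
    return ConcentrationPathway(years, co2, ch4, n2o, label=label)


def standard_pathway(name, end_year=END_YEAR):
    """One of the shipped idealized scenarios: 'low', 'mid', or 'high'."""
    if name not in _SCENARIO_ANCHORS:
        raise KeyError(f"unknown pathway {name!r}; choose from {sorted(_SCENARIO_ANCHORS)}")
    a = _SCENARIO_ANCHORS[name]
    return synthesize_pathway(a["co2"], a["ch4"], a["n2o"], label=name,
                              end_year=end_year)


@dataclass
class EmissionTrajectory:
    """Diagnosed net CO2 emissions consistent with a prescribed pathway.

    ``years``/``emissions`` is the annual-mean series (GtCO2/yr, may
    carry a leading ensemble dimension); ``step_years``/``step_values``
    retain the integrator-resolution series so that an emission-driven
    rerun reproduces the prescribed CO2 to round-off rather than to the
    annual-averaging error.
    """

    years: np.ndarray
    emissions: np.ndarray  # GtCO2/yr, shape (..., n_years)
    provenance: str = ""
    step_years: np.ndarray = field(default=None, repr=False)
    step_values: np.ndarray = field(default=None, repr=False)

    def rate(self, year_grid):
        """Emission rate (GtCO2/yr) on an arbitrary time grid."""
        if self.step_years is not None:
            xs, vs = self.step_years, self.step_values
        else:
            xs, vs = self.years, self.emissions
        year_grid = np.asarray(year_grid, dtype=float)
        if vs.ndim == 1:
            return np.interp(year_grid, xs, vs)
        out = np.empty(vs.shape[:-1] + year_grid.shape)
        for idx in np.ndindex(vs.shape[:-1]):
            out[idx] = np.interp(year_grid, xs, vs[idx])
        return out

    def perturbed(self, delta_fn):
        """New trajectory with emissions(t) -> emissions(t) + delta(t)."""
        new_annual = self.emissions + delta_fn(self.years)
        step_vals = None
        if self.step_years is not None:
            step_vals = self.step_values + delta_fn(self.step_years)
        return EmissionTrajectory(self.years, new_annual,
                                  provenance=self.provenance + "+perturbation",
                                  step_years=self.step_years, step_values=step_vals)

    def to_csv(self, path):
        df = pd.DataFrame({"year": self.years.astype(int)})
        em = np.atleast_2d(self.emissions)
        for i in range(em.shape[0]):
            df[f"emissions_gtco2_{i}" if em.shape[0] > 1 else "emissions_gtco2"] = em[i]
        df.to_csv(path, index=False)


def diagnose_emissions(world, state, pathway, slab_params=None, end_year=None):
    """Invert a prescribed CO2 pathway into net emissions.

    Runs the full coupled model with CO2 forced to the pathway and
    returns (EmissionTrajectory, RunLedger). The consistency contract —
    an emission-driven rerun reproduces the prescribed CO2 to <1 ppm —
    is exercised by the test suite and by ``World.run`` audits.
    """
    ledger = world.run(state, pathway, mode="prescribed", slab_params=slab_params,
                       end_year=end_year)
    return ledger.emission_trajectory, ledger
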