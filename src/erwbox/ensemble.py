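"""Stochastic slab-biosphere ensemble generation and observational filtering.

The slab biosphere's six parameters are drawn from broad priors and
passed through a two-stage filter that mirrors how large
perturbed-parameter ensembles are constrained in practice:

1. *Static* (offline) — each parameter set is integrated standalone
   under historical pCO2 and land temperature; it passes if its modern
   soil carbon stock, NPP, and vegetation turnover time fall inside
   observational windows.
2. *Dynamic* (offline) — its end-of-century changes in vegetation and
   soil carbon under scenario forcing must lie inside envelopes
   spanning the range of CMIP-class projections.

A subset of the survivors is then carried into fully coupled runs and
filtered once more with the same criteria evaluated on the coupled
trajectories, yielding the final ensemble.

Priors and windows are configurable defaults assembled from textbook
modern values (soil carbon 1200-2000 GtC, NPP 45-65 GtC/yr, vegetation
turnover 8-25 yr); every run's manifest records them together with the
seed, counts, and per-criterion rejection reasons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateParams, TwoLayerState, climate_step, radiative_forcing
from .slab import SlabParams, integrate_offline

logger = logging.getLogger(__name__)

__all__ = ["ParameterPrior", "FilterCriteria", "sample_priors", "offline_forcing",
           "filter_static", "filter_dynamic", "build_ensemble", "Ensemble"]


@dataclass
class ParameterPrior:
    """Per-parameter sampling ranges: name -> (lo, hi, 'uniform'|'log')."""

    ranges: dict = field(default_factory=lambda: {
        "n0": (30.0, 80.0, "uniform"),
        "b": (0.2, 1.0, "uniform"),
        "lambda_veg": (0.0, 0.012, "uniform"),
        "lambda_0": (3.0, 45.0, "uniform"),
        "gamma": (0.008, 0.12, "log"),
        "q10": (1.3, 4.5, "uniform"),
    })
    c0: float = 278.0
    t0: float = 0.0

    def __post_init__(self):
        for name, (lo, hi, dist) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"prior for {name}: min must be <= max")
            if dist == "log" and lo <= 0:
                raise ValueError(f"log prior for {name} requires positive range")


@dataclass
class FilterCriteria:
    """Acceptance windows of the two-stage observational filter.

    Static windows constrain the modern state; dynamic envelopes
    constrain the simulated change of each pool from 2015 to 2100
    (GtC) under every scenario tested.
    """

    soil_window_gtc: tuple = (1200.0, 2000.0)
    npp_window_gtc_yr: tuple = (45.0, 65.0)
    turnover_window_yr: tuple = (8.0, 25.0)
    delta_v_window_gtc: tuple = (-25.0, 400.0)
    delta_s_window_gtc: tuple = (-250.0, 150.0)
    modern_years: tuple = (2005, 2015)
    century_years: tuple = (2015, 2100)

    def __post_init__(self):
        for name in ("soil_window_gtc", "npp_window_gtc_yr", "turnover_window_yr",
                     "delta_v_window_gtc", "delta_s_window_gtc"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be below upper")


def sample_priors(prior, n, seed):
    """Draw ``n`` parameter sets from the prior; reproducible given seed.

    Draws violating the structural constraint N0*Lambda_veg < 1 (needed
    for a positive vegetation steady state) are resampled — this is
    part of the prior's support, not a filter criterion.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for name, (lo, hi, dist) in prior.ranges.items():
        u = rng.random(n)
        if dist == "log":
            out[name] = lo * (hi / lo) ** u
        else:
            out[name] = lo + (hi - lo) * u
    bad = out["n0"] * out["lambda_veg"] >= 1.0
    while np.any(bad):
        idx = np.flatnonzero(bad)
        lo, hi, _ = prior.ranges["lambda_veg"]
        out["lambda_veg"][idx] = lo + (hi - lo) * rng.random(idx.size)
        bad = out["n0"] * out["lambda_veg"] >= 1.0
    return SlabParams(c0=prior.c0, t0=prior.t0, **out)


def offline_forcing(pathway, climate_params=None, end_year=None, dt=0.1):
    """Annual (years, co2_ppm, t_land) series for offline slab runs.

    Drives the two-layer climate with the pathway's prescribed
    concentrations (no carbon-cycle feedback) and returns the land
    temperature anomaly series the standalone slab model consumes.
    """
    p = climate_params or ClimateParams()
    end = end_year or int(pathway.years[-1])
    years = np.arange(int(pathway.years[0]), end + 1, dtype=float)
    steps = int(round(1.0 / dt))
    state = TwoLayerState.zeros(())
    t_land = np.empty(years.size)
    t_land[0] = 0.0
    for i in range(years.size - 1):
        for j in range(steps):
            t = years[i] + (j + 0.5) * dt
            co2, ch4, n2o = pathway.at(t)
            f = radiative_forcing(co2, ch4, n2o, p)
            state = climate_step(state, f, p, dt)
        t_land[i + 1] = state.land_anomaly(p)
    co2_annual = np.interp(years, pathway.years, pathway.co2)
    return years, co2_annual, t_land


def _window_mask(values, window):
    lo, hi = window
    return (values >= lo) & (values <= hi)


def filter_static(params, forcing_inputs, criteria):
    """Stage-1 static filter: modern soil stock, NPP, turnover time.

    ``forcing_inputs`` is the (years, co2, t_land) triple from
    :func:`offline_forcing`. Returns (mask, diagnostics DataFrame) with
    each member's modern values and per-criterion verdicts.
    """
    years, co2, t_land = forcing_inputs
    y0, y1 = criteria.modern_years
    sel = (years >= y0) & (years <= y1)
    out = integrate_offline(params, years, co2, t_land)
    soil = out["s"][:, sel].mean(axis=1)
    npp_modern = out["n"][:, sel].mean(axis=1)
    turnover = out["turnover"][:, sel].mean(axis=1)
    ok_soil = _window_mask(soil, criteria.soil_window_gtc)
    ok_npp = _window_mask(npp_modern, criteria.npp_window_gtc_yr)
    ok_turn = _window_mask(turnover, criteria.turnover_window_yr)
    mask = ok_soil & ok_npp & ok_turn
    diag = pd.DataFrame({
        "soil_gtc": soil, "npp_gtc_yr": npp_modern, "turnover_yr": turnover,
        "pass_soil": ok_soil, "pass_npp": ok_npp, "pass_turnover": ok_turn,
        "pass_static": mask,
    })
    return mask, diag


def filter_dynamic(params, scenario_forcings, criteria):
    """Stage-1 dynamic filter: century Delta-V / Delta-S envelopes.

    ``scenario_forcings`` is a list of offline-forcing triples (one per
    scenario); a member passes only if its changes lie inside the
    envelopes for every scenario.
    """
    mask = np.ones(len(params), dtype=bool)
    for years, co2, t_land in scenario_forcings:
        i0 = min(int(np.searchsorted(years, criteria.century_years[0])), years.size - 1)
        i1 = min(int(np.searchsorted(years, criteria.century_years[1])), years.size - 1)
        out = integrate_offline(params, years, co2, t_land)
        dv = out["v"][:, i1] - out["v"][:, i0]
        ds = out["s"][:, i1] - out["s"][:, i0]
        mask &= _window_mask(dv, criteria.delta_v_window_gtc)
        mask &= _window_mask(ds, criteria.delta_s_window_gtc)
    return mask


def coupled_filter(params, ledger, criteria):
    """Stage-2 filter applied to a coupled-run ledger (same windows)."""
    years = ledger.years
    y0, y1 = criteria.modern_years
    sel = (years >= y0) & (years <= y1)
    soil = ledger.soil_gtc[..., sel].mean(axis=-1)
    veg = ledger.veg_gtc[..., sel].mean(axis=-1)
    from .slab import npp as npp_fn, turnover_time
    co2 = ledger.atm_co2_ppm[..., sel].mean(axis=-1)
    npp_modern = npp_fn(co2, params)
    turnover = turnover_time(veg, params)
    i0 = int(np.searchsorted(years, criteria.century_years[0]))
    i1 = min(int(np.searchsorted(years, criteria.century_years[1])), years.size - 1)
    dv = ledger.veg_gtc[..., i1] - ledger.veg_gtc[..., i0]
    ds = ledger.soil_gtc[..., i1] - ledger.soil_gtc[..., i0]
    return (_window_mask(soil, criteria.soil_window_gtc)
            & _window_mask(npp_modern, criteria.npp_window_gtc_yr)
            & _window_mask(turnover, criteria.turnover_window_yr)
            & _window_mask(dv, criteria.delta_v_window_gtc)
            & _window_mask(ds, criteria.delta_s_window_gtc))


@dataclass
class Ensemble:
    """A filtered parameter ensemble with its provenance manifest."""

    params: SlabParams
    manifest: pd.DataFrame
    seed: int
    counts: dict

    def __len__(self):
        return len(self.params)

    def manifest_to_csv(self, path):
        self.manifest.to_csv(path, index=False)


def build_ensemble(prior, criteria, n_initial, n_coupled, seed,
                   historical_forcing, scenario_forcings,
                   coupled_runner=None):
    """Two-stage ensemble construction.

    Stage 1 draws ``n_initial`` parameter sets and applies the offline
    static and dynamic filters; ``n_coupled`` survivors (at most) are
    carried forward. If ``coupled_runner`` is given — a callable
    mapping a SlabParams batch to a coupled-run ledger — the survivors
    are re-filtered on their coupled trajectories (stage 2).

    Returns an :class:`Ensemble`; raises with a per-criterion rejection
    histogram if nothing survives.
    """
    params = sample_priors(prior, n_initial, seed)
    static_mask, diag = filter_static(params, historical_forcing, criteria)
    dyn_mask = np.zeros(n_initial, dtype=bool)
    if static_mask.any():
        dyn_mask[static_mask] = filter_dynamic(
            params.subset(static_mask), scenario_forcings, criteria)
    survivors = np.flatnonzero(dyn_mask)
    counts = {
        "n_initial": n_initial,
        "n_pass_static": int(static_mask.sum()),
        "n_pass_dynamic": int(dyn_mask.sum()),
        "reject_soil": int((~diag["pass_soil"]).sum()),
        "reject_npp": int((~diag["pass_npp"]).sum()),
        "reject_turnover": int((~diag["pass_turnover"]).sum()),
    }
    if survivors.size == 0:
        raise RuntimeError(f"ensemble filtering left no survivors: {counts}")
    chosen = survivors[:n_coupled]
    sub = params.subset(chosen)
    coupled_mask = np.ones(chosen.size, dtype=bool)
    if coupled_runner is not None:
        ledger = coupled_runner(sub)
        coupled_mask = coupled_filter(sub, ledger, criteria)
        if not coupled_mask.any():
            raise RuntimeError(f"coupled filtering left no survivors: {counts}")
    final = sub.subset(coupled_mask)
    counts["n_coupled_in"] = int(chosen.size)
    counts["n_final"] = int(coupled_mask.sum())
    manifest = diag.copy()
    manifest.insert(0, "member", np.arange(n_initial))
    manifest["pass_dynamic"] = dyn_mask
    manifest["seed"] = seed
    for name in ("n0", "b", "lambda_veg", "lambda_0", "gamma", "q10"):
        manifest[name] = getattr(params, name)
    logger.info("ensemble: %s", counts)
    return Ensemble(params=final, manifest=manifest, seed=seed, counts=counts)
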