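"""Backflux, leakage, storage-efficiency and carbonate co-benefit metrics.

For an intervention run *i* paired with its control, the net impact on
atmospheric CO2 is

    eta_i(t) = int_2030^t [ J_CDR,i
                           - (J_sea-air^exp,i - J_sea-air^ctrl)
                           - (J_lnd-air^exp,i - J_lnd-air^ctrl) ] dt'
               / int_2030^t J_CDR,i dt'

(the perturbation airborne fraction of the removal), the carbon
backflux is p_i = (1 - eta_i) * 100%, and the ERW leakage is the excess
backflux over the equivalent baseline intervention,

    p_leak = p_ERW - p_base.

Integrals run from the intervention start year (2030 by default)
through the requested year inclusive, as cumulative sums of the
annual-mean flux series (the trapezoid rule applied to the piecewise-
constant annual-mean representation). "End of the century" means
integrated through 2100 inclusive.
"""

from __future__ import annotations

import numpy as np

__all__ = ["eta", "backflux_percent", "p_leak", "storage_efficiency",
           "omega_cobenefit", "rate_independence_audit", "ensemble_summary"]


class LedgerMismatchError(ValueError):
    pass


def _check_axes(*ledgers):
    first = ledgers[0]
    for led in ledgers[1:]:
        if not first.same_axis(led):
            raise LedgerMismatchError("ledgers do not share a time axis")


def _check_paired(a, b, keys=("scenario", "rate_gtco2", "start_year")):
    for k in keys:
        va, vb = a.meta.get(k), b.meta.get(k)
        if va is not None and vb is not None and va != vb:
            raise LedgerMismatchError(f"paired ledgers disagree on {k}: {va!r} vs {vb!r}")


def eta(exp_ledger, ctrl_ledger, t, start_year=None):
    """Net CDR impact eta at year ``t`` (dimensionless, per member).

    Raises on mismatched time axes; returns NaN where the cumulative
    deployment is zero (eta undefined).
    """
    _check_axes(exp_ledger, ctrl_ledger)
    start = start_year if start_year is not None else exp_ledger.meta.get("start_year", 2030)
    if start not in exp_ledger.years:
        start = 2030
    cdr = exp_ledger.integrate("j_cdr", start, t)
    excess_sea = exp_ledger.integrate("j_sea_air", start, t) \
        - ctrl_ledger.integrate("j_sea_air", start, t)
    excess_lnd = exp_ledger.integrate("j_lnd_air", start, t) \
        - ctrl_ledger.integrate("j_lnd_air", start, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (cdr - excess_sea - excess_lnd) / cdr
    return np.where(cdr > 0, out, np.nan)


def backflux_percent(exp_ledger, ctrl_ledger, t, start_year=None):
    """Carbon backflux p = (1 - eta) * 100, percent."""
    return (1.0 - eta(exp_ledger, ctrl_ledger, t, start_year)) * 100.0


def p_leak(erw_ledger, base_ledger, ctrl_ledger, t, start_year=None):
    """ERW leakage p_leak = p_ERW - p_base (percent).

    The ERW and baseline runs must use the same scenario, rate and
    start year (checked against ledger metadata).
    """
    _check_axes(erw_ledger, base_ledger, ctrl_ledger)
    _check_paired(erw_ledger, base_ledger)
    return (backflux_percent(erw_ledger, ctrl_ledger, t, start_year)
            - backflux_percent(base_ledger, ctrl_ledger, t, start_year))


def storage_efficiency(erw_ledger, base_ledger, ctrl_ledger, t, start_year=None):
    """Fraction of ERW-captured carbon still stored, 100 - p_leak (percent).

    Also reports the excess sub-surface-ocean DIC inventory of the ERW
    run relative to baseline (GtC) — the box-model analogue of the
    depth-integrated DIC storage signal.
    """
    pl = p_leak(erw_ledger, base_ledger, ctrl_ledger, t, start_year)
    i = erw_ledger.year_index(t)
    excess_interior = erw_ledger.subsurface_dic_gtc[..., i] - base_ledger.subsurface_dic_gtc[..., i]
    return 100.0 - pl, excess_interior


def omega_cobenefit(erw_ledger, base_ledger, ctrl_ledger, year):
    """Surface aragonite-saturation co-benefit at ``year``.

    Returns a dict with the area-weighted global-mean surface Omega_arg
    of each run, the percent changes of the ERW and baseline runs
    relative to control, and their ratio.
    """
    _check_axes(erw_ledger, base_ledger, ctrl_ledger)
    i = erw_ledger.year_index(year)
    om_erw = erw_ledger.surface_omega_arg[..., i]
    om_base = base_ledger.surface_omega_arg[..., i]
    om_ctrl = ctrl_ledger.surface_omega_arg[..., i]
    d_erw = (om_erw / om_ctrl - 1.0) * 100.0
    d_base = (om_base / om_ctrl - 1.0) * 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_base != 0, d_erw / d_base, np.nan)
    return {"omega_erw": om_erw, "omega_base": om_base, "omega_ctrl": om_ctrl,
            "pct_change_erw": d_erw, "pct_change_base": d_base, "ratio": ratio}


def rate_independence_audit(runs_by_rate, ctrl_ledger, t, band_pp=5.0, start_year=None):
    """Spread of the backflux p across deployment rates at fixed time.

    ``runs_by_rate`` maps rate (GtCO2/yr) to its experiment ledger.
    Returns a report dict; ``within_band`` flags whether the max-min
    spread of the (member-median) p stays inside ``band_pp`` percentage
    points.
    """
    ps = {}
    for rate, led in runs_by_rate.items():
        p = backflux_percent(led, ctrl_ledger, t, start_year)
        ps[rate] = float(np.median(p))
    values = np.array(list(ps.values()))
    spread = float(values.max() - values.min()) if values.size else 0.0
    return {"p_by_rate": ps, "spread_pp": spread, "band_pp": band_pp,
            "within_band": spread <= band_pp}


def ensemble_summary(values, interval=0.68):
    """Median and central interval of an ensemble statistic.

    Returns (median, lo, hi, std): both a percentile envelope (default
    central 68%) and the standard deviation, since published "±" bands
    may denote either.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    lo, hi = np.percentile(v, [50 * (1 - interval), 50 * (1 + interval)])
    return float(np.median(v)), float(lo), float(hi), float(np.std(v))
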