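"""Programmatic test fixtures.

Everything the test suite needs that is not a live model run is built
here, deterministically from a seed: a miniature concentration pathway,
a small slab-parameter prior sample, toy flux ledgers whose backflux
has a closed-form value, and a two-box ocean configuration whose
transport has an analytic exponential solution.
"""

from __future__ import annotations

import numpy as np

from .constants import OCEAN_AREA
from .ensemble import ParameterPrior, sample_priors
from .forcing import synthesize_pathway
from .ledger import RunLedger
from .ocean import BoxGeometry, CirculationConfig

__all__ = ["make_fixtures", "toy_ledger_pair", "two_box_setup"]


def toy_ledger_pair(backflux_fraction=0.3, rate_gtco2=10.0, start_year=2030,
                    end_year=2100, sea_share=0.6):
    """(experiment, control) ledgers with excess outgassing proportional
    to deployment: eta = 1 - backflux_fraction in closed form."""
    years = np.arange(1765, end_year + 1)
    active = years >= start_year
    ctrl = RunLedger(years=years, meta={"scenario": "toy", "mode": "control",
                                        "rate_gtco2": rate_gtco2, "start_year": start_year})
    exp = RunLedger(years=years, meta={"scenario": "toy", "mode": "baseline",
                                       "rate_gtco2": rate_gtco2, "start_year": start_year})
    exp.j_cdr = np.where(active, rate_gtco2, 0.0)
    excess = backflux_fraction * rate_gtco2
    exp.j_sea_air = np.where(active, sea_share * excess, 0.0)
    exp.j_lnd_air = np.where(active, (1.0 - sea_share) * excess, 0.0)
    return exp, ctrl


def two_box_setup(exchange_sv=20.0):
    """Two-box geometry + pure-mixing circulation with a closed-form
    solution: the concentration difference decays as
    exp(-q (1/V1 + 1/V2) t)."""
    v1, v2 = 4.0e17, 9.3e17
    geometry = BoxGeometry(
        names=("surface", "deep"),
        volume=[v1, v2],
        area=[OCEAN_AREA, 0.0],
        pressure=[0.0, 200.0],
        base_temperature=[15.0, 2.5],
        warming_fraction=[1.0, 0.0],
    )
    circulation = CirculationConfig(overturning_sv=0.0, overturning_path=(0, 1),
                                    mixing_sv={(0, 1): exchange_sv})
    return geometry, circulation


def make_fixtures(seed=0):
    """Build the shipped fixture bundle, byte-stable for a given seed."""
    pathway = synthesize_pathway(
        [(1765, 278.0), (1900, 296.0), (2000, 369.0), (2060, 480.0), (2120, 560.0)],
        label="mini", end_year=2120)
    params = sample_priors(ParameterPrior(), 50, seed)
    exp, ctrl = toy_ledger_pair()
    geometry, circulation = two_box_setup()
    return {
        "pathway": pathway,
        "slab_params": params,
        "toy_ledgers": (exp, ctrl),
        "toy_eta": 0.7,
        "two_box": (geometry, circulation),
        "seed": seed,
    }


def write_fixtures(outdir, seed=0):
    """Write the text-format fixture files (CSV) to a directory."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fx = make_fixtures(seed)
    fx["pathway"].to_csv(out / "mini_pathway.csv")
    fx["slab_params"].to_dataframe().to_csv(out / "slab_prior_sample.csv", index=False)
    exp, ctrl = fx["toy_ledgers"]
    exp.to_dataframe().to_csv(out / "toy_experiment_ledger.csv", index=False)
    ctrl.to_dataframe().to_csv(out / "toy_control_ledger.csv", index=False)
    return sorted(p.name for p in out.iterdir())
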