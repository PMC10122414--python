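"""Run ledger: the annual accounting of every boundary flux of a run.

The backflux and leakage diagnostics are pure functions of these
ledgers, so the ledger records everything their integrals need:
CDR deployment, sea-air and land-air exchange, net emissions,
weathering/rock inputs, and burial, plus reservoir inventories and
surface carbonate chemistry.

Sign convention: every flux is positive INTO the atmosphere
(J_CDR is the deployment magnitude, positive).

Time axis: ``years[i]`` labels the calendar year i; flux entries are
annual means over that year, inventory/chemistry entries are snapshots
at the start of that year. "Through year Y" integrals include the
full year Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RunLedger"]

FLUX_FIELDS = (
    "emissions", "j_cdr", "j_sea_air", "j_lnd_air",  # GtCO2/yr
    "weathering_dic_mol", "weathering_alk_mol",  # mol/yr
    "erw_dic_mol", "erw_alk_mol",  # mol/yr
    "rock_dic_gtco2",  # rock-derived carbon input, GtCO2/yr
    "burial_gtc",  # GtC/yr
)
STATE_FIELDS = (
    "atm_co2_ppm", "veg_gtc", "soil_gtc", "ocean_dic_gtc", "ocean_alk_mol",
    "surface_pco2", "surface_ph", "surface_omega_arg", "surface_omega_cal",
    "subsurface_dic_gtc", "t_anomaly",
)


@dataclass
class RunLedger:
    """Annual time series of one model run (possibly ensemble-stacked).

    Every series is shaped (..., n_years) with a shared leading
    ensemble dimension (or none).
    """

    years: np.ndarray
    emissions: np.ndarray = None
    j_cdr: np.ndarray = None
    j_sea_air: np.ndarray = None
    j_lnd_air: np.ndarray = None
    weathering_dic_mol: np.ndarray = None
    weathering_alk_mol: np.ndarray = None
    erw_dic_mol: np.ndarray = None
    erw_alk_mol: np.ndarray = None
    rock_dic_gtco2: np.ndarray = None
    burial_gtc: np.ndarray = None
    atm_co2_ppm: np.ndarray = None
    veg_gtc: np.ndarray = None
    soil_gtc: np.ndarray = None
    ocean_dic_gtc: np.ndarray = None
    ocean_alk_mol: np.ndarray = None
    subsurface_dic_gtc: np.ndarray = None
    surface_pco2: np.ndarray = None
    surface_ph: np.ndarray = None
    surface_omega_arg: np.ndarray = None
    surface_omega_cal: np.ndarray = None
    t_anomaly: np.ndarray = None
    meta: dict = field(default_factory=dict)
    emission_trajectory: object = None  # set by prescribed-CO2 runs

    def __post_init__(self):
        self.years = np.asarray(self.years)
        n = self.years.size
        for f in FLUX_FIELDS + STATE_FIELDS:
            v = getattr(self, f)
            if v is None:
                setattr(self, f, np.zeros(n))
            else:
                setattr(self, f, np.asarray(v, dtype=float))

    @property
    def n_members(self):
        shape = self.emissions.shape
        return shape[0] if self.emissions.ndim > 1 else 1

    def year_index(self, year):
        idx = np.searchsorted(self.years, year)
        if idx >= self.years.size or self.years[idx] != year:
            raise KeyError(f"year {year} not on ledger axis")
        return int(idx)

    def same_axis(self, other):
        return self.years.size == other.years.size and np.array_equal(self.years, other.years)

    def integrate(self, name, start_year, end_year):
        """Time integral of an annual-mean flux from start_year through
        end_year inclusive (units: flux unit * yr)."""
        i0 = self.year_index(start_year)
        i1 = self.year_index(end_year)
        series = getattr(self, name)
        return series[..., i0:i1 + 1].sum(axis=-1)

    def select(self, index):
        """Subset ensemble members (ledgers with a member dimension)."""
        kw = {"years": self.years, "meta": dict(self.meta)}
        for f in FLUX_FIELDS + STATE_FIELDS:
            v = getattr(self, f)
            kw[f] = v[index] if v.ndim > 1 else v
        return RunLedger(**kw)

    def to_dataframe(self):
        """Tidy long-format frame: (member, year, variable, value)."""
        rows = []
        for f in FLUX_FIELDS + STATE_FIELDS:
            v = np.atleast_2d(getattr(self, f))
            for m in range(v.shape[0]):
                rows.append(pd.DataFrame({
                    "member": m, "year": self.years.astype(int),
                    "variable": f, "value": v[m],
                }))
        return pd.concat(rows, ignore_index=True)

    def to_dataset(self):
        """xarray Dataset (member x year) for NetCDF output."""
        import xarray as xr

        data = {}
        for f in FLUX_FIELDS + STATE_FIELDS:
            v = np.atleast_2d(getattr(self, f))
            data[f] = (("member", "year"), v)
        ds = xr.Dataset(data, coords={"year": self.years.astype(int),
                                      "member": np.arange(self.n_members)})
        ds.attrs.update({k: str(v) for k, v in self.meta.items()})
        return ds

    def to_netcdf(self, path):
        self.to_dataset().to_netcdf(path, engine="scipy")
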