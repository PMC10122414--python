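"""YAML run configuration, serialization, and reproducibility metadata.

A :class:`RunConfig` describes a full experiment matrix — scenarios x
intervention modes x feedstocks x rates — plus the physical model
settings that differ from defaults. Every output artifact produced
from a config carries its content hash and seed, so no run is
unreproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .climate import ClimateParams
from .ocean import (BioPumpConfig, BoxGeometry, CirculationConfig,
                    GasExchangeConfig, SedimentConfig)
from .world import WorldConfig

__all__ = ["RunConfig", "config_hash", "load_config", "save_config",
           "world_config_from_dict"]


@dataclass
class RunConfig:
    """Experiment-matrix description (see ``load_config`` for YAML form)."""

    scenarios: tuple = ("mid",)
    modes: tuple = ("baseline", "erw")
    feedstocks: tuple = ("silicate",)  # used by erw mode only
    rates_gtco2: tuple = (10.0,)
    start_year: float = 2030.0
    end_year: int = 2100
    n_prior: int = 30000
    n_members: int = 130
    seed: int = 0
    world: dict = field(default_factory=dict)  # overrides for WorldConfig
    output_dir: str = "erwbox_output"

    def to_dict(self):
        d = asdict(self)
        for k in ("scenarios", "modes", "feedstocks", "rates_gtco2"):
            d[k] = list(d[k])
        return d


def config_hash(config):
    """Stable short content hash of a config (dict or RunConfig).

    The output directory is excluded: it does not affect the science, and
    identical experiments must hash identically wherever they are written.
    """
    d = config.to_dict() if hasattr(config, "to_dict") else dict(config)
    d.pop("output_dir", None)
    canon = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path):
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kw = {k: v for k, v in data.items() if k in RunConfig.__dataclass_fields__}
    for k in ("scenarios", "modes", "feedstocks", "rates_gtco2"):
        if k in kw:
            kw[k] = tuple(kw[k])
    return RunConfig(**kw)


def save_config(config, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def world_config_from_dict(overrides=None):
    """Build a WorldConfig applying nested YAML-style overrides.

    Recognized top-level keys: dt, routing, circulation (overturning_sv,
    mixing_sv as "i-j: Sv"), gas (piston_velocity_m_per_yr), bio,
    sediment, climate, geometry (volume/area/... lists).
    """
    overrides = overrides or {}
    kw = {}
    if "dt" in overrides:
        kw["dt"] = float(overrides["dt"])
    if "routing" in overrides:
        kw["routing"] = np.asarray(overrides["routing"], dtype=float)
    if "circulation" in overrides:
        c = dict(overrides["circulation"])
        if "mixing_sv" in c:
            c["mixing_sv"] = {tuple(int(x) for x in k.split("-")): float(v)
                              for k, v in c["mixing_sv"].items()}
        kw["circulation"] = CirculationConfig(**c)
    if "gas" in overrides:
        kw["gas"] = GasExchangeConfig(**overrides["gas"])
    if "bio" in overrides:
        kw["bio"] = BioPumpConfig(**overrides["bio"])
    if "sediment" in overrides:
        kw["sediment"] = SedimentConfig(**overrides["sediment"])
    if "climate" in overrides:
        kw["climate"] = ClimateParams(**overrides["climate"])
    if "geometry" in overrides:
        kw["geometry"] = BoxGeometry(**overrides["geometry"])
    return WorldConfig(**kw)
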