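"""YAML scenario configuration and topography CSV I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .domain import BeachProfile, GridSpec, HydraulicProperties, LayerModel
from .flow import FlowBC, TidalForcing
from .scenario import Scenario
from .transport import AerationModel, RateModel, TransportParams

__all__ = [
    "save_scenario",
    "load_scenario",
    "scenario_from_dict",
    "read_topography_csv",
    "write_topography_csv",
]


def save_scenario(sc: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sc.config_dict(), fh, sort_keys=False)


def scenario_from_dict(cfg: dict) -> Scenario:
    """Rebuild a :class:`Scenario` from a ``config_dict`` mapping.

    Missing sections fall back to the season's defaults.
    """
    season = cfg.get("season", "summer")
    kw: dict = {"season": season, "scale": cfg.get("scale", "desk")}
    if "grid" in cfg:
        kw["grid_spec"] = GridSpec(**cfg["grid"])
    if "forcing" in cfg:
        kw["forcing"] = TidalForcing(**cfg["forcing"])
    if "bc" in cfg:
        kw["bc"] = FlowBC(**cfg["bc"])
    if "layers" in cfg:
        kw["layers"] = LayerModel(**cfg["layers"])
    if "hydraulics" in cfg:
        kw["hydraulics"] = HydraulicProperties(**cfg["hydraulics"])
    if "rates" in cfg:
        kw["rate_model"] = RateModel(**cfg["rates"], season=season)
    if "aeration" in cfg:
        kw["aeration"] = AerationModel(**cfg["aeration"])
    if "transport" in cfg:
        t = dict(cfg["transport"])
        if t.get("temperature_C") is None:
            t["temperature_C"] = np.nan
        kw["transport"] = TransportParams(**t)
    if "topography_csv" in cfg:
        kw["profile"] = read_topography_csv(cfg["topography_csv"])
    for key, val in cfg.get("numerics", {}).items():
        kw[key] = val
    return Scenario(**kw)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def read_topography_csv(path) -> BeachProfile:
    """Two-column CSV (x_m, z_m_asl) with a header row."""
    df = pd.read_csv(path)
    need = {"x_m", "z_m_asl"}
    if not need.issubset(df.columns):
        raise ValueError(f"topography CSV needs columns {sorted(need)}")
    x = df["x_m"].to_numpy(float)
    z = df["z_m_asl"].to_numpy(float)
    order = np.argsort(x)
    x, z = x[order], z[order]
    slope = -np.polyfit(x, z, 1)[0]
    return BeachProfile(x=x, z=z, mean_slope=float(slope))


def write_topography_csv(profile: BeachProfile, path) -> None:
    pd.DataFrame({"x_m": profile.x, "z_m_asl": profile.z}).to_csv(path, index=False)
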