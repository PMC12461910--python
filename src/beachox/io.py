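"""NetCDF serialisation of flow and O2 solutions (xarray, NETCDF3)."""

from __future__ import annotations

import json

import numpy as np
import xarray as xr
import yaml

from .flow import PeriodicFlowField
from .scenario import Scenario
from .transport import O2Field

__all__ = ["save_flow", "load_flow", "save_o2", "load_o2"]

_ENGINE = "scipy"


def save_flow(flow: PeriodicFlowField, path, scenario: Scenario | None = None) -> None:
    """Write a periodic flow field to NetCDF (scenario config echoed as attrs)."""
    ds = xr.Dataset(
        {
            "theta": (("edge", "z", "x"), flow.theta),
            "saturation": (("edge", "z", "x"), flow.saturation),
            "head": (("edge", "z", "x"), flow.head),
            "Qv": (("snap", "vface"), flow.Qv),
            "Qh": (("snap", "hface"), flow.Qh),
            "Q_top": (("snap", "x"), flow.Q_top),
            "land_src": (("snap", "cell"), flow.land_src),
            "sea": (("edge",), flow.sea),
            "times": (("snap",), flow.times),
        },
        coords={"z": flow.grid.zc, "x": flow.grid.xc},
        attrs={
            "residual_history": json.dumps(flow.residual_history),
            "cycles": flow.cycles,
            "config": yaml.safe_dump(scenario.config_dict()) if scenario else "",
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def load_flow(path, scenario: Scenario | None = None) -> PeriodicFlowField:
    """Rebuild a flow field; the grid/model comes from the stored (or given) config."""
    from .config import scenario_from_dict

    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    if scenario is None:
        cfg = yaml.safe_load(ds.attrs.get("config") or "") or None
        if cfg is None:
            raise ValueError("file has no embedded config; pass scenario=")
        scenario = scenario_from_dict(cfg)
    model = scenario.build_flow_model()
    return PeriodicFlowField(
        grid=model.grid, forcing=scenario.forcing,
        times=ds["times"].values, theta=ds["theta"].values,
        saturation=ds["saturation"].values, head=ds["head"].values,
        Qv=ds["Qv"].values, Qh=ds["Qh"].values, Q_top=ds["Q_top"].values,
        land_src=ds["land_src"].values, sea=ds["sea"].values,
        residual_history=json.loads(ds.attrs.get("residual_history", "[]")),
        cycles=int(ds.attrs.get("cycles", 0)), model=model)


def save_o2(o2: O2Field, path, scenario: Scenario | None = None) -> None:
    ds = xr.Dataset(
        {"O2_umolL": (("edge", "z", "x"), o2.C)},
        coords={"z": o2.grid.zc, "x": o2.grid.xc},
        attrs={
            "budget": json.dumps(o2.budget),
            "residual_history": json.dumps(o2.residual_history),
            "oxic_volume_history": json.dumps(o2.oxic_volume_history),
            "cycles": o2.cycles,
            "converged": int(o2.converged),
            "config": yaml.safe_dump(scenario.config_dict()) if scenario else "",
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def load_o2(path, grid) -> O2Field:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    n_edge = ds.sizes["edge"]
    times = np.arange(n_edge - 1) / (n_edge - 1)
    return O2Field(grid=grid, times=times, C=ds["O2_umolL"].values,
                   residual_history=json.loads(ds.attrs.get("residual_history", "[]")),
                   cycles=int(ds.attrs.get("cycles", 0)),
                   converged=bool(ds.attrs.get("converged", 0)),
                   budget=json.loads(ds.attrs.get("budget", "{}")),
                   oxic_volume_history=json.loads(
                       ds.attrs.get("oxic_volume_history", "[]")))
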