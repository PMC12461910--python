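"""Shared fixtures: session-scoped scenario runs so the suite solves each
flow/transport problem once."""

import numpy as np
import pytest

from beachox import Scenario
from beachox.diagnostics import assemble_report


@pytest.fixture(scope="session")
def desk_summer():
    return Scenario.summer(scale="desk")


@pytest.fixture(scope="session")
def desk_winter():
    return Scenario.winter(scale="desk")


@pytest.fixture(scope="session")
def summer_flow(desk_summer):
    return desk_summer.run_flow()


@pytest.fixture(scope="session")
def winter_flow(desk_winter):
    return desk_winter.run_flow()


@pytest.fixture(scope="session")
def summer_o2(desk_summer, summer_flow):
    return desk_summer.run_o2(summer_flow)


@pytest.fixture(scope="session")
def winter_o2(desk_winter, winter_flow):
    return desk_winter.run_o2(winter_flow)


@pytest.fixture(scope="session")
def summer_o2_noaer(desk_summer, summer_flow):
    return desk_summer.run_o2(summer_flow, aeration=False)


@pytest.fixture(scope="session")
def summer_report(summer_flow, summer_o2):
    return assemble_report(summer_flow, summer_o2, season="summer")


@pytest.fixture(scope="session")
def winter_report(winter_flow, winter_o2):
    return assemble_report(winter_flow, winter_o2, season="winter")


@pytest.fixture(scope="session")
def mid_summer_result():
    """Finest configuration the default suite runs (45 x 150, full depth)."""
    sc = Scenario.summer(scale="mid")
    flow = sc.run_flow()
    return sc, flow, sc.run_o2(flow), sc.run_o2(flow, aeration=False)


@pytest.fixture(scope="session")
def mid_winter_result():
    sc = Scenario.winter(scale="mid")
    flow = sc.run_flow()
    return sc, flow, sc.run_o2(flow), None


@pytest.fixture(scope="session")
def mini_result():
    """Small, fast full-pipeline run for I/O and plumbing tests."""
    sc = Scenario.summer(scale="mini")
    flow = sc.run_flow()
    o2 = sc.run_o2(flow)
    return sc, flow, o2


def make_column_flow(n_cells=120, dz=0.05, v_pore=1.0, porosity=0.35,
                     n_snap=1, period_days=0.05):
    """Fabricate a steady 1D downward-flow column as a PeriodicFlowField.

    Water enters the (submerged) surface at Darcy flux ``v_pore * porosity``
    and is extracted from the bottom cell, giving a uniform pore velocity —
    the method-of-characteristics reference configuration for transport
    tests.
    """
    from beachox.domain import BeachProfile, GridSpec, Grid
    from beachox.flow import FlowBC, FlowModel, PeriodicFlowField, TidalForcing
    from beachox.domain import HydraulicProperties, LayerModel

    L = n_cells * dz
    spec = GridSpec(n_columns=1, n_layers=n_cells, dx=1.0, dz_top=dz,
                    dz_bottom=dz, z_top=0.0, z_bottom=-L, x_left=0.0)
    profile = BeachProfile(x=np.array([-1.0, 2.0]), z=np.array([0.0, 0.0]),
                           mean_slope=1e-3)
    grid = Grid(spec, profile)
    props = HydraulicProperties(porosity=porosity)
    model = FlowModel(grid, props, LayerModel(z_layer12=-2 * L, z_layer23=-3 * L),
                      FlowBC(Q_in=0.0))
    q = v_pore * porosity            # Darcy flux, m/d
    theta = np.where(grid.active, porosity, np.nan)
    ones = np.ones((n_snap + 1, 1, 1))
    forcing = TidalForcing(amplitude=1.0, period_hours=period_days * 24.0)
    Qv = np.full((n_snap, len(model.vf_G)), q * spec.dx)
    src = np.zeros((n_snap, model.n_eq))
    src[:, -1] = -q * spec.dx        # bottom extraction balances the inflow
    return PeriodicFlowField(
        grid=grid, forcing=forcing,
        times=np.arange(n_snap) * period_days / n_snap,
        theta=theta[None] * ones, saturation=(theta / porosity)[None] * ones,
        head=np.zeros((n_snap + 1,) + grid.shape),
        Qv=Qv, Qh=np.zeros((n_snap, 0)),
        Q_top=np.full((n_snap, 1), q * spec.dx),
        land_src=src, sea=np.ones(n_snap + 1), model=model)
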