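"""Scenario presets: bundle geometry, forcing and reaction parameters.

Two seasonal scenarios are shipped.  They share tidal/wave forcing,
freshwater influx, geology and hydraulics; they differ in beach profile
(slope 1.9 percent with a slight mid-beach depression in summer, 1.7
percent in winter), air-saturated O2 (225 vs 310 umol/L), temperature
(22.2 vs 6.7 degC) and the measured O2 consumption profile.  Grid
scales: ``paper`` is the full 90 x 300 configuration; ``desk`` is a
30 x 100 configuration for quick runs and CI-sized tests.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np

from .domain import BeachProfile, GridSpec, Grid, HydraulicProperties, LayerModel, build_grid
from .flow import FlowBC, FlowModel, PeriodicFlowField, TidalForcing, run_to_periodic
from .synthetic import gen_topography
from .transport import (AerationModel, O2Field, RateModel, TransportParams,
                        run_to_quasi_steady)

__all__ = ["Scenario", "ScenarioResult", "GRID_SCALES"]

GRID_SCALES = {
    "paper": GridSpec(),
    "desk": GridSpec(n_columns=100, n_layers=30, dx=2.4, dz_top=0.12,
                     dz_bottom=3.5, z_top=2.4, z_bottom=-30.0),
    "mid": GridSpec(n_columns=150, n_layers=45, dx=1.6, dz_top=0.08,
                    dz_bottom=2.6, z_top=2.4, z_bottom=-40.0),
    "mini": GridSpec(n_columns=48, n_layers=20, dx=5.0, dz_top=0.2,
                     dz_bottom=3.0, z_top=2.4, z_bottom=-16.0),
}


@dataclass(frozen=True)
class Scenario:
    """A complete, runnable model configuration."""

    season: str = "summer"
    scale: str = "desk"
    grid_spec: GridSpec | None = None
    profile: BeachProfile | None = None
    forcing: TidalForcing = field(default_factory=TidalForcing)
    bc: FlowBC = field(default_factory=FlowBC)
    layers: LayerModel = field(default_factory=LayerModel)
    hydraulics: HydraulicProperties = field(default_factory=HydraulicProperties)
    transport: TransportParams | None = None
    rate_model: RateModel | None = None
    aeration: AerationModel | None = None
    temperature_C: float | None = None
    # numerics
    n_snap: int = 50
    steps_per_snap: int = 1
    flow_tol: float = 1e-3
    flow_max_cycles: int = 80
    o2_tol: float = 1e-3
    o2_max_cycles: int = 400

    @classmethod
    def summer(cls, scale: str = "desk", **kw) -> "Scenario":
        return cls(season="summer", scale=scale, temperature_C=22.2, **kw)

    @classmethod
    def winter(cls, scale: str = "desk", **kw) -> "Scenario":
        return cls(season="winter", scale=scale, temperature_C=6.7, **kw)

    # -- resolved components ---------------------------------------------
    def resolve_grid_spec(self) -> GridSpec:
        if self.grid_spec is not None:
            return self.grid_spec
        try:
            return GRID_SCALES[self.scale]
        except KeyError:
            raise ValueError(f"unknown grid scale {self.scale!r}") from None

    def resolve_profile(self) -> BeachProfile:
        if self.profile is not None:
            return self.profile
        spec = self.resolve_grid_spec()
        return gen_topography(self.season,
                              x_range=(spec.x_left, spec.x_left + spec.width))

    def resolve_rate_model(self) -> RateModel:
        if self.rate_model is not None:
            return self.rate_model
        return RateModel.summer() if self.season == "summer" else RateModel.winter()

    def resolve_aeration(self, enabled: bool = True) -> AerationModel:
        base = self.aeration
        if base is None:
            base = (AerationModel.summer() if self.season == "summer"
                    else AerationModel.winter())
        return base if enabled else base.disabled()

    def resolve_transport(self) -> TransportParams:
        if self.transport is not None:
            return self.transport
        return TransportParams(temperature_C=self.temperature_C
                               if self.temperature_C is not None else np.nan)

    def build_grid(self) -> Grid:
        return build_grid(self.resolve_profile(), self.resolve_grid_spec())

    def build_flow_model(self, grid: Grid | None = None) -> FlowModel:
        return FlowModel(grid or self.build_grid(), self.hydraulics,
                         self.layers, self.bc)

    # -- pipeline ---------------------------------------------------------
    def run_flow(self, verbose: bool = False) -> PeriodicFlowField:
        model = self.build_flow_model()
        return run_to_periodic(model, self.forcing, n_snap=self.n_snap,
                               steps_per_snap=self.steps_per_snap,
                               tol=self.flow_tol, max_cycles=self.flow_max_cycles,
                               verbose=verbose)

    def run_o2(self, flow: PeriodicFlowField, aeration: bool = True,
               verbose: bool = False, **kw) -> O2Field:
        return run_to_quasi_steady(flow, self.resolve_rate_model(),
                                   self.resolve_aeration(aeration),
                                   self.resolve_transport(),
                                   tol=self.o2_tol,
                                   max_cycles=self.o2_max_cycles,
                                   verbose=verbose, **kw)

    def run(self, aeration: bool = True, verbose: bool = False) -> "ScenarioResult":
        t0 = _time.perf_counter()
        flow = self.run_flow(verbose=verbose)
        o2 = self.run_o2(flow, aeration=aeration, verbose=verbose)
        return ScenarioResult(scenario=self, flow=flow, o2=o2,
                              wall_seconds=_time.perf_counter() - t0)

    def config_dict(self) -> dict:
        """Flat, YAML-serialisable echo of every resolved parameter."""
        spec = self.resolve_grid_spec()
        rm = self.resolve_rate_model()
        aer = self.resolve_aeration()
        tp = self.resolve_transport()
        return {
            "season": self.season,
            "scale": self.scale,
            "grid": {k: getattr(spec, k) for k in
                     ("n_columns", "n_layers", "dx", "dz_top", "dz_bottom",
                      "z_top", "z_bottom", "x_left")},
            "forcing": {"amplitude": self.forcing.amplitude,
                        "period_hours": self.forcing.period_hours,
                        "significant_wave_height": self.forcing.significant_wave_height,
                        "setup_factor": self.forcing.setup_factor},
            "bc": {"Q_in": self.bc.Q_in},
            "layers": {"z_layer12": self.layers.z_layer12,
                       "z_layer23": self.layers.z_layer23,
                       "K_layer2": self.layers.K_layer2,
                       "K_layer3": self.layers.K_layer3},
            "hydraulics": {k: getattr(self.hydraulics, k) for k in
                           ("K0_surface", "z_star", "decay_depth", "porosity",
                            "residual_saturation", "vg_alpha", "vg_n",
                            "specific_storage", "hazen_coefficient")},
            "rates": {"R0": rm.R0, "z_decay": rm.z_decay, "R_inf": rm.R_inf,
                      "K_O2": rm.K_O2},
            "aeration": {"C_sat": aer.C_sat, "k_aer": aer.k_aer,
                         "S_threshold": aer.S_threshold},
            "transport": {"alpha_L": tp.alpha_L, "alpha_T": tp.alpha_T,
                          "D_m": tp.D_m, "salinity_PSU": tp.salinity_PSU,
                          "temperature_C": None if np.isnan(tp.temperature_C)
                          else tp.temperature_C},
            "numerics": {"n_snap": self.n_snap,
                         "steps_per_snap": self.steps_per_snap,
                         "flow_tol": self.flow_tol,
                         "flow_max_cycles": self.flow_max_cycles,
                         "o2_tol": self.o2_tol,
                         "o2_max_cycles": self.o2_max_cycles},
        }


@dataclass
class ScenarioResult:
    scenario: Scenario
    flow: PeriodicFlowField
    o2: O2Field
    wall_seconds: float = np.nan

    def report(self):
        from .diagnostics import assemble_report
        return assemble_report(self.flow, self.o2, season=self.scenario.season)
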