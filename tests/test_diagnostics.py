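"""Oxic-volume, penetration, partition and station-comparison diagnostics."""

import numpy as np
import pandas as pd
import pytest

from beachox.diagnostics import (assemble_report, compare_stations,
                                 desaturated_volume, infiltration_partition,
                                 oxic_volume, penetration_depth,
                                 permanently_unsaturated_mask, sample_field,
                                 seasonal_redox_volume, tide_average)
from beachox.domain import BeachProfile, GridSpec, Grid

from conftest import make_column_flow


def flat_grid(nz=10, nx=10, dz=1.0, dx=10.0):
    spec = GridSpec(n_columns=nx, n_layers=nz, dx=dx, dz_top=dz, dz_bottom=dz,
                    z_top=0.0, z_bottom=-nz * dz, x_left=0.0)
    profile = BeachProfile(x=np.array([-1.0, nx * dx + 1.0]),
                           z=np.array([0.0, 0.0]), mean_slope=1e-3)
    return Grid(spec, profile)


class TestTideAverage:
    def test_constant_field(self):
        f = np.full((5, 3, 3), 7.0)
        assert np.allclose(tide_average(f), 7.0)

    def test_zero_mean_sine(self):
        t = np.arange(200) / 200
        vals = np.sin(2 * np.pi * t)[:, None] * np.ones((200, 4))
        assert np.allclose(tide_average(vals), 0.0, atol=1e-12)

    def test_weighted_two_snapshot_mean(self):
        assert tide_average(np.array([1.0, 3.0]),
                            durations=[0.5, 0.5]) == pytest.approx(2.0)

    def test_bad_durations_rejected(self):
        with pytest.raises(ValueError):
            tide_average(np.array([1.0, 2.0]), durations=[1.0])


class TestOxicVolume:
    def test_uniform_above_threshold(self):
        g = flat_grid()  # 100 cells of 10 m2 each
        C = np.full(g.shape, 2.0)
        assert oxic_volume(C, g) == pytest.approx(1000.0)

    def test_below_threshold_counts_nothing(self):
        g = flat_grid()
        assert oxic_volume(np.full(g.shape, 0.5), g) == 0.0

    def test_threshold_is_strict(self):
        g = flat_grid()
        assert oxic_volume(np.full(g.shape, 1.0), g) == 0.0

    def test_mask_and_porosity_conventions(self):
        g = flat_grid()
        C = np.full(g.shape, 2.0)
        mask = np.zeros(g.shape, bool)
        mask[:, :5] = True
        assert oxic_volume(C, g, exclude_mask=mask) == pytest.approx(500.0)
        assert oxic_volume(C, g, porosity=0.35) == pytest.approx(350.0)
        with pytest.raises(ValueError):
            oxic_volume(C, g, exclude_mask=np.zeros((2, 2), bool))

    def test_average_between_snapshot_extremes(self, summer_o2, summer_flow):
        g = summer_flow.grid
        mask = permanently_unsaturated_mask(summer_flow)
        snaps = [oxic_volume(summer_o2.C[k], g, exclude_mask=mask)
                 for k in range(summer_o2.C.shape[0])]
        avg = oxic_volume(summer_o2.tide_averaged(), g, exclude_mask=mask)
        assert min(snaps) <= avg <= max(snaps)


class TestPenetrationDepth:
    def test_top_cell_only(self):
        g = flat_grid(dz=0.05)
        C = np.zeros(g.shape)
        C[0, :] = 5.0
        assert penetration_depth(C, g) == pytest.approx(0.05)

    def test_deepest_column_wins(self):
        g = flat_grid(dz=1.0)  # 10 layers of 1 m
        C = np.zeros(g.shape)
        C[:3, :] = 5.0       # 3 m everywhere
        C[:7, 4] = 5.0       # 7 m in one column
        assert penetration_depth(C, g) == pytest.approx(7.0)

    def test_fully_anoxic_returns_zero(self):
        g = flat_grid()
        assert penetration_depth(np.zeros(g.shape), g) == 0.0

    def test_adding_oxygen_never_decreases_depth(self):
        g = flat_grid()
        rng = np.random.default_rng(3)
        C = rng.uniform(0, 3, g.shape)
        base = penetration_depth(C, g)
        C2 = C.copy()
        C2[8, 2] = 5.0
        assert penetration_depth(C2, g) >= base


class TestInfiltrationPartition:
    def test_all_influx_is_100_percent(self):
        flow = make_column_flow(n_snap=2)
        flow.sea[:] = 10.0   # whole (flat) surface intertidal & submerged
        from dataclasses import replace
        flow.forcing = replace(flow.forcing, amplitude=11.0)
        part = infiltration_partition(flow)
        assert part["net_infiltration_area_fraction"] == pytest.approx(100.0)

    def test_antisymmetric_pattern_is_50_percent(self, summer_flow):
        import copy
        flow = copy.copy(summer_flow)
        Q = np.zeros_like(flow.Q_top)
        inter = (flow.grid.surface >= flow.forcing.low_water) & \
                (flow.grid.surface <= flow.forcing.high_water)
        cols = np.nonzero(inter)[0]
        Q[:, cols[:len(cols) // 2]] = 1.0
        Q[:, cols[len(cols) // 2:]] = -1.0
        flow.Q_top = Q
        part = infiltration_partition(flow)
        assert part["net_infiltration_area_fraction"] == pytest.approx(50.0, abs=2.0)

    def test_summer_zone_structure(self, summer_flow):
        part = infiltration_partition(summer_flow)
        assert 0.0 <= part["net_infiltration_area_fraction"] <= 100.0
        assert part["infiltration_rate"] > 0


class TestDesaturatedVolume:
    def test_fully_saturated_is_zero(self):
        flow = make_column_flow()
        flow.sea[:] = 10.0
        from dataclasses import replace
        flow.forcing = replace(flow.forcing, amplitude=11.0)
        assert desaturated_volume(flow)["volume"] == 0.0

    def test_synthetic_layer_volume(self, summer_flow):
        import copy
        flow = copy.copy(summer_flow)
        g = flow.grid
        S = np.where(g.active, 1.0, np.nan)[None].repeat(len(flow.sea), axis=0)
        inter = (g.surface >= flow.forcing.low_water) & \
                (g.surface <= flow.forcing.high_water)
        cols = np.nonzero(inter)[0][:int(round(30.0 / g.dx))]  # 30 m wide
        depth = g.depth_below_surface()
        sel = (depth < 0.6)  # top 0.6 m
        for j in cols:
            S[:, sel[:, j], j] = 0.5
        flow.saturation = S
        out = desaturated_volume(flow)
        expect = sum(g.cell_volume[sel[:, j], j].sum() for j in cols)
        assert out["volume"] == pytest.approx(expect)
        assert expect == pytest.approx(18.0, rel=0.3)  # ~0.6 m x 30 m


class TestStationComparison:
    def test_perfect_observations_give_r2_of_1(self, summer_o2, summer_flow):
        g = summer_flow.grid
        Cavg = summer_o2.tide_averaged()
        rows = [{"x": x, "depth": d,
                 "O2": sample_field(Cavg, g, x, d)}
                for x in (10.0, 40.0, 70.0) for d in (0.5, 1.5)]
        out = compare_stations(Cavg, g, pd.DataFrame(rows))
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_observations_give_nonpositive_r2(self, summer_o2,
                                                       summer_flow):
        g = summer_flow.grid
        Cavg = summer_o2.tide_averaged()
        rows = [{"x": x, "depth": 0.5, "O2": 100.0}
                for x in (5.0, 25.0, 50.0, 75.0, 100.0)]
        out = compare_stations(Cavg, g, pd.DataFrame(rows))
        assert out["r_squared"] <= 0.0

    def test_too_few_or_outside_rejected(self, summer_o2, summer_flow):
        g = summer_flow.grid
        Cavg = summer_o2.tide_averaged()
        with pytest.raises(ValueError):
            compare_stations(Cavg, g, pd.DataFrame([{"x": 1.0, "depth": 1.0,
                                                     "O2": 5.0}]))
        bad = pd.DataFrame([{"x": 1e4, "depth": 1.0, "O2": 5.0},
                            {"x": 2.0, "depth": 1.0, "O2": 5.0}])
        with pytest.raises(ValueError, match="outside"):
            compare_stations(Cavg, g, bad)


class TestReport:
    def test_deterministic_assembly(self, summer_flow, summer_o2):
        a = assemble_report(summer_flow, summer_o2, season="summer")
        b = assemble_report(summer_flow, summer_o2, season="summer")
        assert a.to_json() == b.to_json()
        assert a.to_frame().to_csv(index=False) == b.to_frame().to_csv(index=False)

    def test_supply_decomposition_is_additive(self, summer_report):
        assert summer_report.O2_supply_total == pytest.approx(
            summer_report.O2_supply_infiltration
            + summer_report.O2_supply_aeration)

    def test_oxic_fluctuation_small_versus_mean(self, summer_report,
                                                winter_report):
        """Tidal oxic-volume fluctuation is minor against the tide average."""
        for rep in (summer_report, winter_report):
            assert rep.oxic_volume_fluctuation < 0.05 * rep.oxic_volume

    def test_seasonal_redox_volume(self):
        assert seasonal_redox_volume(711.0, 849.6) == pytest.approx(138.6)
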