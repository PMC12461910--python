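"""Reaction kinetics, rate-profile fitting, and transport-scheme verification."""

import numpy as np
import pytest

from beachox.transport import (AerationModel, RateModel, TransportParams,
                               aeration_source, consumption_rate,
                               fit_rate_profile, run_to_quasi_steady)

from conftest import make_column_flow


class TestConsumptionRate:
    def test_no_oxygen_no_consumption(self):
        assert consumption_rate(0.1, 0.0, RateModel.summer()) == 0.0

    @pytest.mark.parametrize("model,floor", [(RateModel.winter(), 0.1),
                                             (RateModel.summer(), 0.19)])
    def test_deep_floor_rates(self, model, floor):
        # far below the reactive layer, C >> K_O2: rate -> seasonal floor
        assert consumption_rate(10.0, 1e4, model) == pytest.approx(floor, rel=1e-3)

    def test_summer_rate_dominates_winter_at_all_depths(self):
        z = np.linspace(0, 2, 50)
        assert np.all(RateModel.summer().depth_rate(z)
                      >= RateModel.winter().depth_rate(z))

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            consumption_rate(-0.1, 10.0, RateModel.summer())

    def test_monotone_non_increasing_with_depth(self):
        z = np.linspace(0, 5, 200)
        r = RateModel.summer().depth_rate(z)
        assert np.all(np.diff(r) <= 0)
        assert np.all(r >= RateModel.summer().R_inf)


class TestRateProfileFit:
    def test_exact_recovery(self):
        model = RateModel(R0=50.0, z_decay=0.15, R_inf=0.19)
        z = np.linspace(0, 0.7, 14)
        fit = fit_rate_profile(list(zip(z, model.depth_rate(z))))
        assert fit["R0"] == pytest.approx(50.0, rel=1e-5)
        assert fit["z_decay"] == pytest.approx(0.15, rel=1e-5)
        assert fit["R_inf"] == pytest.approx(0.19, rel=1e-4)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_fifteen_percent(self):
        rng = np.random.default_rng(11)
        model = RateModel(R0=50.0, z_decay=0.15, R_inf=0.19)
        z = np.linspace(0, 0.7, 14)
        sigma = np.sqrt(np.log1p(0.10 ** 2))
        r = model.depth_rate(z) * rng.lognormal(-sigma**2 / 2, sigma, 14)
        fit = fit_rate_profile(list(zip(z, r)))
        assert fit["R0"] == pytest.approx(50.0, rel=0.15)
        assert fit["z_decay"] == pytest.approx(0.15, rel=0.15)

    def test_flat_profile_caps_decay_length(self):
        z = np.linspace(0, 0.7, 8)
        fit = fit_rate_profile([(zi, 0.19) for zi in z])
        assert fit["capped"]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_rate_profile([(0.1, 1.0)] * 6)
        with pytest.raises(ValueError):
            fit_rate_profile([(0.0, 1.0), (0.1, 2.0), (0.2, 3.0)])


class TestAeration:
    def test_off_above_threshold(self):
        assert aeration_source(0.99, 0.0, AerationModel.summer()) == 0.0

    def test_zero_at_equilibrium(self):
        m = AerationModel.summer()
        assert aeration_source(0.9, m.C_sat, m) == 0.0

    def test_initial_rate_and_relaxation_time(self):
        m = AerationModel.summer(k_aer=10.0)
        assert aeration_source(0.9, 0.0, m) == pytest.approx(2250.0)
        # closed parcel: C(t) = C_sat (1 - exp(-k t)); within 1% at ln(100)/k
        t99 = np.log(100.0) / m.k_aer
        assert t99 <= 0.47
        assert m.C_sat * (1 - np.exp(-m.k_aer * t99)) == pytest.approx(
            0.99 * m.C_sat)

    def test_never_drives_beyond_saturation(self):
        m = AerationModel.summer()
        assert aeration_source(0.5, m.C_sat + 50.0, m) == 0.0

    def test_disabled_model(self):
        m = AerationModel.summer().disabled()
        assert aeration_source(0.5, 0.0, m) == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AerationModel(C_sat=-1.0)
        with pytest.raises(ValueError):
            AerationModel(C_sat=225.0, S_threshold=1.5)


class TestTransportScheme:
    def test_no_flow_no_reaction_conserves_mass(self):
        """Closed, stagnant column: concentrations frozen, mass exact."""
        flow = make_column_flow(n_cells=40, v_pore=0.0)
        flow.Q_top[:] = 0.0
        flow.land_src[:] = 0.0
        rate = RateModel(R0=1e-9, z_decay=1.0, R_inf=1e-9, K_O2=1.0)
        o2 = run_to_quasi_steady(flow, rate, AerationModel.summer().disabled(),
                                 TransportParams(alpha_L=0.0, alpha_T=0.0,
                                                 D_m=1e-12),
                                 C0=np.full(flow.grid.shape, 100.0),
                                 max_cycles=4)
        assert np.allclose(o2.C[-1][flow.grid.active], 100.0, atol=1e-6)

    def test_steady_advection_reaction_profile(self):
        """1D column, v = 1 m/d, zero-order consumption 24 umol/L/d,
        inflow 225 umol/L: steady C(x) = 225 - 24 x; C(5 m) = 105."""
        from beachox.transport import O2Transport
        flow = make_column_flow(n_cells=120, dz=0.05, v_pore=1.0)
        rate = RateModel(R0=1.0, z_decay=1.0, R_inf=1.0, K_O2=1e-9)
        aer = AerationModel(C_sat=225.0, enabled=False)
        eng = O2Transport(flow, rate, aer,
                          TransportParams(alpha_L=0.0, alpha_T=0.0, D_m=1e-12))
        C = np.zeros(eng.fm.n_eq)
        for _ in range(600):         # 30 days: several column flush-throughs
            C = eng.step_interval(C, 0)
        depth = flow.grid.depth_below_surface()[flow.grid.active]
        target = 225.0 - 24.0 * depth
        i5 = np.argmin(np.abs(depth - 5.0))
        assert C[i5] == pytest.approx(105.0, rel=0.02)
        sel = depth < 5.5
        assert np.allclose(C[sel], target[sel], rtol=0.02, atol=1.0)

    def test_advection_front_tracks_velocity(self):
        """Pure advection: the 50-percent front sits at v*t within one cell."""
        from beachox.transport import O2Transport
        flow = make_column_flow(n_cells=120, dz=0.05, v_pore=1.0)
        rate = RateModel(R0=1e-9, z_decay=1.0, R_inf=1e-9)
        aer = AerationModel(C_sat=225.0, enabled=False)
        eng = O2Transport(flow, rate, aer,
                          TransportParams(alpha_L=0.0, alpha_T=0.0, D_m=1e-12))
        C = np.zeros(eng.fm.n_eq)
        t = 0.0
        for _ in range(40):          # 40 intervals of 0.05 d -> t = 2 d
            C = eng.step_interval(C, 0)
            t += flow.dt_snap
        depth = flow.grid.depth_below_surface()[flow.grid.active]
        front = depth[np.argmin(np.abs(C - 0.5 * 225.0))]
        assert abs(front - 1.0 * t) <= 3 * 0.05 + 1e-9  # upwind-smeared front

    def test_concentrations_bounded(self, summer_o2, winter_o2):
        for o2, csat in ((summer_o2, 225.0), (winter_o2, 310.0)):
            C = o2.C[np.isfinite(o2.C)]
            assert C.min() >= -1e-9
            assert C.max() <= csat + 1e-6


class TestQuasiSteady:
    def test_reaction_free_uniform_field_is_stationary(self):
        flow = make_column_flow(n_cells=30, v_pore=0.5)
        rate = RateModel(R0=1e-12, z_decay=1.0, R_inf=1e-12)
        aer = AerationModel(C_sat=200.0, enabled=False)
        o2 = run_to_quasi_steady(flow, rate, aer,
                                 TransportParams(alpha_L=0.0, D_m=1e-12,
                                                 alpha_T=0.0),
                                 C0=np.full(flow.grid.shape, 200.0),
                                 max_cycles=50)
        # inflow at C_sat equals the initial field: nothing changes
        assert o2.converged
        assert o2.cycles <= 6
        assert np.allclose(o2.C[-1][flow.grid.active], 200.0, atol=1e-6)

    def test_cycle_budget_closes(self, summer_o2, winter_o2):
        """Supply - consumption - outflow - storage change ~ 0 (vs supply)."""
        for o2 in (summer_o2, winter_o2):
            assert abs(o2.budget["closure"]) < 0.02

    def test_no_oxygenated_outflow(self, summer_o2, winter_o2):
        """Exfiltrating water is O2-free: outflow < 2 percent of supply."""
        for o2 in (summer_o2, winter_o2):
            assert o2.budget["outflow"] < 0.02 * o2.budget["supply_total"]

    def test_aeration_monotonically_increases_oxic_volume(
            self, summer_o2, summer_o2_noaer):
        assert (summer_o2.oxic_volume_history[-1]
                >= summer_o2_noaer.oxic_volume_history[-1])

    def test_aeration_supply_zero_when_disabled(self, summer_o2_noaer):
        assert summer_o2_noaer.budget.get("aeration_in", 0.0) == 0.0
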