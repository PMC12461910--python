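"""Transient variably-saturated (Richards) flow under tidal forcing.

The solver advances the mixed-form Richards equation

    d(theta)/dt = div( K kr grad(psi + z) ) + sources

with a cell-centred finite-volume discretisation (two-point flux,
harmonic-mean saturated conductivity, upstream-weighted relative
permeability) and modified-Picard implicit time stepping.  The beach
face is a switching boundary: prescribed head where the sea stands
above the sediment surface, a seepage face (psi = 0, outflow only)
where the surface is emerged but the column is saturated, and no-flow
otherwise.  Internal units: metres, days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .domain import Grid, HydraulicProperties, LayerModel

__all__ = [
    "TidalForcing",
    "FlowBC",
    "FlowModel",
    "PeriodicFlowField",
    "sea_level",
    "classify_beach_boundary",
    "run_to_periodic",
    "StepFailure",
    "NonPeriodicError",
]

HOURS_PER_DAY = 24.0


class StepFailure(RuntimeError):
    """Picard iteration failed to converge for a time step."""

    def __init__(self, msg, residual=np.nan):
        super().__init__(msg)
        self.residual = residual


class NonPeriodicError(RuntimeError):
    """Cycle iteration did not reach a periodic state."""

    def __init__(self, msg, residual_history=()):
        super().__init__(msg)
        self.residual_history = list(residual_history)


@dataclass(frozen=True)
class TidalForcing:
    """Sinusoidal tide plus a constant wave setup.

    ``wave_setup = setup_factor * significant_wave_height`` is added to the
    instantaneous tide level, representing the mean shoreward water-level
    raise by breaking waves.
    """

    amplitude: float = 1.37          # m
    period_hours: float = 12.42      # semidiurnal M2 by default
    significant_wave_height: float = 0.59  # m
    setup_factor: float = 0.2
    phase: float = 0.0               # radians

    def __post_init__(self):
        if self.amplitude <= 0 or self.period_hours <= 0:
            raise ValueError("amplitude and period must be positive")
        if self.setup_factor < 0:
            raise ValueError("setup factor must be >= 0")

    @property
    def wave_setup(self) -> float:
        return self.setup_factor * self.significant_wave_height

    @property
    def period_days(self) -> float:
        return self.period_hours / HOURS_PER_DAY

    @property
    def high_water(self) -> float:
        return self.amplitude + self.wave_setup

    @property
    def low_water(self) -> float:
        return -self.amplitude + self.wave_setup


def sea_level(t_days, forcing: TidalForcing):
    """Instantaneous sea level (m asl) at time ``t_days``."""
    t = np.asarray(t_days, dtype=float)
    out = (forcing.amplitude
           * np.sin(2.0 * np.pi * t / forcing.period_days + forcing.phase)
           + forcing.wave_setup)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FlowBC:
    """Lateral/bottom boundary conditions.

    ``Q_in`` is the fresh groundwater influx through the landward boundary
    (m3 per m shoreline per day), distributed over the saturated part of
    that boundary.  Bottom and the seaward side wall are no-flow; the beach
    face switches between prescribed head and seepage (see module docstring).
    """

    Q_in: float = 0.51

    def __post_init__(self):
        if self.Q_in < 0:
            raise ValueError("Q_in must be >= 0")


def classify_beach_boundary(psi: np.ndarray, sea: float, grid: Grid) -> np.ndarray:
    """Label each column's surface face: 'head', 'seepage' or 'noflow'.

    Submerged faces (surface below the instantaneous sea level) carry the
    prescribed sea-level head.  Emerged faces over a saturated column
    (psi >= 0 in the top active cell) form a seepage face; the rest are
    closed.
    """
    labels = np.empty(grid.shape[1], dtype=object)
    submerged = grid.surface < sea
    cols = np.arange(grid.shape[1])
    h_top = psi[grid.itop, cols] + grid.zc[grid.itop]
    labels[:] = "noflow"
    labels[(~submerged) & (h_top >= grid.surface)] = "seepage"
    labels[submerged] = "head"
    return labels


class FlowModel:
    """Finite-volume Richards solver on a terrain-following structured grid."""

    def __init__(self, grid: Grid, props: HydraulicProperties,
                 layers: LayerModel | None = None,
                 bc: FlowBC | None = None):
        self.grid = grid
        self.props = props
        self.layers = layers or LayerModel()
        self.bc = bc or FlowBC()
        self.K = props.conductivity_field(grid, self.layers)
        self._build_topology()

    # -- topology ---------------------------------------------------------
    def _build_topology(self):
        g = self.grid
        nz, nx = g.shape
        act = g.active
        self.eq = -np.ones(g.shape, dtype=int)
        self.eq[act] = np.arange(act.sum())
        self.n_eq = int(act.sum())
        self.act_i, self.act_j = np.nonzero(act)
        self.zc_cell = g.zc[self.act_i]
        self.vol = np.broadcast_to(g.dz[:, None] * g.dx, g.shape)[act]

        # vertical faces between (i, j) and (i+1, j)
        vi, vj = np.nonzero(act[:-1, :] & act[1:, :])
        self.vf_up = self.eq[vi, vj]
        self.vf_dn = self.eq[vi + 1, vj]
        dz_u, dz_d = g.dz[vi], g.dz[vi + 1]
        K_u, K_d = self.K[vi, vj], self.K[vi + 1, vj]
        Kf = (dz_u + dz_d) / (dz_u / K_u + dz_d / K_d)
        self.vf_G = Kf * g.dx / (g.zc[vi] - g.zc[vi + 1])   # conductance, m2/d per unit kr
        self.vf_i, self.vf_j = vi, vj

        # horizontal faces between (i, j) and (i, j+1)
        hi, hj = np.nonzero(act[:, :-1] & act[:, 1:])
        self.hf_l = self.eq[hi, hj]
        self.hf_r = self.eq[hi, hj + 1]
        K_l, K_r = self.K[hi, hj], self.K[hi, hj + 1]
        Kf = 2.0 * K_l * K_r / (K_l + K_r)
        self.hf_G = Kf * g.dz[hi] / g.dx
        self.hf_i, self.hf_j = hi, hj

        # surface faces (one per column, on the top active cell)
        cols = np.arange(nx)
        self.top_cell = self.eq[g.itop, cols]
        self.top_G = self.K[g.itop, cols] * g.dx / g.d_surf
        self.top_z = g.zc[g.itop]

        # landward-boundary cells (column 0)
        self.land_cells = self.eq[act[:, 0], 0]
        self.land_dz = g.dz[act[:, 0]]


    # -- constitutive -----------------------------------------------------
    def _se(self, psi):
        p = self.props
        Se = np.where(psi >= 0.0, 1.0,
                      (1.0 + (p.vg_alpha * np.abs(psi)) ** p.vg_n) ** (-p.vg_m))
        return Se

    def _theta(self, psi):
        p = self.props
        return p.porosity * (p.residual_saturation
                             + (1 - p.residual_saturation) * self._se(psi))

    def _capacity(self, psi):
        """d(theta)/d(psi), analytic van Genuchten (0 where saturated)."""
        p = self.props
        apsin = (p.vg_alpha * np.abs(psi)) ** p.vg_n
        dSe = (p.vg_m * p.vg_n * p.vg_alpha
               * (p.vg_alpha * np.abs(psi)) ** (p.vg_n - 1)
               * (1.0 + apsin) ** (-p.vg_m - 1.0))
        C = p.porosity * (1 - p.residual_saturation) * dSe
        return np.where(psi >= 0.0, 0.0, C)

    def _kr(self, psi):
        p = self.props
        Se = np.clip(self._se(psi), 1e-12, 1.0)
        return np.sqrt(Se) * (1.0 - (1.0 - Se ** (1.0 / p.vg_m)) ** p.vg_m) ** 2

    def saturation(self, psi):
        """Water saturation S in [S_r, 1] for active cells (2D array)."""
        p = self.props
        S = p.residual_saturation + (1 - p.residual_saturation) * self._se(psi)
        return np.where(self.grid.active, S, np.nan)

    # -- boundary handling ------------------------------------------------
    def _surface_bc(self, psi_flat, sea):
        """Per-column surface BC: (is_dirichlet, bc_head, kr_face, seepage_mask).

        Submerged faces carry the sea-level head.  Emerged faces act as a
        one-way drain: where the column head reaches the surface the face is
        held at atmospheric pressure (head = surface elevation), giving an
        outflow proportional to ``max(h - z_surf, 0)`` that is continuous in
        the head, so the face classification settles within the Picard loop.
        """
        g = self.grid
        submerged = g.surface < sea
        h_top = psi_flat[self.top_cell] + self.top_z
        seep = (~submerged) & (h_top >= g.surface)
        bc_head = np.where(submerged, sea, g.surface)
        dirich = submerged | seep
        kr_cell = self._kr(psi_flat[self.top_cell])
        # upstream weighting across the surface face: saturated water above
        # for inflow, the cell's kr for outflow
        kr_face = np.where(bc_head > h_top, 1.0, kr_cell)
        return dirich, bc_head, kr_face, seep

    def _land_source(self, psi_flat):
        """Q_in (m3/d) distributed over saturated landward-boundary cells."""
        src = np.zeros(self.n_eq)
        if self.bc.Q_in == 0 or len(self.land_cells) == 0:
            return src
        sat = psi_flat[self.land_cells] >= 0.0
        w = np.where(sat, self.land_dz, 0.0)
        if w.sum() == 0.0:   # fully unsaturated column: feed the deepest cell
            w[-1] = 1.0
        src[self.land_cells] = self.bc.Q_in * w / w.sum()
        return src

    # -- core step --------------------------------------------------------
    def richards_step(self, psi, t_new, dt, forcing: TidalForcing,
                      max_picard=30, tol_psi=5e-4):
        """One implicit step to time ``t_new`` (days); returns the new state.

        Returns ``(psi_new, info)`` where ``info`` carries the converged
        seepage mask, iteration count, and face fluxes at the new time.
        Raises :class:`StepFailure` if Picard stalls (caller may halve dt).
        """
        g = self.grid
        sea = sea_level(t_new, forcing)
        psi_old = psi[g.active]
        theta_old = self._theta(psi_old)
        psi_m = psi_old.copy()
        p = self.props
        err_prev = np.inf

        for it in range(max_picard):
            theta_m = self._theta(psi_m)
            C_m = self._capacity(psi_m)
            S_m = theta_m / p.porosity
            kr = self._kr(psi_m)

            h_m = psi_m + self.zc_cell
            # upstream kr on faces
            kr_v = np.where(h_m[self.vf_up] >= h_m[self.vf_dn],
                            kr[self.vf_up], kr[self.vf_dn])
            kr_h = np.where(h_m[self.hf_l] >= h_m[self.hf_r],
                            kr[self.hf_l], kr[self.hf_r])
            Gv = self.vf_G * kr_v
            Gh = self.hf_G * kr_h

            diag = (C_m + p.specific_storage * S_m) * self.vol / dt
            b = diag * psi_m - (theta_m - theta_old) * self.vol / dt
            b += self._land_source(psi_m)

            # gravity contributions of internal faces: flux = G*(h_nb - h_c)
            dz_v = self.zc_cell[self.vf_up] - self.zc_cell[self.vf_dn]
            np.add.at(b, self.vf_up, -Gv * dz_v)   # neighbour below: z_nb - z_c = -dz_v
            np.add.at(b, self.vf_dn, Gv * dz_v)

            diag_add = np.zeros(self.n_eq)
            np.add.at(diag_add, self.vf_up, Gv)
            np.add.at(diag_add, self.vf_dn, Gv)
            np.add.at(diag_add, self.hf_l, Gh)
            np.add.at(diag_add, self.hf_r, Gh)

            dirich, bc_head, kr_face, seep = self._surface_bc(psi_m, sea)
            Gt = self.top_G * kr_face * dirich
            np.add.at(diag_add, self.top_cell, Gt)
            np.add.at(b, self.top_cell, Gt * (bc_head - self.top_z))

            A = sp.coo_matrix((np.concatenate([
                    diag + diag_add, -Gv, -Gv, -Gh, -Gh]),
                (np.concatenate([np.arange(self.n_eq),
                                 self.vf_up, self.vf_dn, self.hf_l, self.hf_r]),
                 np.concatenate([np.arange(self.n_eq),
                                 self.vf_dn, self.vf_up, self.hf_r, self.hf_l]))),
                shape=(self.n_eq, self.n_eq)).tocsr()
            psi_new = spsolve(A, b)

            err = float(np.max(np.abs(psi_new - psi_m)))
            # damp when the update grows, which breaks face-flip limit cycles
            omega = 0.5 if err > err_prev else 1.0
            psi_m = psi_m + omega * (psi_new - psi_m)
            err_prev = err
            if err < tol_psi:
                break
        else:
            raise StepFailure(f"Picard stalled (last update {err:.2e} m)", err)

        info = self._post_step(psi_m, psi_old, theta_old, sea, dt)
        info["iterations"] = it + 1
        info["residual"] = err
        out = np.full(g.shape, np.nan)
        out[g.active] = psi_m
        return out, info

    def _post_step(self, psi_flat, psi_old, theta_old, sea, dt):
        """Face fluxes and mass-balance bookkeeping for a converged state."""
        g = self.grid
        kr = self._kr(psi_flat)
        h = psi_flat + self.zc_cell
        kr_v = np.where(h[self.vf_up] >= h[self.vf_dn], kr[self.vf_up], kr[self.vf_dn])
        kr_h = np.where(h[self.hf_l] >= h[self.hf_r], kr[self.hf_l], kr[self.hf_r])
        # volumetric face flows, positive from 'up'/'left' cell to its neighbour
        Qv = self.vf_G * kr_v * (h[self.vf_up] - h[self.vf_dn])
        Qh = self.hf_G * kr_h * (h[self.hf_l] - h[self.hf_r])
        dirich, bc_head, kr_face, seepage_mask = self._surface_bc(psi_flat, sea)
        Q_top = self.top_G * kr_face * (bc_head - (psi_flat[self.top_cell] + self.top_z))
        Q_top = np.where(dirich, Q_top, 0.0)        # positive = into the sediment
        src = self._land_source(psi_flat)

        storage = (self._theta(psi_flat) - theta_old) * self.vol / dt
        div = np.zeros(self.n_eq)
        np.add.at(div, self.vf_up, -Qv)
        np.add.at(div, self.vf_dn, Qv)
        np.add.at(div, self.hf_l, -Qh)
        np.add.at(div, self.hf_r, Qh)
        np.add.at(div, self.top_cell, Q_top)
        cell_res = storage - div - src
        gross = np.abs(Q_top).sum() + src.sum() + 1e-30
        return {
            "Qv": Qv, "Qh": Qh, "Q_top": Q_top, "land_src": src,
            "seepage_mask": seepage_mask, "sea_level": sea,
            "mass_residual": float(np.abs(cell_res.sum()) / gross),
        }


@dataclass
class PeriodicFlowField:
    """One tidal cycle of the periodic flow solution, replayed cyclically.

    Fluxes are interval means over ``n_snap`` equal sub-intervals of the
    cycle; ``theta`` and ``saturation`` are stored at the interval edges
    (``n_snap + 1`` states, the last wrapping to the first).  All fluxes
    are volumetric (m3/d per m shoreline): ``Qv[k]`` positive downward
    across the face below layer ``i``'s cells... positive from the upper
    to the lower cell; ``Qh`` positive seaward; ``Q_top`` positive into
    the sediment.
    """

    grid: Grid
    forcing: TidalForcing
    times: np.ndarray              # interval-start times within the cycle, days
    theta: np.ndarray              # (n_snap+1, nz, nx)
    saturation: np.ndarray         # (n_snap+1, nz, nx)
    head: np.ndarray               # (n_snap+1, nz, nx) total head, m
    Qv: np.ndarray                 # (n_snap, n_vfaces)
    Qh: np.ndarray                 # (n_snap, n_hfaces)
    Q_top: np.ndarray              # (n_snap, nx)
    land_src: np.ndarray           # (n_snap, n_cells) interval-mean source, m3/d
    sea: np.ndarray                # (n_snap+1,) sea level at interval edges
    residual_history: list = field(default_factory=list)
    cycles: int = 0
    model: "FlowModel | None" = None

    @property
    def n_snap(self) -> int:
        return len(self.times)

    @property
    def dt_snap(self) -> float:
        return self.forcing.period_days / self.n_snap

    def low_tide_snapshot(self) -> int:
        """Index of the interval edge with the lowest sea level."""
        return int(np.argmin(self.sea))

    def cycle_water_balance(self) -> dict:
        """Cycle-integrated water budget (m3 per m shoreline per cycle)."""
        dt = self.dt_snap
        infil = float(np.clip(self.Q_top, 0, None).sum() * dt)
        exfil = float(-np.clip(self.Q_top, None, 0).sum() * dt)
        q_in = float(self.land_src.sum() * dt)
        act = self.grid.active
        vol = (self.grid.dz[:, None] * self.grid.dx)
        storage = float(((self.theta[-1] - self.theta[0]) * vol)[act].sum())
        gross = infil + exfil + q_in + 1e-30
        return {"infiltration": infil, "exfiltration": exfil, "Q_in": q_in,
                "storage_change": storage,
                "closure": (infil + q_in - exfil - storage) / gross}


def run_to_periodic(model: FlowModel, forcing: TidalForcing,
                    n_snap: int = 50, steps_per_snap: int = 3,
                    tol: float = 1e-3, max_cycles: int = 30,
                    psi0: np.ndarray | None = None,
                    verbose: bool = False) -> PeriodicFlowField:
    """Iterate whole tidal cycles until the head field repeats within ``tol``.

    The initial condition is hydrostatic with the water table at the high
    water line (the domain fully saturated below it).  The periodicity
    residual is the maximum head change between corresponding end-of-cycle
    states, relative to the tidal range (floored at 0.1 m so the steady,
    vanishing-tide limit stays well-defined).
    """
    g = model.grid
    if psi0 is None:
        hwl = forcing.high_water
        psi = np.where(g.active, hwl - g.zc[:, None], np.nan)
    else:
        psi = psi0.copy()
    T = forcing.period_days
    dt0 = T / (n_snap * steps_per_snap)
    seep = np.zeros(g.shape[1], dtype=bool)
    residuals = []
    nf = {"Qv": len(model.vf_G), "Qh": len(model.hf_G)}

    for cycle in range(max_cycles):
        psi_start = psi.copy()
        times = np.arange(n_snap) * T / n_snap
        theta_e = np.empty((n_snap + 1,) + g.shape)
        sat_e = np.empty_like(theta_e)
        head_e = np.full((n_snap + 1,) + g.shape, np.nan)
        sea_e = np.empty(n_snap + 1)
        Qv_m = np.zeros((n_snap, nf["Qv"]))
        Qh_m = np.zeros((n_snap, nf["Qh"]))
        Qt_m = np.zeros((n_snap, g.shape[1]))
        src_m = np.zeros((n_snap, model.n_eq))

        def record_edge(k, psi_arr, t):
            th = np.where(g.active, 0.0, np.nan).copy()
            th[g.active] = model._theta(psi_arr[g.active])
            theta_e[k] = th
            sat_e[k] = th / model.props.porosity
            head_e[k][g.active] = psi_arr[g.active] + model.zc_cell
            sea_e[k] = sea_level(t, forcing)

        record_edge(0, psi, cycle * T)
        for k in range(n_snap):
            t_snap0 = cycle * T + k * T / n_snap
            sub = 0
            t_loc = 0.0
            dt = dt0
            while t_loc < T / n_snap - 1e-12:
                dt_eff = min(dt, T / n_snap - t_loc)
                try:
                    psi_new, info = model.richards_step(
                        psi, t_snap0 + t_loc + dt_eff, dt_eff, forcing)
                except StepFailure:
                    if dt <= dt0 / 16:
                        raise
                    dt *= 0.5
                    continue
                psi = psi_new
                seep = info["seepage_mask"]
                w = dt_eff / (T / n_snap)
                Qv_m[k] += w * info["Qv"]
                Qh_m[k] += w * info["Qh"]
                Qt_m[k] += w * info["Q_top"]
                src_m[k] += w * info["land_src"]
                t_loc += dt_eff
                sub += 1
            record_edge(k + 1, psi, t_snap0 + T / n_snap)

        scale = max(forcing.high_water - forcing.low_water, 0.1)
        res = float(np.nanmax(np.abs(psi - psi_start)) / scale)
        residuals.append(res)
        if verbose:
            print(f"flow cycle {cycle + 1}: periodicity residual {res:.2e}")
        if res < tol:
            return PeriodicFlowField(
                grid=g, forcing=forcing, times=times, theta=theta_e,
                saturation=sat_e, head=head_e, Qv=Qv_m, Qh=Qh_m, Q_top=Qt_m,
                land_src=src_m, sea=sea_e, residual_history=residuals,
                cycles=cycle + 1, model=model)
    raise NonPeriodicError(
        f"no periodic state within {max_cycles} cycles "
        f"(last residual {residuals[-1]:.2e})", residuals)
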