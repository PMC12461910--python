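"""Diagnostics: turn flow and O2 solutions into reported beach-aquifer numbers.

All volumes are bulk sediment volumes per metre of shoreline (m3 m-1);
the oxic zone is porewater with O2 above 1 umol/L (strict inequality),
excluding permanently unsaturated sand above the high-water line.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .domain import Grid
from .flow import PeriodicFlowField
from .transport import OXIC_THRESHOLD, O2Field

__all__ = [
    "BudgetReport",
    "tide_average",
    "permanently_unsaturated_mask",
    "oxic_volume",
    "penetration_depth",
    "infiltration_partition",
    "o2_supply_decomposition",
    "desaturated_volume",
    "compare_stations",
    "seasonal_redox_volume",
    "assemble_report",
]


def tide_average(values, durations=None):
    """Duration-weighted mean of per-interval snapshot values.

    ``values`` has the snapshot axis first; ``durations`` (optional)
    weights each snapshot by its interval length.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 1:
        raise ValueError("need at least one snapshot")
    if durations is None:
        w = np.full(values.shape[0], 1.0 / values.shape[0])
    else:
        w = np.asarray(durations, dtype=float)
        if len(w) != values.shape[0] or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("durations must match snapshots and be positive")
        w = w / w.sum()
    return np.tensordot(w, values, axes=(0, 0))


def permanently_unsaturated_mask(flow: PeriodicFlowField,
                                 S_threshold: float = 0.97) -> np.ndarray:
    """Cells unsaturated (S < threshold) at every snapshot of the cycle."""
    S = flow.saturation
    mask = np.all(np.where(np.isnan(S), True, S < S_threshold), axis=0)
    return mask & flow.grid.active


def oxic_volume(C: np.ndarray, grid: Grid, exclude_mask: np.ndarray | None = None,
                threshold: float = OXIC_THRESHOLD,
                porosity: float | None = None) -> float:
    """Bulk volume (m3 m-1) of cells with O2 strictly above ``threshold``.

    ``exclude_mask`` removes (typically permanently unsaturated) cells;
    pass ``porosity`` to get pore volume instead of the default bulk
    convention.
    """
    if exclude_mask is not None and exclude_mask.shape != grid.shape:
        raise ValueError("mask/grid shape mismatch")
    oxic = np.where(np.isnan(C), False, C > threshold) & grid.active
    if exclude_mask is not None:
        oxic &= ~exclude_mask
    vol = grid.cell_volume[oxic].sum()
    if porosity is not None:
        vol *= porosity
    return float(vol)


def penetration_depth(C: np.ndarray, grid: Grid,
                      threshold: float = OXIC_THRESHOLD) -> float:
    """Maximum O2 penetration (m below the local sediment surface).

    Per column, the depth from the surface to the bottom face of the
    deepest cell with O2 above threshold; the maximum over columns is
    returned (0 for a fully anoxic field).
    """
    oxic = np.where(np.isnan(C), False, C > threshold) & grid.active
    depth = 0.0
    z_bot = grid.z_faces[1:]
    for j in range(grid.shape[1]):
        rows = np.nonzero(oxic[:, j])[0]
        if len(rows):
            depth = max(depth, float(grid.surface[j] - z_bot[rows.max()]))
    return depth


def _intertidal_columns(flow: PeriodicFlowField):
    g, f = flow.grid, flow.forcing
    return (g.surface >= f.low_water) & (g.surface <= f.high_water)


def _face_lengths(grid: Grid) -> np.ndarray:
    """Sloping surface-face length per column (m)."""
    if grid.shape[1] < 2:
        return np.full(grid.shape[1], grid.dx)
    slope = np.gradient(grid.surface, grid.xc)
    return grid.dx * np.sqrt(1.0 + slope ** 2)


def infiltration_partition(flow: PeriodicFlowField) -> dict:
    """Net-infiltration statistics of the intertidal beach face.

    Returns the fraction (percent) of intertidal face length with positive
    cycle-averaged boundary flux, the total infiltration rate (cycle-mean
    of the positive boundary flux, m3 m-1 d-1), per-column mean fluxes,
    and the area-weighted centroid of the net-infiltration faces.
    """
    g = flow.grid
    q_mean = flow.Q_top.mean(axis=0)             # m3/d per column, cycle mean
    inter = _intertidal_columns(flow)
    lengths = _face_lengths(g)
    net_in = (q_mean > 0) & inter
    frac = 100.0 * lengths[net_in].sum() / max(lengths[inter].sum(), 1e-300)
    infil_rate = float(np.clip(flow.Q_top, 0, None).sum(axis=1).mean())
    exfil_rate = float(np.clip(-flow.Q_top, 0, None).sum(axis=1).mean())
    if net_in.any():
        centroid = float((g.xc[net_in] * lengths[net_in]).sum()
                         / lengths[net_in].sum())
        start = float(g.xc[net_in].min())
    else:
        centroid = np.nan
        start = np.nan
    x_int = g.xc[inter]
    return {
        "net_infiltration_area_fraction": float(frac),
        "infiltration_rate": infil_rate,
        "exfiltration_rate": exfil_rate,
        "mean_face_flux": q_mean,
        "net_infiltration_mask": net_in,
        "intertidal_mask": inter,
        "infiltration_centroid_x": centroid,
        "infiltration_start_x": start,
        "mid_intertidal_x": float(0.5 * (x_int.min() + x_int.max())) if inter.any() else np.nan,
    }


def o2_supply_decomposition(o2: O2Field) -> tuple[float, float]:
    """(infiltration supply, aeration supply) in mol per m shoreline per day."""
    b = o2.budget
    if not b:
        raise ValueError("O2 field carries no cycle budget; rerun transport")
    return float(b.get("infiltration_in", 0.0)), float(b.get("aeration_in", 0.0))


def desaturated_volume(flow: PeriodicFlowField, S_threshold: float = 0.97,
                       snapshot: int | None = None) -> dict:
    """Desaturated intertidal sand at (by default) low tide.

    Returns the bulk volume (m3 m-1) of intertidal cells with S below the
    threshold, the desaturated thickness per column, its maximum and the
    position of the maximum.
    """
    g = flow.grid
    k = flow.low_tide_snapshot() if snapshot is None else snapshot
    S = flow.saturation[k]
    desat = np.where(np.isnan(S), False, S < S_threshold) & g.active
    inter = _intertidal_columns(flow)
    desat &= inter[None, :]
    volume = float(g.cell_volume[desat].sum())
    thickness = (g.dz[:, None] * desat).sum(axis=0)
    jmax = int(np.argmax(thickness)) if desat.any() else 0
    return {
        "volume": volume,
        "thickness": thickness,
        "max_thickness": float(thickness[jmax]),
        "x_max_thickness": float(g.xc[jmax]),
        "snapshot": k,
    }


def sample_field(C: np.ndarray, grid: Grid, x: float, depth: float) -> float:
    """Bilinear sample of a cell field at cross-shore x and depth below surface."""
    z = float(np.interp(x, grid.xc, grid.surface)) - depth
    j1 = int(np.clip(np.searchsorted(grid.xc, x), 1, grid.shape[1] - 1))
    j0 = j1 - 1
    wx = np.clip((x - grid.xc[j0]) / (grid.xc[j1] - grid.xc[j0]), 0.0, 1.0)
    vals = []
    for j in (j0, j1):
        col = C[:, j]
        ok = np.isfinite(col) & grid.active[:, j]
        if not ok.any():
            return np.nan
        zc = grid.zc[ok]
        vals.append(float(np.interp(z, zc[::-1], col[ok][::-1])))
    return (1 - wx) * vals[0] + wx * vals[1]


def compare_stations(C: np.ndarray, grid: Grid,
                     observations: pd.DataFrame) -> dict:
    """Model-vs-measurement comparison at sampling stations.

    ``observations`` needs columns ``x`` (m from mHWL), ``depth`` (m below
    surface) and ``O2`` (umol/L); optional ``station``.  The skill score is
    the R-squared of the model = measurement line,
    ``1 - sum((model - obs)^2) / sum((obs - mean(obs))^2)`` (can be
    negative; it is not clipped).
    """
    if len(observations) < 2:
        raise ValueError("need at least 2 observations")
    x = observations["x"].to_numpy(float)
    d = observations["depth"].to_numpy(float)
    obs = observations["O2"].to_numpy(float)
    if (x < grid.xc[0]).any() or (x > grid.xc[-1]).any():
        bad = observations.loc[(x < grid.xc[0]) | (x > grid.xc[-1])]
        raise ValueError(f"stations outside the domain: {bad.to_dict('records')}")
    model = np.array([sample_field(C, grid, xi, di) for xi, di in zip(x, d)])
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((model - obs) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    table = observations.copy()
    table["model"] = model
    return {"r_squared": float(r2), "table": table}


def seasonal_redox_volume(oxic_summer: float, oxic_winter: float) -> float:
    """Sediment volume (m3 m-1) alternating between oxic and anoxic seasonally."""
    return abs(oxic_winter - oxic_summer)


@dataclass
class BudgetReport:
    """Tide-averaged flow/O2 budget for one seasonal scenario."""

    season: str
    infiltration_rate: float              # m3 m-1 d-1
    exfiltration_rate: float
    net_infiltration_area_fraction: float  # percent of intertidal face length
    oxic_volume: float                    # m3 m-1, tide-averaged
    oxic_volume_fluctuation: float        # m3 m-1, max - min over the cycle
    penetration_depth: float              # m below surface
    O2_supply_infiltration: float         # mol m-1 d-1
    O2_supply_aeration: float
    O2_supply_total: float
    O2_consumption: float
    O2_outflow: float
    budget_closure: float                 # fraction of supply
    desaturated_volume_low_tide: float    # m3 m-1
    desaturated_max_thickness: float      # m
    transport_cycles: int
    quasi_steady: bool

    def to_json(self, path=None, **meta):
        payload = {**asdict(self), **meta}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def assemble_report(flow: PeriodicFlowField, o2: O2Field,
                    season: str = "") -> BudgetReport:
    """Deterministic summary of a converged flow + O2 scenario."""
    g = flow.grid
    part = infiltration_partition(flow)
    mask = permanently_unsaturated_mask(flow)
    Cavg = o2.tide_averaged()
    vox_avg = oxic_volume(Cavg, g, exclude_mask=mask)
    vox_snaps = [oxic_volume(o2.C[k], g, exclude_mask=mask)
                 for k in range(o2.C.shape[0])]
    infil_s, aer_s = o2_supply_decomposition(o2)
    desat = desaturated_volume(flow)
    return BudgetReport(
        season=season,
        infiltration_rate=part["infiltration_rate"],
        exfiltration_rate=part["exfiltration_rate"],
        net_infiltration_area_fraction=part["net_infiltration_area_fraction"],
        oxic_volume=vox_avg,
        oxic_volume_fluctuation=float(max(vox_snaps) - min(vox_snaps)),
        penetration_depth=penetration_depth(Cavg, g),
        O2_supply_infiltration=infil_s,
        O2_supply_aeration=aer_s,
        O2_supply_total=infil_s + aer_s,
        O2_consumption=float(o2.budget.get("consumption", np.nan)),
        O2_outflow=float(o2.budget.get("outflow", np.nan)),
        budget_closure=float(o2.budget.get("closure", np.nan)),
        desaturated_volume_low_tide=desat["volume"],
        desaturated_max_thickness=desat["max_thickness"],
        transport_cycles=o2.cycles,
        quasi_steady=o2.converged,
    )
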