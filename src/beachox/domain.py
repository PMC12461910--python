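"""Model domain: beach topography, structured grid, layered geology, hydraulics.

The cross-section is a 2D slice through an intertidal beach aquifer,
1 m wide in the alongshore direction.  The coordinate convention follows
the field survey: ``x`` is the cross-shore distance from the mean
high-water line (mHWL) in metres (negative landward, positive seaward)
and ``z`` is elevation in metres above average sea level (m asl).
All volumes derived from the grid are per metre of shoreline (m3 m-1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BeachProfile",
    "GridSpec",
    "Grid",
    "LayerModel",
    "HydraulicProperties",
    "build_planar_profile",
    "add_depression",
    "build_grid",
    "hazen_conductivity",
    "fit_depth_conductivity",
    "retention_saturation",
    "relative_permeability",
]


class GeometryError(ValueError):
    """Raised for inconsistent topography or grid geometry."""


# ---------------------------------------------------------------------------
# topography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeachProfile:
    """Sediment surface elevation along the cross-shore transect.

    Attributes
    ----------
    x : ndarray
        Sample locations, m from the mHWL (negative landward).
    z : ndarray
        Surface elevation at ``x``, m asl.
    mean_slope : float
        Mean beach slope (dimensionless, positive seaward-dipping).
    mHWL : float
        Elevation of the mean high-water line, m asl.
    season_label : str
    """

    x: np.ndarray
    z: np.ndarray
    mean_slope: float
    mHWL: float = 1.37
    season_label: str = ""

    def elevation(self, x):
        """Surface elevation (m asl) at cross-shore position(s) ``x``."""
        return np.interp(np.asarray(x, dtype=float), self.x, self.z)

    def intertidal_extent(self, z_low: float, z_high: float) -> tuple[float, float]:
        """Cross-shore interval where the surface lies between two water levels."""
        xi = np.linspace(self.x[0], self.x[-1], 8 * len(self.x))
        zi = self.elevation(xi)
        inside = (zi <= z_high) & (zi >= z_low)
        if not inside.any():
            raise GeometryError("surface never intersects the given water levels")
        return float(xi[inside].min()), float(xi[inside].max())


def build_planar_profile(slope: float, mHWL: float = 1.37,
                         x_range: tuple[float, float] = (-50.0, 190.0),
                         n_points: int = 481,
                         season_label: str = "") -> BeachProfile:
    """Planar beach: ``z(x) = mHWL - slope * x`` with x=0 at the mHWL.

    Raises
    ------
    GeometryError
        If the slope is non-positive or unrealistically steep, or the
        requested range does not cover the tidal excursion around x=0.
    """
    if not 0.0 < slope <= 0.2:
        raise GeometryError(f"slope must be in (0, 0.2], got {slope}")
    x0, x1 = x_range
    if x1 <= x0:
        raise GeometryError("empty x_range")
    # the intertidal zone around the mHWL must fit inside the domain
    if x0 > 0.0 or x1 < 2.0 * mHWL / slope:
        raise GeometryError(
            "x_range narrower than the tidal excursion implied by slope and mHWL")
    x = np.linspace(x0, x1, n_points)
    return BeachProfile(x=x, z=mHWL - slope * x, mean_slope=slope,
                        mHWL=mHWL, season_label=season_label)


def add_depression(profile: BeachProfile, x_start: float, x_end: float,
                   depth: float) -> BeachProfile:
    """Superimpose a smooth (cosine-tapered) topographic depression.

    The lowering is ``depth/2 * (1 - cos(2 pi s))`` with ``s`` the relative
    position in ``[x_start, x_end]``: continuous and differentiable, maximal
    at the midpoint, zero at and outside the edges.
    """
    if depth == 0.0:
        return profile
    if depth < 0.0 or x_end <= x_start:
        raise GeometryError("depression needs x_start < x_end and depth >= 0")
    s = np.clip((profile.x - x_start) / (x_end - x_start), 0.0, 1.0)
    dz = 0.5 * depth * (1.0 - np.cos(2.0 * np.pi * s))
    return replace(profile, z=profile.z - dz)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Structured-grid parameters.

    Vertical spacing grows geometrically from ``dz_top`` at the surface,
    capped at ``dz_bottom``; the growth ratio is solved so the layers
    exactly tile ``[z_bottom, z_top]``.
    """

    n_columns: int = 300
    n_layers: int = 90
    dx: float = 0.8
    dz_top: float = 0.05
    dz_bottom: float = 1.7
    z_top: float = 2.4
    z_bottom: float = -40.0
    x_left: float = -50.0
    stretching_rule: str = "geometric, capped"

    @property
    def width(self) -> float:
        return self.n_columns * self.dx

    def vertical_spacings(self) -> np.ndarray:
        """Layer thicknesses from the top down, summing to z_top - z_bottom."""
        total = self.z_top - self.z_bottom
        n = self.n_layers
        if total <= 0 or n < 1:
            raise GeometryError("need z_top > z_bottom and n_layers >= 1")
        if abs(n * self.dz_top - total) / total < 1e-12:
            return np.full(n, self.dz_top)
        if n * self.dz_top > total:
            raise GeometryError("dz_top too coarse for the requested extent")
        if self.dz_bottom < self.dz_top:
            raise GeometryError("dz_bottom must be >= dz_top")

        def tiled(r):
            dz = self.dz_top * r ** np.arange(n)
            return np.minimum(dz, self.dz_bottom).sum() - total

        if n * self.dz_bottom < total:
            raise GeometryError("grid cannot span the domain even at dz_bottom")
        r = brentq(tiled, 1.0 + 1e-12, 4.0, xtol=1e-14)
        dz = np.minimum(self.dz_top * r ** np.arange(n), self.dz_bottom)
        # absorb the cap's rounding into the deepest layer
        dz[-1] += total - dz.sum()
        if np.any(np.diff(dz) < -1e-12):
            raise GeometryError("vertical spacings are not monotone")
        return dz


class Grid:
    """Structured finite-volume grid with terrain-following active cells.

    Layers are indexed top-down (``i=0`` is the shallowest), columns
    landward to seaward (``j=0`` is the landward edge).  Cells whose
    centre lies above the local sediment surface are inactive (air).
    """

    def __init__(self, spec: GridSpec, profile: BeachProfile):
        self.spec = spec
        self.profile = profile
        self.dx = spec.dx
        self.xc = spec.x_left + (np.arange(spec.n_columns) + 0.5) * spec.dx
        self.dz = spec.vertical_spacings()
        z_faces = spec.z_top - np.concatenate(([0.0], np.cumsum(self.dz)))
        self.z_faces = z_faces                      # length n_layers+1, descending
        self.zc = 0.5 * (z_faces[:-1] + z_faces[1:])
        self.surface = np.minimum(profile.elevation(self.xc), spec.z_top)
        if np.any(self.surface <= spec.z_bottom):
            raise GeometryError("sediment surface below the domain bottom")
        self.active = self.zc[:, None] < self.surface[None, :]
        if not self.active.any(axis=0).all():
            raise GeometryError("some column has no active cells")
        self.itop = np.argmax(self.active, axis=0)  # first active layer per column
        self.cell_volume = self.dz[:, None] * self.dx * np.ones_like(self.active, float)
        self.cell_volume[~self.active] = 0.0
        # distance from top-active cell centre to the sediment surface
        cols = np.arange(spec.n_columns)
        self.d_surf = self.surface - self.zc[self.itop]
        self._cols = cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.spec.n_layers, self.spec.n_columns)

    @property
    def n_cells(self) -> int:
        return int(self.active.size)

    def depth_below_surface(self) -> np.ndarray:
        """Depth of each cell centre below the local sediment surface (m, >=0 active)."""
        d = self.surface[None, :] - self.zc[:, None]
        return np.where(self.active, d, np.nan)

    def total_area(self) -> float:
        """Active cross-sectional area (m2) == bulk volume per m shoreline."""
        return float(self.cell_volume.sum() / self.dx * self.dx)


def build_grid(profile: BeachProfile, spec: GridSpec | None = None) -> Grid:
    """Build the structured grid for a beach profile (defaults: 90 x 300)."""
    return Grid(spec or GridSpec(), profile)


# ---------------------------------------------------------------------------
# geology and hydraulics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerModel:
    """Three-layer geology: beach sands over tidal-flat deposits over glacial sands.

    Interfaces are planar elevations (m asl).  Layer 2 (tidal-flat muds and
    fine sands with peat/clay lenses) is the low-permeability unit.
    """

    z_layer12: float = -4.0
    z_layer23: float = -12.0
    K_layer2: float = 6.25   # m/d, slug-test adjusted
    K_layer3: float = 46.0   # m/d

    def __post_init__(self):
        if not self.z_layer12 > self.z_layer23:
            raise GeometryError("layer interfaces out of order")
        if min(self.K_layer2, self.K_layer3) <= 0:
            raise ValueError("layer conductivities must be positive")

    def layer_index(self, zc: np.ndarray) -> np.ndarray:
        """1, 2 or 3 for each elevation."""
        idx = np.ones_like(zc, dtype=int)
        idx[zc <= self.z_layer12] = 2
        idx[zc <= self.z_layer23] = 3
        return idx


@dataclass(frozen=True)
class HydraulicProperties:
    """Hydraulic parameter set for the variably saturated flow model.

    The beach-sand layer takes a depth-decaying conductivity
    ``K(d) = K0 * exp(-d / z_star)`` over the upper ``decay_depth`` metres
    (below which it is held at its value at ``decay_depth``), reflecting
    grain-size (d10, Hazen) profiles that show conductivity decreasing
    within the top metre.  Retention follows van Genuchten-Mualem.
    """

    K0_surface: float = 35.0      # m/d at the sediment surface
    z_star: float = 1.2           # m, e-folding depth of the K decrease
    decay_depth: float = 1.0      # m, depth over which the decay applies
    porosity: float = 0.35
    residual_saturation: float = 0.05
    vg_alpha: float = 3.5         # 1/m
    vg_n: float = 3.0
    specific_storage: float = 1e-4   # 1/m, keeps saturated cells well-posed
    hazen_coefficient: float = 100.0  # cgs convention: K[cm/s] = C_H * d10[cm]^2

    def __post_init__(self):
        if self.vg_n <= 1:
            raise ValueError("van Genuchten n must exceed 1")
        if not 0 < self.residual_saturation < 1:
            raise ValueError("residual saturation must be in (0, 1)")
        if min(self.K0_surface, self.z_star, self.porosity) <= 0:
            raise ValueError("hydraulic parameters must be positive")

    @property
    def vg_m(self) -> float:
        return 1.0 - 1.0 / self.vg_n

    def conductivity_field(self, grid: Grid, layers: LayerModel) -> np.ndarray:
        """Saturated K (m/d) for every grid cell (NaN-free; inactive cells get layer value)."""
        zc2d = np.broadcast_to(grid.zc[:, None], grid.shape)
        lay = layers.layer_index(zc2d)
        depth = np.clip(grid.surface[None, :] - zc2d, 0.0, None)
        d_eff = np.minimum(depth, self.decay_depth)
        K = self.K0_surface * np.exp(-d_eff / self.z_star)
        K = np.where(lay == 2, layers.K_layer2, K)
        K = np.where(lay == 3, layers.K_layer3, K)
        return K


def hazen_conductivity(d10_cm, C_H: float = 100.0):
    """Hazen's empirical conductivity from the 10th-percentile grain size.

    ``K [cm/s] = C_H * (d10 [cm])**2``, returned in m/d.
    """
    d10 = np.asarray(d10_cm, dtype=float)
    if np.any(d10 <= 0):
        raise ValueError("d10 must be positive")
    K_cm_s = C_H * d10 ** 2
    out = K_cm_s * 864.0  # cm/s -> m/d
    return float(out) if out.ndim == 0 else out


_ZSTAR_CAP = 1e6  # m; effectively depth-independent conductivity


def fit_depth_conductivity(samples) -> dict:
    """Fit ``K(d) = K0 * exp(-d / z_star)`` to (depth, K) samples on log-K.

    Least squares on ``log K = log K0 - d / z_star`` (linear in the
    parameters), with ``z_star`` capped when the profile is depth-flat.

    Returns a dict with ``K0`` (m/d), ``z_star`` (m), ``r_squared`` and a
    ``capped`` flag.
    """
    d = np.asarray([s[0] for s in samples], dtype=float)
    K = np.asarray([s[1] for s in samples], dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 samples")
    if np.any(K <= 0):
        raise ValueError("conductivities must be positive")
    if np.ptp(d) == 0:
        raise ValueError("degenerate fit: all depths equal")
    y = np.log(K)
    A = np.vstack([np.ones_like(d), -d]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    logK0, inv_zstar = coef
    capped = inv_zstar <= 1.0 / _ZSTAR_CAP
    z_star = _ZSTAR_CAP if capped else 1.0 / inv_zstar
    yhat = logK0 - d / z_star
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return {"K0": float(np.exp(logK0)), "z_star": float(z_star),
            "r_squared": r2, "capped": bool(capped)}


def retention_saturation(pressure_head, alpha: float = 3.5, n: float = 3.0):
    """Van Genuchten effective saturation Se(psi); Se=1 for psi >= 0."""
    if n <= 1:
        raise ValueError("van Genuchten n must exceed 1")
    psi = np.asarray(pressure_head, dtype=float)
    m = 1.0 - 1.0 / n
    Se = np.where(psi >= 0.0, 1.0, (1.0 + (alpha * np.abs(psi)) ** n) ** (-m))
    return float(Se) if Se.ndim == 0 else Se


def relative_permeability(Se, n: float = 3.0):
    """Mualem relative permeability from effective saturation."""
    if n <= 1:
        raise ValueError("van Genuchten n must exceed 1")
    m = 1.0 - 1.0 / n
    Se = np.clip(np.asarray(Se, dtype=float), 0.0, 1.0)
    kr = np.sqrt(Se) * (1.0 - (1.0 - Se ** (1.0 / m)) ** m) ** 2
    return float(kr) if kr.ndim == 0 else kr
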