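"""Synthetic field data: topography, grain sizes, rate profiles, station obs.

These generators stand in for the field campaign inputs the pipeline
needs: seasonal beach profiles, grain-size (d10) depth profiles that feed
the Hazen conductivity fit, noisy O2-consumption-rate profiles from the
upper 70 cm, and porewater O2 "observations" sampled from a model field.
Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import BeachProfile, add_depression, build_planar_profile
from .transport import RateModel

__all__ = [
    "NoiseSpec",
    "gen_topography",
    "gen_d10_profile",
    "gen_rate_measurements",
    "gen_station_obs",
    "DEFAULT_STATIONS",
]

# seasonal topography: mean slopes from the June/December surveys; the
# summer berm carries a slight depression 50-65 m seaward of the mHWL
SEASON_SLOPES = {"summer": 0.019, "winter": 0.017}
SUMMER_DEPRESSION = (50.0, 65.0, 0.1)   # x_start, x_end (m), depth (m)

# schematic IT-station layout in the upper-intertidal infiltration zone
DEFAULT_STATIONS = [
    ("IT1", 10.0, (0.5, 1.0, 2.0)),
    ("IT2", 35.0, (0.5, 1.0, 2.0)),
    ("IT3", 60.0, (0.5, 1.0, 2.0)),
    ("IT4", 85.0, (0.5, 1.0, 2.0)),
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description for the generators."""

    rel_sd: float = 0.05
    distribution: str = "lognormal"   # or "normal"
    seed: int | None = None

    def __post_init__(self):
        if self.rel_sd < 0:
            raise ValueError("relative sd must be >= 0")
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError("distribution must be 'lognormal' or 'normal'")

    def rng(self, seed=None) -> np.random.Generator:
        return np.random.default_rng(self.seed if self.seed is not None else seed)

    def apply(self, values, rng, scale=None):
        """Perturb values: multiplicative lognormal or additive normal."""
        values = np.asarray(values, dtype=float)
        if self.rel_sd == 0:
            return values.copy()
        if self.distribution == "lognormal":
            sigma = np.sqrt(np.log1p(self.rel_sd ** 2))
            return values * rng.lognormal(-0.5 * sigma ** 2, sigma, values.shape)
        sd = self.rel_sd * (np.ptp(values) if scale is None else scale)
        return values + rng.normal(0.0, sd, values.shape)


def gen_topography(season: str, depression: tuple | None = "default",
                   seed: int | None = None, perturbation_amplitude: float = 0.0,
                   x_range: tuple[float, float] = (-50.0, 190.0)) -> BeachProfile:
    """Seasonal beach profile: planar slope, plus the summer depression.

    ``depression="default"`` adds the 50-65 m depression for summer and
    none for winter; pass ``None`` to suppress it or an explicit
    ``(x_start, x_end, depth)``.  ``perturbation_amplitude`` (m)
    superimposes smooth seeded low-frequency undulations.
    """
    if season not in SEASON_SLOPES:
        raise ValueError(f"unknown season {season!r}")
    prof = build_planar_profile(SEASON_SLOPES[season], x_range=x_range,
                                season_label=season)
    if depression == "default":
        depression = SUMMER_DEPRESSION if season == "summer" else None
    if depression is not None:
        prof = add_depression(prof, *depression)
    if perturbation_amplitude > 0:
        rng = np.random.default_rng(seed)
        L = x_range[1] - x_range[0]
        z = prof.z.copy()
        for mode in (3, 5, 7):
            amp = perturbation_amplitude * rng.uniform(0, 1) / mode
            phase = rng.uniform(0, 2 * np.pi)
            z = z - amp * np.cos(2 * np.pi * mode * (prof.x - x_range[0]) / L + phase)
        from dataclasses import replace
        prof = replace(prof, z=z)
    return prof


def gen_d10_profile(K0: float = 35.0, z_star: float = 1.2, n_samples: int = 20,
                    noise: NoiseSpec = NoiseSpec(), seed: int | None = None,
                    max_depth: float = 1.0, C_H: float = 100.0) -> list[tuple[float, float]]:
    """Grain-size (d10, cm) depth profile consistent with a K(z) decay.

    Inverts the Hazen relation ``K[cm/s] = C_H d10^2`` for
    ``K(z) = K0 exp(-z / z_star)`` (m/d) and perturbs the grain sizes.
    Returns (depth m, d10 cm) pairs over the upper metre.
    """
    if K0 <= 0 or z_star <= 0:
        raise ValueError("K0 and z_star must be positive")
    depths = np.linspace(0.02, max_depth, n_samples)
    K = K0 * np.exp(-depths / z_star)          # m/d
    d10 = np.sqrt((K / 864.0) / C_H)           # cm
    d10 = noise.apply(d10, noise.rng(seed))
    return list(zip(depths.tolist(), d10.tolist()))


def gen_rate_measurements(model: RateModel, depths=None,
                          noise: NoiseSpec = NoiseSpec(rel_sd=0.1),
                          seed: int | None = None) -> list[tuple[float, float]]:
    """Noisy O2-consumption-rate samples (umol/L/h) in the upper 70 cm.

    The default depths mimic a core-incubation microprofile: centimetre
    spacing through the steep near-surface gradient, opening up below.
    """
    if depths is None:
        depths = np.array([0.0, 0.02, 0.04, 0.06, 0.09, 0.12, 0.16, 0.2,
                           0.25, 0.3, 0.4, 0.5, 0.6, 0.7])
    depths = np.asarray(depths, dtype=float)
    rates = model.depth_rate(depths)
    rates = noise.apply(rates, noise.rng(seed))
    return list(zip(depths.tolist(), rates.tolist()))


def gen_station_obs(C: np.ndarray, grid, stations=None,
                    noise: NoiseSpec = NoiseSpec(rel_sd=0.05, distribution="normal"),
                    seed: int | None = None, season: str = "") -> pd.DataFrame:
    """Sample a (tide-averaged) O2 field at station positions, with noise.

    ``stations`` is a list of ``(id, x, depths)``; the default is the
    four-station layout of the upper infiltration zone.  Normal noise is
    scaled by the sampled field's range.  Negative draws are clipped to 0.
    """
    from .diagnostics import sample_field

    if stations is None:
        stations = DEFAULT_STATIONS
    if len(stations) == 0:
        raise ValueError("empty station list")
    rows = []
    for sid, x, depths in stations:
        if not (grid.xc[0] <= x <= grid.xc[-1]):
            raise ValueError(f"station {sid} at x={x} outside the domain")
        for d in np.atleast_1d(depths):
            rows.append({"station": sid, "x": float(x), "depth": float(d),
                         "O2": sample_field(C, grid, float(x), float(d)),
                         "season": season})
    obs = pd.DataFrame(rows)
    rng = noise.rng(seed)
    obs["O2"] = np.clip(noise.apply(obs["O2"].to_numpy(), rng), 0.0, None)
    return obs
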