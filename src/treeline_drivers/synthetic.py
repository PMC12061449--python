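"""Synthetic volcano landscape with known expansion drivers.

Generates everything the real study derives from satellite and reanalysis
products — a cone-shaped DEM with stochastic roughness, elevation-lapsed
monthly climate with aspect modulation and noise, and a multi-year
expansion-only presence series whose colonization probability is a known
logistic function of chosen (z-scored) factors including pairwise
interactions — so that every downstream stage, and in particular the
driver-recovery power of the detectors, is testable end to end with no
external data.  The parameter ledger (`SyntheticTruth`) is serialisable
and is the ground truth that recovery experiments compare against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .change import CoverSeries
from .climate import ClimateStack, FactorSet, derive_climate_variables
from .raster import RasterGrid, block_aggregate
from .terrain import TerrainStack, derive_terrain

__all__ = [
    "SyntheticTruth",
    "generate_dem",
    "generate_climate",
    "generate_presence_series",
    "aggregate_terrain",
    "coarsen_climate",
    "simulate_scene",
]

# Sea-level monthly normals for a continental NE-Asia climate: mean
# temperature (°C) and precipitation (mm), January first.
_SEA_LEVEL_TMEAN = (-10.0, -7.0, 0.0, 8.0, 14.0, 18.0, 21.0, 22.0, 16.0, 8.0, -1.0, -8.0)
_SEA_LEVEL_PRECIP = (15.0, 15.0, 25.0, 40.0, 80.0, 110.0, 140.0, 130.0, 80.0, 45.0, 25.0, 15.0)


@dataclass
class SyntheticTruth:
    """Full parameter ledger of one synthetic scene."""

    seed: int = 0
    # grid
    nrows: int = 200
    ncols: int = 200
    cell_size: float = 50.0
    # DEM: cone + smoothed Gaussian field
    summit_height: float = 2690.0
    cone_slope: float = 0.12
    roughness_amplitude: float = 15.0
    roughness_correlation_cells: float = 5.0
    # climate
    sea_level_tmean: tuple[float, ...] = _SEA_LEVEL_TMEAN
    sea_level_precip: tuple[float, ...] = _SEA_LEVEL_PRECIP
    lapse_rate: float = -0.0065  # °C per metre
    precip_elevation_gradient: float = 0.01  # mm per metre per month
    aspect_temp_amplitude: float = 0.5  # °C, warm-south modulation
    temp_noise_sd: float = 0.3
    precip_noise_sd: float = 3.0
    # climate anomalies are spatially correlated fields (storm tracks,
    # windward effects), not white noise; 0 gives iid cell noise
    climate_noise_correlation_cells: float = 8.0
    # suitability (logistic, on z-scored factors)
    beta0: float = -1.0
    betas: dict[str, float] = field(
        default_factory=lambda: {"elevation": -0.5, "TWI": 0.5, "Pre_1": 0.5}
    )
    interactions: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("TWI", "Pre_1"): 1.0}
    )
    # colonization
    colonization_scale: float = 0.6
    neighborhood_radius: int = 1
    initial_presence_quantile: float = 0.35
    years: tuple[int, ...] = (2002, 2010, 2017, 2021)

    def __post_init__(self) -> None:
        if self.lapse_rate >= 0:
            raise ValueError("temperature lapse rate must be negative")
        if not 0 <= self.colonization_scale <= 1:
            raise ValueError("colonization scale must be a probability scale in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["interactions"] = {f"{a}*{b}": v for (a, b), v in self.interactions.items()}
        Path(path).write_text(json.dumps(payload, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["interactions"] = {
            tuple(k.split("*")): v for k, v in payload.pop("interactions", {}).items()
        }
        for key in ("sea_level_tmean", "sea_level_precip", "years"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _summit_xy(truth: SyntheticTruth) -> tuple[float, float]:
    return (
        truth.ncols * truth.cell_size / 2,
        -truth.nrows * truth.cell_size / 2,
    )


def generate_dem(truth: SyntheticTruth) -> RasterGrid:
    """Cone-shaped DEM plus a smoothed Gaussian random field.

    The cone is centred on the grid, so all four azimuth sectors around
    the summit are non-empty by construction; roughness amplitude 0 gives
    the pure analytic cone.  Bit-identical for a given truth + seed.
    """
    if truth.nrows < 32 or truth.ncols < 32:
        raise ValueError("synthetic grid must be at least 32x32")
    template = RasterGrid(
        np.zeros((truth.nrows, truth.ncols)), cell_size=truth.cell_size, origin=(0.0, 0.0)
    )
    xs, ys = template.cell_centers()
    sx, sy = _summit_xy(truth)
    dist = np.hypot(xs - sx, ys - sy)
    z = truth.summit_height - truth.cone_slope * dist
    if truth.roughness_amplitude > 0:
        rng = np.random.default_rng([truth.seed, 11])
        noise = rng.standard_normal(z.shape)
        noise = ndimage.gaussian_filter(noise, truth.roughness_correlation_cells)
        sd = noise.std()
        if sd > 0:
            z = z + noise * (truth.roughness_amplitude / sd)
    return template.with_values(z)


def generate_climate(dem: RasterGrid, truth: SyntheticTruth) -> ClimateStack:
    """Monthly temperature/precipitation fields lapsed from the DEM.

    T_month = sea-level normal + lapse x elevation + aspect modulation
    (warm-south cosine) + noise; precipitation adds an elevation gradient
    and is floored at zero.  Monthly noise fields are spatially correlated
    Gaussian fields (correlation length in cells from the truth ledger)
    scaled to the configured SD.
    """
    rng = np.random.default_rng([truth.seed, 23])

    def noise_field(sd: float) -> np.ndarray:
        white = rng.standard_normal(dem.shape)
        corr = truth.climate_noise_correlation_cells
        if corr <= 0 or sd == 0:
            return sd * white
        smooth = ndimage.gaussian_filter(white, corr)
        s = smooth.std()
        return smooth * (sd / s) if s > 0 else np.zeros_like(smooth)

    xs, ys = dem.cell_centers()
    sx, sy = _summit_xy(truth)
    azimuth = np.degrees(np.arctan2(xs - sx, ys - sy)) % 360.0
    south_warmth = truth.aspect_temp_amplitude * np.cos(np.radians(azimuth - 180.0))
    elev = dem.values

    tmean, tmax, tmin, precip = [], [], [], []
    for m in range(12):
        t = (
            truth.sea_level_tmean[m]
            + truth.lapse_rate * elev
            + south_warmth
            + noise_field(truth.temp_noise_sd)
        )
        p = (
            truth.sea_level_precip[m]
            + truth.precip_elevation_gradient * elev
            + noise_field(truth.precip_noise_sd)
        )
        tmean.append(dem.with_values(t))
        tmax.append(dem.with_values(t + 5.0))
        tmin.append(dem.with_values(t - 5.0))
        precip.append(dem.with_values(np.maximum(p, 0.0)))
    return ClimateStack(
        monthly_precip=precip, monthly_tmean=tmean, monthly_tmax=tmax, monthly_tmin=tmin
    )


def _zscore(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mu = values[mask].mean()
    sd = values[mask].std()
    return (values - mu) / sd if sd > 0 else np.zeros_like(values)


def generate_presence_series(
    factors: FactorSet,
    truth: SyntheticTruth,
    return_diagnostics: bool = False,
) -> CoverSeries | tuple[CoverSeries, dict]:
    """Expansion-only presence series driven by a logistic suitability model.

    Initial presence occupies the cells below the configured elevation
    quantile.  Each simulated year, every absent cell with at least one
    occupied neighbour within the Chebyshev radius colonizes with
    probability scale x logistic(beta0 + sum beta_i z_i + sum beta_ij z_i z_j);
    occupied cells never revert.  Maps are recorded at the epoch years.

    With ``return_diagnostics`` an exposure ledger is returned alongside:
    per-cell counts of exposure-years (years spent absent with an occupied
    neighbour, i.e. colonization attempts), the per-cell colonization
    probability actually applied, and the final colonized mask.  The
    events-per-exposure-year ratio is a direct estimate of that
    probability, free of the wave-arrival-time confound that the raw
    density response carries.
    """
    elevation = factors["elevation"]
    valid = elevation.valid_mask
    z = {name: _zscore(factors[name].values, valid) for name in factors.names()}

    logit = np.full(elevation.shape, truth.beta0)
    for name, beta in truth.betas.items():
        logit = logit + beta * z[name]
    for (a, b), beta in truth.interactions.items():
        logit = logit + beta * z[a] * z[b]
    p_col = truth.colonization_scale / (1.0 + np.exp(-logit))

    threshold = np.quantile(elevation.values[valid], truth.initial_presence_quantile)
    presence = (elevation.values <= threshold) & valid
    if not presence.any():
        raise ValueError("initial presence is empty; raise the elevation quantile")

    r = truth.neighborhood_radius
    structure = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    rng = np.random.default_rng([truth.seed, 37])

    years = truth.years
    maps: dict[int, RasterGrid] = {}
    initial = presence.copy()
    exposure_years = np.zeros(presence.shape, dtype=int)

    def record(year: int) -> None:
        vals = np.where(valid, presence.astype(float), np.nan)
        maps[year] = elevation.with_values(vals)

    record(years[0])
    for year in range(years[0] + 1, years[-1] + 1):
        frontier = ndimage.binary_dilation(presence, structure=structure) & ~presence & valid
        exposure_years += frontier
        draws = rng.random(presence.shape)
        presence = presence | (frontier & (draws < p_col))
        if year in years:
            record(year)
    series = CoverSeries(list(years), maps)
    if not return_diagnostics:
        return series
    diagnostics = {
        "exposure_years": exposure_years,
        "colonized": presence & ~initial,
        "p_colonization": np.where(valid, p_col, np.nan),
    }
    return series, diagnostics


def aggregate_terrain(dem: RasterGrid, factor: int, relief_window: int = 3) -> TerrainStack:
    """Terrain stack of the block-mean-aggregated (coarse) DEM."""
    return derive_terrain(block_aggregate(dem, factor), relief_window=relief_window)


def coarsen_climate(stack: ClimateStack, factor: int) -> ClimateStack:
    """Block-mean aggregate every monthly layer to a coarser grid."""
    def agg(layers: list[RasterGrid] | None) -> list[RasterGrid] | None:
        if layers is None:
            return None
        return [block_aggregate(g, factor) for g in layers]

    return ClimateStack(
        monthly_precip=agg(stack.monthly_precip),
        monthly_tmean=agg(stack.monthly_tmean),
        monthly_tmax=agg(stack.monthly_tmax),
        monthly_tmin=agg(stack.monthly_tmin),
    )


def simulate_scene(truth: SyntheticTruth, diagnostics: bool = False) -> dict:
    """Generate the full scene: DEM, terrain, climate, factor set, series.

    Returns a dict with keys 'truth', 'dem', 'terrain', 'climate',
    'factors' (the nine-factor set) and 'series'; with ``diagnostics``
    also the generator's exposure ledger under 'exposure'.
    """
    dem = generate_dem(truth)
    terrain = derive_terrain(dem)
    climate = generate_climate(dem, truth)
    clim_factors = derive_climate_variables(climate)
    factors = FactorSet(
        {
            **clim_factors,
            "elevation": terrain.elevation,
            "slope": terrain.slope_deg,
            "relief": terrain.relief,
            "TWI": terrain.twi,
        },
        notes={"source": "synthetic scene", "seed": str(truth.seed)},
    )
    result = {
        "truth": truth,
        "dem": dem,
        "terrain": terrain,
        "climate": climate,
        "factors": factors,
    }
    if diagnostics:
        series, ledger = generate_presence_series(factors, truth, return_diagnostics=True)
        result["series"] = series
        result["exposure"] = ledger
    else:
        result["series"] = generate_presence_series(factors, truth)
    return result
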