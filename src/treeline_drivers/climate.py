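"""Climate downscaling and derivation of the climate explanatory factors.

Coarse monthly temperature/precipitation grids are downscaled to the
analysis resolution with a multiple linear regression on terrain
covariates (elevation, slope, and aspect as a sin/cos pair), the standard
statistical-downscaling approach for mountain climatologies where the
dominant signal is the elevation lapse rate.  From the downscaled monthly
stack the seasonal factors are derived: growing-season precipitation
(Pre_g), coldest-month (January) precipitation (Pre_1), warmest-month
(August) precipitation (Pre_8), warmest-month mean temperature (T_MEAN8)
and growing-season mean temperature (T_MEANg).  Highly collinear factors
(|Pearson r| above a threshold) are pruned greedily, keeping the factor
ranked earlier in a priority list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid
from .terrain import FLAT_ASPECT, TerrainStack

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateStack",
    "FactorSet",
    "downscale_mlr",
    "validate_downscaling",
    "derive_climate_variables",
    "prune_correlated",
    "DEFAULT_SEASON",
    "DEFAULT_FACTOR_PRIORITY",
]

#: Growing-season months (June-September, the alpine NE-Asia convention).
DEFAULT_SEASON: tuple[int, ...] = (6, 7, 8, 9)

#: Priority order used when pruning collinear factors (climate first, then
#: topography, mirroring the factor-table ordering of the analysis).
DEFAULT_FACTOR_PRIORITY: tuple[str, ...] = (
    "Pre_g", "Pre_1", "Pre_8", "T_MEAN8", "T_MEANg",
    "elevation", "slope", "relief", "TWI",
)


@dataclass
class ClimateStack:
    """Twelve monthly layers per climate variable on one shared grid."""

    monthly_precip: list[RasterGrid]
    monthly_tmean: list[RasterGrid]
    monthly_tmax: list[RasterGrid] | None = None
    monthly_tmin: list[RasterGrid] | None = None

    def __post_init__(self) -> None:
        for name in ("monthly_precip", "monthly_tmean", "monthly_tmax", "monthly_tmin"):
            stack = getattr(self, name)
            if stack is not None and len(stack) != 12:
                raise ValueError(f"{name} must contain 12 monthly layers, got {len(stack)}")

    @property
    def resolution_m(self) -> float:
        return self.monthly_precip[0].cell_size


@dataclass
class FactorSet:
    """Named, grid-aligned factor rasters plus provenance notes."""

    factors: dict[str, RasterGrid]
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.factors.values())
        for g in grids[1:]:
            if not g.same_geometry(grids[0]):
                raise ValueError("all factor rasters must share grid geometry")

    def names(self) -> list[str]:
        return list(self.factors)

    def __getitem__(self, name: str) -> RasterGrid:
        return self.factors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.factors

    def __len__(self) -> int:
        return len(self.factors)

    def subset(self, names: list[str]) -> "FactorSet":
        return FactorSet(
            {n: self.factors[n] for n in names},
            {n: v for n, v in self.notes.items() if n in names},
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat fishnet table: one row per cell with x/y and factor columns."""
        first = next(iter(self.factors.values()))
        xs, ys = first.cell_centers()
        data = {"x": xs.ravel(), "y": ys.ravel()}
        for name, grid in self.factors.items():
            data[name] = grid.values.ravel()
        frame = pd.DataFrame(data)
        frame.insert(0, "cell_id", np.arange(len(frame)))
        return frame


def _terrain_design(topo: TerrainStack) -> np.ndarray:
    """Covariate matrix [elevation, slope, sin(aspect), cos(aspect)] per cell.

    Flat-aspect cells (sentinel -1) contribute zero to both circular terms.
    """
    elev = topo.elevation.values.ravel()
    slope = topo.slope_deg.values.ravel()
    aspect = topo.aspect_deg.values.ravel()
    flat = aspect == FLAT_ASPECT
    rad = np.radians(aspect)
    sin_a = np.where(flat, 0.0, np.sin(rad))
    cos_a = np.where(flat, 0.0, np.cos(rad))
    return np.column_stack([elev, slope, sin_a, cos_a])


def downscale_mlr(
    coarse: RasterGrid,
    coarse_topo: TerrainStack,
    fine_topo: TerrainStack,
    min_cells: int = 10,
    return_coefficients: bool = False,
) -> RasterGrid | tuple[RasterGrid, np.ndarray]:
    """Downscale one coarse climate layer to the fine grid by OLS on terrain.

    Fits coarse values on [elevation, slope, sin(aspect), cos(aspect)] over
    valid coarse cells and predicts at every fine cell.  A rank-deficient
    design triggers a fall-back to the elevation-only lapse regression.
    With ``return_coefficients`` the fitted coefficient vector (intercept
    first, then the covariates of the design actually used) is returned too.
    """
    if not coarse.same_geometry(coarse_topo.elevation):
        raise ValueError("coarse climate and coarse terrain are not aligned")
    y = coarse.values.ravel()
    X = _terrain_design(coarse_topo)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if ok.sum() < min_cells:
        raise ValueError(f"need at least {min_cells} valid coarse cells, have {int(ok.sum())}")

    design = np.column_stack([np.ones(ok.sum()), X[ok]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient downscaling design (rank %d of %d); "
            "falling back to elevation-only regression", rank, design.shape[1]
        )
        design = np.column_stack([np.ones(ok.sum()), X[ok, 0]])
        coef, *_ = np.linalg.lstsq(design, y[ok], rcond=None)
        Xf = np.column_stack(
            [np.ones(fine_topo.elevation.values.size), fine_topo.elevation.values.ravel()]
        )
    else:
        coef, *_ = np.linalg.lstsq(design, y[ok], rcond=None)
        Xfull = _terrain_design(fine_topo)
        Xf = np.column_stack([np.ones(Xfull.shape[0]), Xfull])
    pred = Xf @ coef
    pred = pred.reshape(fine_topo.elevation.shape)
    pred[~fine_topo.elevation.valid_mask] = np.nan
    result = fine_topo.elevation.with_values(pred)
    if return_coefficients:
        return result, coef
    return result


def validate_downscaling(pred: np.ndarray, obs: np.ndarray) -> dict[str, float]:
    """Station-level validation: RMSE and R² = 1 − SSE/SST of the observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must be paired vectors of equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 paired values")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(obs))):
        raise ValueError("pred and obs must be finite")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: observations have zero variance")
    return {"rmse": float(np.sqrt(sse / obs.size)), "r2": 1.0 - sse / sst}


def derive_climate_variables(
    stack: ClimateStack,
    season: tuple[int, ...] = DEFAULT_SEASON,
) -> dict[str, RasterGrid]:
    """Seasonal climate factors from a monthly stack.

    Pre_g sums precipitation over the growing-season months; Pre_1/Pre_8
    are the January/August layers (coldest/warmest month of the study
    region); T_MEAN8 is the August mean temperature; T_MEANg averages the
    monthly means over the season.
    """
    if not season:
        raise ValueError("season must contain at least one month")
    if any(m < 1 or m > 12 for m in season):
        raise ValueError("season months must be in 1..12")
    precip = stack.monthly_precip
    tmean = stack.monthly_tmean
    template = precip[0]
    pre_g = template.with_values(
        np.sum([precip[m - 1].values for m in season], axis=0)
    )
    t_meang = template.with_values(
        np.mean([tmean[m - 1].values for m in season], axis=0)
    )
    return {
        "Pre_g": pre_g,
        "Pre_1": precip[0],
        "Pre_8": precip[7],
        "T_MEAN8": tmean[7],
        "T_MEANg": t_meang,
    }


def prune_correlated(
    candidates: FactorSet,
    threshold: float = 0.90,
    priority: tuple[str, ...] | None = None,
) -> tuple[FactorSet, pd.DataFrame]:
    """Greedily eliminate factors until no pair has |Pearson r| > threshold.

    At each step the most-correlated offending pair is found and its
    lower-priority member dropped (priority = position in ``priority``,
    defaulting to insertion order).  Returns the surviving set and a drop
    log (dropped factor, kept partner, their correlation).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    names = candidates.names()
    if len(names) < 2:
        raise ValueError("need at least 2 candidate factors")
    order = {n: i for i, n in enumerate(priority or names)}
    for n in names:
        if n not in order:
            order[n] = len(order)

    mat = np.column_stack([candidates[n].values.ravel() for n in names])
    shared = np.all(np.isfinite(mat), axis=1)
    if shared.sum() < 3:
        raise ValueError("need at least 3 shared valid cells")
    corr = pd.DataFrame(mat[shared], columns=names).corr().to_numpy()

    alive = list(range(len(names)))
    dropped: list[dict[str, object]] = []
    while True:
        worst_r, worst_pair = 0.0, None
        for ii, i in enumerate(alive):
            for j in alive[ii + 1:]:
                r = abs(corr[i, j])
                if r > threshold and r > worst_r:
                    worst_r, worst_pair = r, (i, j)
        if worst_pair is None:
            break
        i, j = worst_pair
        loser = i if order[names[i]] > order[names[j]] else j
        keeper = j if loser == i else i
        alive.remove(loser)
        dropped.append(
            {"dropped": names[loser], "kept": names[keeper], "abs_r": worst_r}
        )
    survivors = [names[i] for i in alive]
    return candidates.subset(survivors), pd.DataFrame(
        dropped, columns=["dropped", "kept", "abs_r"]
    )
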