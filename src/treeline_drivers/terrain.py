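"""DEM derivatives: slope, aspect, relief, D8 flow accumulation, TWI.

These are the topographic explanatory factors of the driver analysis —
elevation, slope (degrees), neighbourhood relief (max − min elevation) and
the topographic wetness index TWI = ln(alpha / tan(beta)), where alpha is
the specific upslope contributing area per unit contour width and beta the
local slope angle.  Slope/aspect use the Horn third-order finite difference
on the 3x3 neighbourhood (the standard GIS estimator); flow routing is
single-direction D8 over a sink-filled surface.

Grid convention: north-up, row 0 northernmost; aspect azimuths are degrees
clockwise from north; flat cells receive the sentinel -1.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterGrid

__all__ = [
    "TerrainStack",
    "compute_slope",
    "compute_aspect",
    "compute_relief",
    "fill_sinks",
    "d8_flow_directions",
    "flow_accumulation_d8",
    "specific_catchment_area",
    "compute_twi",
    "classify_slope",
    "assign_aspect_sector",
    "derive_terrain",
    "FLAT_ASPECT",
    "SLOPE_CLASS_NAMES",
    "DEFAULT_SECTORS",
    "D8_OFFSETS",
]

#: Sentinel aspect for cells with gradient below the flat threshold.
FLAT_ASPECT = -1.0

#: D8 neighbour offsets in fixed tie-break order: E, SE, S, SW, W, NW, N, NE.
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)

SLOPE_CLASS_NAMES = {
    1: "plain",
    2: "gentle ramp",
    3: "ramp",
    4: "steep",
    5: "very steep",
    6: "scarp",
    7: "vertical slope",
}

# Degree thresholds for the 7-class taxonomy; the published scheme skips
# 45-55, so the scarp class is extended to [35, 55) to keep classes contiguous.
_SLOPE_EDGES = np.array([2.0, 5.0, 15.0, 25.0, 35.0, 55.0])

#: Azimuth sectors (name, start_deg, end_deg), half-open, wrapping at 360.
DEFAULT_SECTORS: tuple[tuple[str, float, float], ...] = (
    ("northern", 315.0, 45.0),
    ("eastern", 45.0, 135.0),
    ("southern", 135.0, 225.0),
    ("western", 225.0, 315.0),
)

SECTOR_CODES = {"northern": 1, "eastern": 2, "southern": 3, "western": 4}


@dataclass
class TerrainStack:
    """All DEM-derived layers on one shared grid geometry."""

    elevation: RasterGrid
    slope_deg: RasterGrid
    aspect_deg: RasterGrid
    relief: RasterGrid
    twi: RasterGrid
    slope_class: RasterGrid
    window_relief: int = 3

    def layers(self) -> dict[str, RasterGrid]:
        return {
            "elevation": self.elevation,
            "slope": self.slope_deg,
            "aspect": self.aspect_deg,
            "relief": self.relief,
            "TWI": self.twi,
            "slope_class": self.slope_class,
        }


def _check_dem(dem: RasterGrid) -> None:
    if dem.n_valid == 0:
        raise ValueError("DEM contains no valid cells")
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must be at least 3x3")


def _horn_gradients(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """(dz/dx east-positive, dz/dy north-positive).

    Interior cells use the Horn weighted 3x3 differences; border cells fall
    back to one-sided/central simple differences.  A NaN anywhere in the
    Horn window propagates to the output cell.
    """
    z = dem.values
    h = dem.cell_size
    # simple-gradient fallback (central interior, one-sided borders)
    d_row, d_col = np.gradient(z, h)
    gx = d_col.copy()
    gy = -d_row  # rows increase southwards
    # Horn on the interior
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx[1:-1, 1:-1] = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * h)
    gy[1:-1, 1:-1] = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * h)
    invalid = ~np.isfinite(z)
    gx[invalid] = np.nan
    gy[invalid] = np.nan
    return gx, gy


def compute_slope(dem: RasterGrid) -> RasterGrid:
    """Slope angle in degrees from the Horn gradient magnitude."""
    _check_dem(dem)
    gx, gy = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return dem.with_values(slope)


def compute_aspect(dem: RasterGrid, flat_threshold: float = 1e-6) -> RasterGrid:
    """Azimuth of steepest descent, degrees clockwise from north.

    Cells whose gradient magnitude falls below ``flat_threshold`` (m/m)
    receive the flat sentinel -1.
    """
    _check_dem(dem)
    gx, gy = _horn_gradients(dem)
    azimuth = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    grad = np.hypot(gx, gy)
    azimuth = np.where(grad < flat_threshold, FLAT_ASPECT, azimuth)
    azimuth[~np.isfinite(grad)] = np.nan
    return dem.with_values(azimuth)


def compute_relief(dem: RasterGrid, window: int = 3) -> RasterGrid:
    """Max - min elevation of valid cells in a window x window neighbourhood.

    Edge windows are clipped to the grid.  The window must be an odd
    integer >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("relief window must be an odd integer >= 3")
    _check_dem(dem)
    z = dem.values
    zmax = ndimage.maximum_filter(np.where(np.isfinite(z), z, -np.inf), size=window, mode="nearest")
    zmin = ndimage.minimum_filter(np.where(np.isfinite(z), z, np.inf), size=window, mode="nearest")
    relief = zmax - zmin
    relief[~np.isfinite(relief)] = np.nan
    relief[~np.isfinite(z)] = np.nan
    return dem.with_values(relief)


def fill_sinks(dem: RasterGrid, epsilon: float = 1e-6) -> RasterGrid:
    """Priority-flood depression filling.

    Pit cells are raised to their lowest pour point plus a small epsilon
    gradient so that every cell keeps a strictly descending path to the
    grid edge (or to a nodata boundary); this also resolves flats
    deterministically.
    """
    _check_dem(dem)
    z = dem.values
    nrows, ncols = z.shape
    valid = np.isfinite(z)
    filled = z.copy()
    visited = np.zeros_like(valid)

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    # seeds: valid cells on the grid edge or adjacent to nodata
    edge = np.zeros_like(valid)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    next_to_nodata = ndimage.binary_dilation(~valid) & valid
    for r, c in zip(*np.nonzero(valid & (edge | next_to_nodata))):
        heapq.heappush(heap, (z[r, c], counter, int(r), int(c)))
        counter += 1
        visited[r, c] = True

    while heap:
        zc, _, r, c = heapq.heappop(heap)
        for dr, dc in D8_OFFSETS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and valid[nr, nc] and not visited[nr, nc]:
                visited[nr, nc] = True
                fill_level = max(z[nr, nc], zc + epsilon)
                filled[nr, nc] = fill_level
                heapq.heappush(heap, (fill_level, counter, nr, nc))
                counter += 1
    return dem.with_values(filled)


def d8_flow_directions(filled: RasterGrid) -> np.ndarray:
    """Index into ``D8_OFFSETS`` of each cell's steepest-descent neighbour.

    -1 marks outlet cells (no lower valid neighbour: flow leaves the grid)
    and -2 marks nodata cells.  Descent is slope-weighted (diagonal steps
    divided by sqrt(2)); ties take the first neighbour in the fixed order
    E, SE, S, SW, W, NW, N, NE.
    """
    z = filled.values
    nrows, ncols = z.shape
    valid = np.isfinite(z)
    h = filled.cell_size
    pointers = np.full(z.shape, -2, dtype=int)
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            best_drop = 0.0
            best_k = -1
            for k, (dr, dc) in enumerate(D8_OFFSETS):
                nr, nc = r + dr, c + dc
                if 0 <= nr < nrows and 0 <= nc < ncols and valid[nr, nc]:
                    dist = h * (np.sqrt(2.0) if dr and dc else 1.0)
                    drop = (z[r, c] - z[nr, nc]) / dist
                    if drop > best_drop:
                        best_drop = drop
                        best_k = k
            pointers[r, c] = best_k
    return pointers


def flow_accumulation_d8(dem: RasterGrid, epsilon: float = 1e-6) -> RasterGrid:
    """Upslope contributing area (m², own cell included) by D8 routing.

    The DEM is sink-filled first; each cell then passes its entire
    accumulated area to its single steepest-descent neighbour.
    """
    filled = fill_sinks(dem, epsilon=epsilon)
    pointers = d8_flow_directions(filled)
    z = filled.values
    valid = np.isfinite(z)
    acc = np.where(valid, 1.0, np.nan)

    # process in decreasing filled elevation: every upstream cell is strictly
    # higher than its downstream cell, so a single sorted pass suffices
    order = np.argsort(z, axis=None, kind="stable")[::-1]
    nrows, ncols = z.shape
    for flat in order:
        r, c = divmod(int(flat), ncols)
        if not valid[r, c]:
            continue
        k = pointers[r, c]
        if k >= 0:
            dr, dc = D8_OFFSETS[k]
            acc[r + dr, c + dc] += acc[r, c]
    return dem.with_values(acc * dem.cell_area)


def specific_catchment_area(dem: RasterGrid, epsilon: float = 1e-6) -> RasterGrid:
    """alpha: contributing area per unit contour width (accumulation / cell width)."""
    acc = flow_accumulation_d8(dem, epsilon=epsilon)
    return acc.with_values(acc.values / dem.cell_size)


def compute_twi(
    specific_catchment: RasterGrid,
    slope_deg: RasterGrid,
    flat_epsilon: float = 1e-3,
) -> RasterGrid:
    """TWI = ln(alpha / max(tan(beta), eps)).

    ``flat_epsilon`` bounds tan(beta) away from zero on flat cells so the
    index stays finite.
    """
    if not specific_catchment.same_geometry(slope_deg):
        raise ValueError("catchment and slope grids are not aligned")
    alpha = specific_catchment.values
    if np.any(alpha[np.isfinite(alpha)] <= 0):
        raise ValueError("specific catchment area must be positive")
    tanb = np.tan(np.radians(slope_deg.values))
    twi = np.log(alpha / np.maximum(tanb, flat_epsilon))
    return specific_catchment.with_values(twi)


def classify_slope(slope_deg: RasterGrid) -> RasterGrid:
    """Classify slope angle into the 7-class taxonomy (degrees, left-closed).

    1 plain [0,2), 2 gentle ramp [2,5), 3 ramp [5,15), 4 steep [15,25),
    5 very steep [25,35), 6 scarp [35,55), 7 vertical slope >= 55.
    """
    vals = slope_deg.values
    finite = np.isfinite(vals)
    if np.any(vals[finite] < 0):
        raise ValueError("slope angles must be non-negative")
    classes = np.digitize(np.where(finite, vals, 0.0), _SLOPE_EDGES) + 1.0
    classes = np.where(finite, classes, np.nan)
    return slope_deg.with_values(classes)


def assign_aspect_sector(
    grid: RasterGrid,
    summit: tuple[float, float],
    sectors: tuple[tuple[str, float, float], ...] = DEFAULT_SECTORS,
    mask: tuple[str, ...] = (),
) -> RasterGrid:
    """Label each cell by the azimuth sector of its direction from the summit.

    Sectors are (name, start, end) azimuth ranges in degrees clockwise from
    north, half-open and wrapping at 360.  Names in ``mask`` (e.g. the
    eastern sector when it lies outside the study area) become nodata, as
    does the summit's own cell, whose direction is undefined.
    """
    x0, y0 = summit
    try:
        grid.index_of(x0, y0)
    except IndexError as exc:
        raise ValueError("summit must lie inside the grid extent") from exc
    xs, ys = grid.cell_centers()
    azimuth = np.degrees(np.arctan2(xs - x0, ys - y0)) % 360.0
    labels = np.full(grid.shape, np.nan)
    for code, (name, start, end) in enumerate(sectors, start=1):
        if start <= end:
            in_sector = (azimuth >= start) & (azimuth < end)
        else:  # wraps through north
            in_sector = (azimuth >= start) | (azimuth < end)
        if name not in mask:
            labels[in_sector] = code
    dist = np.hypot(xs - x0, ys - y0)
    labels[dist < grid.cell_size / 2] = np.nan
    labels[~grid.valid_mask] = np.nan
    return grid.with_values(labels)


def derive_terrain(
    dem: RasterGrid,
    relief_window: int = 3,
    flat_threshold: float = 1e-6,
    twi_epsilon: float = 1e-3,
) -> TerrainStack:
    """Compute the full topographic factor stack from a DEM."""
    slope = compute_slope(dem)
    aspect = compute_aspect(dem, flat_threshold=flat_threshold)
    relief = compute_relief(dem, window=relief_window)
    alpha = specific_catchment_area(dem)
    twi = compute_twi(alpha, slope, flat_epsilon=twi_epsilon)
    return TerrainStack(
        elevation=dem,
        slope_deg=slope,
        aspect_deg=aspect,
        relief=relief,
        twi=twi,
        slope_class=classify_slope(slope),
        window_relief=relief_window,
    )
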