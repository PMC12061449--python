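"""Change products from year-keyed binary cover maps.

Turns the per-year presence/absence maps into the quantities the driver
analysis consumes: 4-way change maps (stable absence, unchanged presence,
expansion, reduction), annual expansion rates, per-aspect-sector area and
maximum-elevation summaries, slope-class occupancy distributions, and the
aggregated density-increase response surface (percent of fine cells inside
an analysis cell that switched from absent to present).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid, block_aggregate

logger = logging.getLogger(__name__)

__all__ = [
    "CoverSeries",
    "ChangeMap",
    "CHANGE_CATEGORIES",
    "change_map",
    "annual_rate",
    "sector_summary",
    "slope_distribution",
    "density_increase",
    "M2_PER_HM2",
]

M2_PER_HM2 = 1e4  # 1 hm² (hectare) = 10⁴ m²

CHANGE_CATEGORIES = {
    0: "absent-stable",
    1: "present-stable",
    2: "expanded",
    3: "reduced",
}


@dataclass
class CoverSeries:
    """Ordered binary presence maps sharing one grid."""

    years: list[int]
    maps: dict[int, RasterGrid]

    def __post_init__(self) -> None:
        if sorted(self.years) != self.years:
            raise ValueError("years must be in increasing order")
        first = self.maps[self.years[0]]
        for y in self.years:
            if y not in self.maps:
                raise ValueError(f"missing map for year {y}")
            if not self.maps[y].same_geometry(first):
                raise ValueError("all yearly maps must share grid geometry")

    @property
    def cell_area(self) -> float:
        return self.maps[self.years[0]].cell_area

    def presence_mask(self, year: int) -> np.ndarray:
        return self.maps[year].values == 1

    def area_hm2(self, year: int, where: np.ndarray | None = None) -> float:
        """Presence area in hm², optionally restricted to a boolean mask."""
        mask = self.presence_mask(year)
        if where is not None:
            mask = mask & where
        return float(mask.sum()) * self.cell_area / M2_PER_HM2

    def clamp_expansion_only(self) -> "CoverSeries":
        """Force presence to never revert (reductions become unchanged)."""
        out: dict[int, RasterGrid] = {}
        carry = None
        for y in self.years:
            vals = self.maps[y].values.copy()
            if carry is not None:
                vals = np.where((carry == 1) & np.isfinite(vals), 1.0, vals)
            out[y] = self.maps[y].with_values(vals)
            carry = out[y].values
        return CoverSeries(self.years, out)


@dataclass
class ChangeMap:
    """Cell-wise 4-way change categories between two years."""

    categories: RasterGrid  # codes of CHANGE_CATEGORIES, NaN = nodata
    from_year: int
    to_year: int
    counts: dict[str, int] = field(default_factory=dict)
    areas_hm2: dict[str, float] = field(default_factory=dict)


def change_map(series: CoverSeries, y1: int, y2: int) -> ChangeMap:
    """Categorise every cell between two years of the series."""
    for y in (y1, y2):
        if y not in series.maps:
            raise ValueError(f"year {y} not in series")
    a = series.maps[y1].values
    b = series.maps[y2].values
    valid = np.isfinite(a) & np.isfinite(b)
    cat = np.full(a.shape, np.nan)
    cat[valid & (a == 0) & (b == 0)] = 0
    cat[valid & (a == 1) & (b == 1)] = 1
    cat[valid & (a == 0) & (b == 1)] = 2
    cat[valid & (a == 1) & (b == 0)] = 3
    cell_hm2 = series.cell_area / M2_PER_HM2
    counts = {name: int(np.sum(cat == code)) for code, name in CHANGE_CATEGORIES.items()}
    areas = {name: counts[name] * cell_hm2 for name in counts}
    return ChangeMap(
        categories=series.maps[y1].with_values(cat),
        from_year=y1,
        to_year=y2,
        counts=counts,
        areas_hm2=areas,
    )


def annual_rate(area1: float, area2: float, span_years: float) -> float:
    """Annual expansion rate in % a⁻¹: ((area2-area1)/area1) × 100 / span.

    The simple (non-compound) convention; the span divisor is the caller's
    choice of year-difference convention.
    """
    if area1 <= 0:
        raise ValueError("rate undefined for non-positive base area")
    if span_years <= 0:
        raise ValueError("span_years must be positive")
    return (area2 - area1) / area1 * 100.0 / span_years


def sector_summary(
    series: CoverSeries,
    sectors: RasterGrid,
    dem: RasterGrid,
    sector_names: dict[int, str] | None = None,
    spans: dict[tuple[int, int], float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-sector areas, annual rates and yearly maximum elevations.

    Rates are computed for consecutive year pairs plus the full first-to-
    last period; ``spans`` overrides the calendar year difference for any
    pair (a stated-span convention).  Sectors with no cells produce nodata
    rows with a warning.
    """
    if not sectors.same_geometry(series.maps[series.years[0]]):
        raise ValueError("sector map not aligned with cover series")
    codes = np.unique(sectors.values[np.isfinite(sectors.values)]).astype(int)
    names = sector_names or {int(c): str(int(c)) for c in codes}
    years = series.years
    pairs = list(zip(years[:-1], years[1:]))
    if len(years) > 2:
        pairs.append((years[0], years[-1]))

    area_rows, rate_rows, elev_rows = [], [], []
    scopes = [(names.get(int(c), str(c)), sectors.values == c) for c in codes]
    scopes.append(("total", np.isfinite(sectors.values)))
    for label, mask in scopes:
        if not mask.any():
            logger.warning("sector %s contains no cells", label)
            continue
        for y in years:
            area_rows.append({"sector": label, "year": y, "area_hm2": series.area_hm2(y, mask)})
            pres = series.presence_mask(y) & mask
            max_elev = float(np.nanmax(dem.values[pres])) if pres.any() else np.nan
            if not pres.any():
                logger.warning("sector %s has no presence cells in %d", label, y)
            elev_rows.append({"sector": label, "year": y, "max_elevation_m": max_elev})
        for y1, y2 in pairs:
            a1, a2 = series.area_hm2(y1, mask), series.area_hm2(y2, mask)
            span = (spans or {}).get((y1, y2), float(y2 - y1))
            rate = annual_rate(a1, a2, span) if a1 > 0 else np.nan
            rate_rows.append(
                {"sector": label, "period": f"{y1}-{y2}", "span_years": span,
                 "annual_rate_pct": rate}
            )
    return {
        "areas": pd.DataFrame(area_rows),
        "rates": pd.DataFrame(rate_rows),
        "max_elevation": pd.DataFrame(elev_rows),
    }


def slope_distribution(series: CoverSeries, slope_class: RasterGrid) -> pd.DataFrame:
    """Percent of presence cells per slope class and year (rows sum to 100)."""
    if not slope_class.same_geometry(series.maps[series.years[0]]):
        raise ValueError("slope-class map not aligned with cover series")
    rows = []
    for y in series.years:
        pres = series.presence_mask(y)
        total = int(pres.sum())
        if total == 0:
            continue
        for cls in range(1, 8):
            count = int(np.sum(pres & (slope_class.values == cls)))
            rows.append(
                {"year": y, "slope_class": cls, "percent": 100.0 * count / total}
            )
    return pd.DataFrame(rows, columns=["year", "slope_class", "percent"])


def density_increase(change: ChangeMap, aggregation: int = 10) -> RasterGrid:
    """Density-increase response: % of fine cells per analysis cell that expanded.

    Aggregates ``aggregation``×``aggregation`` fine cells into one analysis
    cell; partial edge blocks use the cells they contain.  Values lie in
    [0, 100]; analysis cells with no valid fine cell are nodata.
    """
    if aggregation < 1:
        raise ValueError("aggregation must be >= 1")
    cat = change.categories
    expanded = cat.with_values(np.where(np.isfinite(cat.values), cat.values == 2, np.nan))
    frac = block_aggregate(expanded, aggregation, how="mean")
    return frac.with_values(frac.values * 100.0)
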