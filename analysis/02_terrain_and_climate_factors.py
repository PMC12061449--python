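#!/usr/bin/env python
"""Derive the nine explanatory factors and check the climate downscaling.

From the seed-1 scene: computes the terrain stack (slope, aspect, relief,
TWI), downscales a block-aggregated (coarse, 400 m) August temperature
field back to 50 m with the terrain MLR and validates it at random
station cells, derives the five seasonal climate factors, and prunes
factors with |r| > 0.90.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from treeline_drivers.climate import (
    DEFAULT_FACTOR_PRIORITY,
    downscale_mlr,
    prune_correlated,
    validate_downscaling,
)
from treeline_drivers.raster import block_aggregate
from treeline_drivers.synthetic import SyntheticTruth, aggregate_terrain, simulate_scene

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    truth = SyntheticTruth(seed=1)
    scene = simulate_scene(truth)
    terrain = scene["terrain"]

    # climate downscaling check: coarsen August temperature 8x (400 m),
    # regress on coarse terrain, predict at 50 m, validate at 200 stations
    aug = scene["climate"].monthly_tmean[7]
    coarse = block_aggregate(aug, 8)
    coarse_topo = aggregate_terrain(scene["dem"], 8)
    pred, coef = downscale_mlr(coarse, coarse_topo, terrain, return_coefficients=True)
    rng = np.random.default_rng(1)
    idx = rng.choice(aug.values.size, 200, replace=False)
    stats = validate_downscaling(pred.values.ravel()[idx], aug.values.ravel()[idx])
    stats["fitted_lapse_rate"] = float(coef[1])
    (RESULTS / "downscaling_validation.json").write_text(json.dumps(stats, indent=2))
    print(f"downscaling: lapse {coef[1]:.5f} degC/m (truth {truth.lapse_rate}), "
          f"station RMSE {stats['rmse']:.3f} degC, R2 {stats['r2']:.3f}")

    pruned, drop_log = prune_correlated(
        scene["factors"], threshold=0.90, priority=DEFAULT_FACTOR_PRIORITY
    )
    drop_log.to_csv(RESULTS / "factor_drop_log.csv", index=False)
    frame = pd.DataFrame(
        {n: pruned[n].values.ravel() for n in pruned.names()}
    ).dropna()
    frame.corr().round(3).to_csv(RESULTS / "factor_correlations.csv")
    print(f"factors: {len(scene['factors'])} candidates -> {len(pruned)} after "
          f"pruning at |r| > 0.90 "
          f"(dropped: {', '.join(drop_log['dropped']) if len(drop_log) else 'none'})")

    terrain_summary = {
        name: {"min": float(np.nanmin(g.values)), "max": float(np.nanmax(g.values))}
        for name, g in terrain.layers().items()
    }
    (RESULTS / "terrain_summary.json").write_text(json.dumps(terrain_summary, indent=2))


if __name__ == "__main__":
    main()
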