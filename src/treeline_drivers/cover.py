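"""Spectral features, sample handling, and binary presence classification.

Maps the focal tree species as a per-cell binary raster from a 9-band
feature space (six reflectance bands plus NDVI, NDWI and NDSI), a field
sample table that is filtered (study boundary, visual screening) and split
70/30 into training/validation, and a pluggable binary classifier
defaulting to a soft-margin kernel SVM.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .raster import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "REFLECTANCE_BANDS",
    "INDEX_BANDS",
    "compute_indices",
    "build_feature_stack",
    "temporal_features",
    "filter_samples",
    "split_samples",
    "classify_cover",
    "assess_accuracy",
    "patch_change_report",
    "default_classifier",
]

REFLECTANCE_BANDS = ("Blue", "Green", "Red", "NIR", "SWIR1", "SWIR2")
INDEX_BANDS = ("NDVI", "NDWI", "NDSI")

TARGET = "target"
NON_TARGET = "non-target"


def _normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / denom
    out[denom == 0] = np.nan  # 0/0: undefined, becomes nodata
    return out


def compute_indices(bands: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    """NDVI, NDWI and NDSI from the reflectance bands.

    NDVI = (NIR-Red)/(NIR+Red); NDWI = (Green-NIR)/(Green+NIR);
    NDSI = (SWIR1-NIR)/(SWIR1+NIR) — the *soil* index convention, which
    contrasts bare-soil SWIR brightness against vegetation NIR.
    """
    for needed in ("Green", "Red", "NIR", "SWIR1"):
        if needed not in bands:
            raise ValueError(f"missing reflectance band {needed!r}")
    for name, grid in bands.items():
        vals = grid.values
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError(f"band {name!r} has negative reflectance")
    nir = bands["NIR"].values
    template = bands["NIR"]
    return {
        "NDVI": template.with_values(_normalized_difference(nir, bands["Red"].values)),
        "NDWI": template.with_values(_normalized_difference(bands["Green"].values, nir)),
        "NDSI": template.with_values(_normalized_difference(bands["SWIR1"].values, nir)),
    }


def build_feature_stack(bands: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    """The 9-band feature space: reflectances plus derived indices."""
    missing = [b for b in REFLECTANCE_BANDS if b not in bands]
    if missing:
        raise ValueError(f"missing reflectance bands: {missing}")
    stack = {b: bands[b] for b in REFLECTANCE_BANDS}
    stack.update(compute_indices(bands))
    return stack


def temporal_features(
    dated_stacks: list[dict[str, RasterGrid]],
) -> dict[str, RasterGrid]:
    """Per-band temporal mean and SD layers across acquisition dates.

    With a single date this is a no-op returning that date's stack; with
    several, '<band>_mean' and '<band>_sd' layers are appended to the most
    recent date's stack, stabilising the classification against
    phenological noise.
    """
    if not dated_stacks:
        raise ValueError("need at least one dated feature stack")
    if len(dated_stacks) == 1:
        return dict(dated_stacks[0])
    out = dict(dated_stacks[-1])
    for band in dated_stacks[0]:
        layers = np.stack([s[band].values for s in dated_stacks])
        template = dated_stacks[-1][band]
        out[f"{band}_mean"] = template.with_values(np.nanmean(layers, axis=0))
        out[f"{band}_sd"] = template.with_values(np.nanstd(layers, axis=0))
    return out


def filter_samples(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop samples outside the study boundary, then visually rejected ones.

    ``raw`` needs boolean columns 'inside_boundary' and 'visual_ok'.
    Returns the retained table plus a conserved count ledger
    (raw = removed_boundary + removed_visual + retained).
    """
    n_raw = len(raw)
    inside = raw[raw["inside_boundary"].astype(bool)]
    removed_boundary = n_raw - len(inside)
    retained = inside[inside["visual_ok"].astype(bool)]
    removed_visual = len(inside) - len(retained)
    ledger = {
        "raw": n_raw,
        "removed_boundary": removed_boundary,
        "removed_visual": removed_visual,
        "retained": len(retained),
    }
    if ledger["retained"] == 0:
        logger.warning("sample filtering retained no points")
    return retained.reset_index(drop=True), ledger


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_samples(
    samples: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    class_column: str = "observed_class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/validation split.

    The total training size is round-half-up(n * fraction) (411 samples at
    0.7 give 288); per-class counts are allocated proportionally with
    largest-remainder adjustment so the split is exactly stratified,
    disjoint and exhaustive.  Deterministic for a given seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    target_total = _round_half_up(n * train_fraction)

    classes = sorted(samples[class_column].astype(str).unique())
    ideal = {c: (samples[class_column] == c).sum() * train_fraction for c in classes}
    alloc = {c: int(np.floor(ideal[c])) for c in classes}
    leftover = target_total - sum(alloc.values())
    by_remainder = sorted(classes, key=lambda c: (-(ideal[c] - alloc[c]), c))
    for c in by_remainder[:leftover]:
        alloc[c] += 1

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for c in classes:
        members = samples.index[samples[class_column] == c].to_numpy()
        take = min(alloc[c], len(members))
        train_idx.extend(rng.choice(members, size=take, replace=False))
    train_mask = samples.index.isin(train_idx)
    return (
        samples[train_mask].reset_index(drop=True),
        samples[~train_mask].reset_index(drop=True),
    )


def default_classifier():
    """Soft-margin RBF-kernel SVM with feature standardisation."""
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale"))


def classify_cover(
    features: dict[str, RasterGrid],
    train: pd.DataFrame,
    classifier=None,
) -> RasterGrid:
    """Train on per-point feature vectors and label every valid cell 0/1.

    The classifier is any object with fit(X, y)/predict(X); training
    points carry x/y coordinates and 'observed_class'.  A degenerate
    training set with identical feature vectors but mixed labels yields a
    majority-class map with a warning.
    """
    names = list(features)
    template = features[names[0]]
    X_train = np.column_stack(
        [features[n].sample(train["x"].to_numpy(), train["y"].to_numpy()) for n in names]
    )
    y_train = (train["observed_class"].astype(str) == TARGET).to_numpy(dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    ok = np.all(np.isfinite(X_train), axis=1)
    X_train, y_train = X_train[ok], y_train[ok]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes after dropping nodata")

    grid_X = np.column_stack([features[n].values.ravel() for n in names])
    valid = np.all(np.isfinite(grid_X), axis=1)
    out = np.full(grid_X.shape[0], np.nan)

    if np.allclose(X_train, X_train[0], equal_nan=True):
        majority = int(np.round(y_train.mean()))
        logger.warning(
            "all training feature vectors identical with mixed labels; "
            "returning majority-class (%d) map", majority
        )
        out[valid] = majority
    else:
        clf = classifier if classifier is not None else default_classifier()
        clf.fit(X_train, y_train)
        out[valid] = clf.predict(grid_X[valid])
    return template.with_values(out.reshape(template.shape))


def assess_accuracy(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Overall accuracy at validation points, as percent to one decimal."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must be paired vectors of equal length")
    if pred.size < 1:
        raise ValueError("need at least one validation point")
    correct = int(np.sum(pred == truth))
    n = int(pred.size)
    return {
        "n": n,
        "correct": correct,
        "misclassified": n - correct,
        "overall_accuracy": round(100.0 * correct / n, 1),
    }


def patch_change_report(map1: RasterGrid, map2: RasterGrid) -> pd.DataFrame:
    """Per-patch class-change fraction, for manual interpretation review.

    Patches are 8-connected components of presence in either year; each row
    reports the fraction of the patch whose class differs between the two
    maps, supporting a human screening rule on excessive patch change.
    """
    if not map1.same_geometry(map2):
        raise ValueError("maps must share grid geometry")
    union = (map1.values == 1) | (map2.values == 1)
    labels, n_patches = ndimage.label(union, structure=np.ones((3, 3)))
    rows = []
    changed = map1.values != map2.values
    for patch in range(1, n_patches + 1):
        cells = labels == patch
        rows.append(
            {
                "patch_id": patch,
                "n_cells": int(cells.sum()),
                "changed_fraction": float(changed[cells].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["patch_id", "n_cells", "changed_fraction"])
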