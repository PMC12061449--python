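"""Stratified-heterogeneity q statistic: factor and interaction detectors.

The factor detector measures how much of a response's spatial variance a
stratification explains:

    q = 1 - SSW / SST,   SSW = sum_h N_h * sigma_h^2,   SST = N * sigma^2

with population variances (sigma^2 divides by N, sigma_h^2 by N_h).
q = 0 means the strata carry no information about the response; q = 1
means the response is constant within every stratum.  The interaction
detector computes q on the overlay of two stratifications (the distinct
pairs of labels) and classifies the pair by comparing the overlay q with
the single-factor q values, distinguishing independence, bivariate and
nonlinear enhancement, and the weaken categories.

Because the overlay refines both partitions, q(A∩B) >= max(qA, qB) holds
exactly whenever all three are computed on the same observations, so the
weaken categories can only arise under unequal sample handling; both q
values here are always recomputed on the shared retained set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StrataAssignment",
    "QResult",
    "InteractionResult",
    "discretize",
    "factor_q",
    "interaction_q",
    "classify_interaction",
    "run_detectors",
    "q_sensitivity",
    "INTERACTION_CATEGORIES",
]

INTERACTION_CATEGORIES = (
    "nonlinear-weaken",
    "single-weaken",
    "bi-enhance",
    "independent",
    "nonlinear-enhance",
)

MISSING_LABEL = 0


@dataclass
class StrataAssignment:
    """Integer stratum labels (1..L; 0 = missing) for one factor."""

    factor_name: str
    labels: np.ndarray
    L: int
    method: str
    breakpoints: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = self.labels[self.labels != MISSING_LABEL]
        if present.size and (present.min() < 1 or present.max() > self.L):
            raise ValueError("labels must lie in 1..L (0 for missing)")
        if self.L < 1:
            raise ValueError("L must be >= 1")


@dataclass
class QResult:
    """The q statistic with its variance decomposition."""

    factor_name: str
    q: float
    ssw: float
    sst: float
    n: int
    strata: pd.DataFrame  # columns: stratum, N_h, mean_h, var_h
    dropped_strata: list[int] = field(default_factory=list)


@dataclass
class InteractionResult:
    factor_a: str
    factor_b: str
    q_a: float
    q_b: float
    q_ab: float
    category: str
    n: int


def _kmeans_1d(values: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Variance-minimising 1-D k-means breakpoints (interior cut points).

    Centres are initialised at evenly spaced quantiles; Lloyd iterations on
    the sorted values converge quickly and, for well-separated groups,
    reach the optimal partition.
    """
    x = np.sort(values)
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(max_iter):
        cuts = (centers[:-1] + centers[1:]) / 2
        labels = np.searchsorted(cuts, x)
        new_centers = np.array(
            [x[labels == j].mean() if np.any(labels == j) else centers[j] for j in range(k)]
        )
        if np.allclose(new_centers, centers):
            break
        centers = new_centers
    return (centers[:-1] + centers[1:]) / 2


def discretize(
    values: np.ndarray,
    method: str = "quantile",
    k: int = 5,
    factor_name: str = "",
) -> StrataAssignment:
    """Assign stratum labels 1..k to a real vector.

    Methods: 'quantile' (equal-frequency), 'equal-interval',
    'natural-breaks' (1-D variance-minimising k-means partition), and
    'categorical' (integer codes passed through).  Non-finite values get
    the missing label 0.  If fewer than k distinct values exist, k is
    reduced with a warning; a constant vector yields a single stratum.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    labels = np.zeros(values.shape, dtype=int)

    if method == "categorical":
        cats = np.unique(values[finite])
        code = {v: i + 1 for i, v in enumerate(cats)}
        labels[finite] = [code[v] for v in values[finite]]
        return StrataAssignment(factor_name, labels, max(len(cats), 1), method, cats)

    if k < 2:
        raise ValueError("k must be >= 2 for continuous discretization")
    distinct = np.unique(values[finite])
    if distinct.size == 0:
        raise ValueError("no finite values to discretize")
    if distinct.size < k:
        logger.warning(
            "only %d distinct values for %r; reducing strata count from %d",
            distinct.size, factor_name, k,
        )
        k = max(int(distinct.size), 1)
    if k == 1:
        labels[finite] = 1
        return StrataAssignment(factor_name, labels, 1, method, None)

    x = values[finite]
    if method == "quantile":
        cuts = np.unique(np.quantile(x, np.arange(1, k) / k))
    elif method == "equal-interval":
        cuts = np.linspace(x.min(), x.max(), k + 1)[1:-1]
    elif method == "natural-breaks":
        cuts = _kmeans_1d(x, k)
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    labels[finite] = np.searchsorted(cuts, x, side="right") + 1
    # relabel to consecutive 1..L in case of empty bins from tied quantiles
    present = np.unique(labels[finite])
    remap = {old: new + 1 for new, old in enumerate(present)}
    labels[finite] = [remap[v] for v in labels[finite]]
    return StrataAssignment(factor_name, labels, len(present), method, np.asarray(cuts))


def _q_from_groups(y: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, pd.DataFrame]:
    """(q, SSW, SST, per-stratum table) over observations already screened."""
    n = y.size
    sst = n * float(np.var(y))  # population variance
    rows = []
    ssw = 0.0
    for h in np.unique(labels):
        yh = y[labels == h]
        var_h = float(np.var(yh))
        ssw += yh.size * var_h
        rows.append({"stratum": int(h), "N_h": int(yh.size),
                     "mean_h": float(yh.mean()), "var_h": var_h})
    if sst <= 0:
        raise ValueError("q undefined: response has zero variance (SST = 0)")
    q = 1.0 - ssw / sst
    assert -1e-9 <= q <= 1 + 1e-9, f"q out of [0,1]: {q}"
    return float(np.clip(q, 0.0, 1.0)), ssw, sst, pd.DataFrame(rows)


def factor_q(
    y: np.ndarray,
    strata: StrataAssignment,
    min_stratum_n: int = 2,
) -> QResult:
    """Factor detector: q for one stratified factor.

    Observations with missing y or missing stratum are excluded listwise;
    strata smaller than ``min_stratum_n`` are dropped (and logged), never
    merged.
    """
    y = np.asarray(y, dtype=float)
    labels = strata.labels
    if y.shape != labels.shape:
        raise ValueError("y and stratum labels must be aligned")
    ok = np.isfinite(y) & (labels != MISSING_LABEL)
    y, labels = y[ok], labels[ok]

    dropped = []
    uniq, counts = np.unique(labels, return_counts=True)
    for h, c in zip(uniq, counts):
        if c < min_stratum_n:
            dropped.append(int(h))
    if dropped:
        keep = ~np.isin(labels, dropped)
        y, labels = y[keep], labels[keep]
        logger.info("dropped strata %s of %r (fewer than %d observations)",
                    dropped, strata.factor_name, min_stratum_n)
    if y.size < 2:
        raise ValueError("fewer than 2 observations remain after dropping small strata")
    q, ssw, sst, table = _q_from_groups(y, labels)
    return QResult(strata.factor_name, q, ssw, sst, int(y.size), table, dropped)


def classify_interaction(q_a: float, q_b: float, q_ab: float, tol: float = 1e-9) -> str:
    """Five-way interaction taxonomy from the three q values.

    The sum comparisons take precedence: the pair is nonlinearly enhancing
    if the overlay exceeds the sum of the single-factor contributions, and
    independent if it equals the sum (within tol).  Otherwise the overlay
    is compared with the individual contributions: bivariate enhancement
    if it beats the larger one (ties at the boundary, e.g. a factor
    overlaid with itself, resolve to bi-enhance), single-weaken if it lies
    between the two, nonlinear-weaken below both.
    """
    for v in (q_a, q_b, q_ab):
        if not -tol <= v <= 1 + tol:
            raise ValueError("q values must lie in [0, 1]")
    hi, lo = max(q_a, q_b), min(q_a, q_b)
    if q_ab > q_a + q_b + tol:
        return "nonlinear-enhance"
    if abs(q_ab - (q_a + q_b)) <= tol:
        return "independent"
    if q_ab > hi - tol:
        return "bi-enhance"
    if q_ab >= lo - tol:
        return "single-weaken"
    return "nonlinear-weaken"


def interaction_q(
    y: np.ndarray,
    strata_a: StrataAssignment,
    strata_b: StrataAssignment,
    min_stratum_n: int = 2,
    tol: float = 1e-9,
) -> InteractionResult:
    """Interaction detector: q on the overlay of two stratifications.

    The overlay strata are the distinct (label_a, label_b) pairs.  After
    dropping overlay strata below ``min_stratum_n``, the two single-factor
    q values are recomputed on exactly the retained observations so that
    the three q values are comparable (and the refinement inequality
    q_ab >= max(q_a, q_b) holds by construction).
    """
    y = np.asarray(y, dtype=float)
    la, lb = strata_a.labels, strata_b.labels
    if not (y.shape == la.shape == lb.shape):
        raise ValueError("y and both label vectors must be aligned")
    ok = np.isfinite(y) & (la != MISSING_LABEL) & (lb != MISSING_LABEL)
    y, la, lb = y[ok], la[ok], lb[ok]

    overlay = la * (lb.max() + 1) + lb if y.size else la
    uniq, counts = np.unique(overlay, return_counts=True)
    small = uniq[counts < min_stratum_n]
    keep = ~np.isin(overlay, small)
    y, la, lb, overlay = y[keep], la[keep], lb[keep], overlay[keep]
    if y.size < 2:
        raise ValueError("fewer than 2 observations remain after dropping small overlay strata")

    q_ab, *_ = _q_from_groups(y, overlay)
    q_a, *_ = _q_from_groups(y, la)
    q_b, *_ = _q_from_groups(y, lb)
    return InteractionResult(
        factor_a=strata_a.factor_name,
        factor_b=strata_b.factor_name,
        q_a=q_a,
        q_b=q_b,
        q_ab=q_ab,
        category=classify_interaction(q_a, q_b, q_ab, tol=tol),
        n=int(y.size),
    )


def run_detectors(
    data: pd.DataFrame,
    response: str,
    factor_names: list[str],
    sector_column: str | None = None,
    method: str = "quantile",
    k: int = 5,
    categorical: tuple[str, ...] = (),
    min_stratum_n: int = 2,
    min_sector_cells: int = 30,
) -> dict[str, pd.DataFrame]:
    """Factor and interaction detectors over a flat cell table.

    ``data`` holds one row per analysis cell with the response and factor
    columns (and optionally a sector column for per-sector runs).  Every
    continuous factor is discretized with the same method and strata
    count; factors named in ``categorical`` pass through as integer codes.
    Returns ranked 'factor_q' and 'interaction_q' tables.
    """
    if len(factor_names) < 2:
        raise ValueError("need at least 2 factors")
    sectors = (
        [("all", data)]
        if sector_column is None
        else [(s, g) for s, g in data.groupby(sector_column)]
    )
    fq_rows, iq_rows = [], []
    for sector, sub in sectors:
        sub = sub.dropna(subset=[response, *factor_names])
        if len(sub) < min_sector_cells:
            logger.warning("sector %s has %d cells (< %d); skipped", sector, len(sub), min_sector_cells)
            continue
        y = sub[response].to_numpy()
        assignments = {
            name: discretize(
                sub[name].to_numpy(),
                method="categorical" if name in categorical else method,
                k=k,
                factor_name=name,
            )
            for name in factor_names
        }
        for name, strata in assignments.items():
            try:
                res = factor_q(y, strata, min_stratum_n=min_stratum_n)
            except ValueError as exc:
                logger.warning("factor %s in sector %s skipped: %s", name, sector, exc)
                continue
            fq_rows.append({"sector": sector, "factor": name, "q": res.q, "N": res.n})
        for a, b in itertools.combinations(factor_names, 2):
            try:
                res = interaction_q(y, assignments[a], assignments[b], min_stratum_n=min_stratum_n)
            except ValueError as exc:
                logger.warning("pair (%s, %s) in sector %s skipped: %s", a, b, sector, exc)
                continue
            iq_rows.append(
                {"sector": sector, "factor_a": a, "factor_b": b,
                 "q_a": res.q_a, "q_b": res.q_b, "q_ab": res.q_ab,
                 "category": res.category, "N": res.n}
            )
    factor_table = pd.DataFrame(fq_rows, columns=["sector", "factor", "q", "N"])
    pair_table = pd.DataFrame(
        iq_rows, columns=["sector", "factor_a", "factor_b", "q_a", "q_b", "q_ab", "category", "N"]
    )
    if not factor_table.empty:
        factor_table = factor_table.sort_values(
            ["sector", "q"], ascending=[True, False]
        ).reset_index(drop=True)
    if not pair_table.empty:
        pair_table = pair_table.sort_values(
            ["sector", "q_ab"], ascending=[True, False]
        ).reset_index(drop=True)
    return {"factor_q": factor_table, "interaction_q": pair_table}


def q_sensitivity(
    y: np.ndarray,
    values: np.ndarray,
    factor_name: str = "",
    method: str = "quantile",
    ks: tuple[int, ...] = (3, 4, 5, 6, 7, 8),
    min_stratum_n: int = 2,
) -> pd.DataFrame:
    """q as a function of the strata count — the discretization sensitivity report."""
    rows = []
    for k in ks:
        strata = discretize(values, method=method, k=k, factor_name=factor_name)
        res = factor_q(y, strata, min_stratum_n=min_stratum_n)
        rows.append({"factor": factor_name, "k": k, "L_effective": strata.L, "q": res.q})
    return pd.DataFrame(rows)
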