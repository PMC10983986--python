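"""Statistics on top of a finished gradient map.

Two layers: (i) asymmetric gradient-to-gradient proximity — for every grid
point carrying a passing gradient of program A, the distance to the nearest
grid point carrying program B, averaged over A's grids (note D(A,B) and
D(B,A) generally differ); (ii) tumor association — the fraction of
tumor-flagged spots per window, averaged over a program's passing windows,
then grouped into three tumor-ratio clusters (TRCs: normal-leaning,
boundary, tumor-leaning) by optimal one-dimensional k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .gradient import GradientMap, GridWindow

__all__ = [
    "ProximityMatrix",
    "TumorAssociation",
    "gradient_distance",
    "proximity_matrix",
    "window_tumor_ratio",
    "program_mean_tumor_ratio",
    "cluster_tumor_ratios",
    "tumor_association",
]


@dataclass
class ProximityMatrix:
    """Pairwise gradient proximity; rows = from-program, columns = to.

    ``distance`` holds the raw means in coordinate units; ``log_distance``
    is log(D + eps) for display, with eps avoiding log(0) at coincident
    grids.
    """

    distance: pd.DataFrame
    log_distance: pd.DataFrame
    eps: float


@dataclass
class TumorAssociation:
    """Per-program mean tumor ratio over passing windows, plus TRC labels."""

    window_ratio: pd.Series       # grid_id -> ratio in [0, 1]
    program_mean: pd.Series       # program -> mean ratio
    trc: pd.Series                # program -> cluster label 1..k (1 = lowest)


def _mean_min_dist(a_xy: np.ndarray, b_xy: np.ndarray) -> float:
    d = cdist(a_xy, b_xy)
    return float(d.min(axis=1).mean())


def gradient_distance(gmap: GradientMap, a, b) -> float:
    """Mean distance from each A-passing grid point to its nearest B grid.

    Asymmetric by construction.  Returns NaN with a warning when B has no
    passing grid points (undefined, never imputed as 0).
    """
    a_xy = gmap.passing_grid_xy(a)
    b_xy = gmap.passing_grid_xy(b)
    if len(a_xy) == 0:
        raise ValueError(f"program {a!r} has no passing grid points")
    if len(b_xy) == 0:
        warnings.warn(f"gradient_distance: program {b!r} has no passing grids; NaN")
        return float("nan")
    return _mean_min_dist(a_xy, b_xy)


def proximity_matrix(gmap: GradientMap, eps: float = 1.0) -> ProximityMatrix:
    """Full pairwise proximity over retained programs.

    The diagonal is 0 (a grid is its own nearest neighbor).  The display
    copy is log(D + eps); the raw matrix is always reported untransformed.
    """
    progs = list(gmap.retained)
    if not progs:
        raise ValueError("no retained programs")
    coords = {p: gmap.passing_grid_xy(p) for p in progs}
    D = pd.DataFrame(index=progs, columns=progs, dtype=float)
    for a in progs:
        for b in progs:
            D.loc[a, b] = _mean_min_dist(coords[a], coords[b])
    logD = np.log(D + eps)
    return ProximityMatrix(distance=D, log_distance=logD, eps=eps)


def window_tumor_ratio(windows: Sequence[GridWindow],
                       tumor_flag: np.ndarray) -> pd.Series:
    """Fraction of tumor-flagged spots among each window's Q members."""
    if tumor_flag is None:
        raise ValueError("tumor flags are required for tumor ratios")
    tumor_flag = np.asarray(tumor_flag)
    if np.issubdtype(tumor_flag.dtype, np.floating) and np.isnan(tumor_flag).any():
        bad = np.flatnonzero(np.isnan(tumor_flag))
        raise ValueError(f"tumor flag missing for spots {bad[:10].tolist()}")
    tumor_flag = tumor_flag.astype(bool)
    ratios = {w.grid_id: float(tumor_flag[w.members].mean()) for w in windows}
    s = pd.Series(ratios, name="tumor_ratio")
    s.index.name = "grid_id"
    return s


def program_mean_tumor_ratio(gmap: GradientMap, ratios: pd.Series) -> pd.Series:
    """Unweighted mean window tumor ratio over each retained program's
    passing grid points."""
    out = {}
    passing = gmap.passing
    for p in gmap.retained:
        grids = passing.loc[passing["program"] == p, "grid_id"]
        out[p] = float(ratios.loc[grids].mean())
    s = pd.Series(out, name="mean_tumor_ratio")
    s.index.name = "program"
    return s


# ---------------------------------------------------------------------------
# 1-D clustering of mean tumor ratios (TRC labels)
# ---------------------------------------------------------------------------

def _kmeans_1d(values: np.ndarray, k: int):
    """Optimal 1-D k-means by dynamic programming over contiguous segments.

    In one dimension the optimal k-means partition is contiguous in sorted
    order, so an O(k n^2) DP over split points is exact and deterministic.
    Returns cluster labels (0-based, in sorted-value order).
    """
    n = len(values)
    order = np.argsort(values, kind="stable")
    x = values[order]
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: int, j: int) -> float:  # half-open [i, j)
        s, s2, m = pref[j] - pref[i], pref2[j] - pref2[i], j - i
        return s2 - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + seg_cost(i, j)
                if v < best:
                    best, arg = v, i
            cost[c, j], split[c, j] = best, arg
    labels_sorted = np.zeros(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = split[c, j]
        labels_sorted[i:j] = c - 1
        j = i
    labels = np.zeros(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def cluster_tumor_ratios(means: pd.Series, k: int = 3, seed: int = 0) -> pd.Series:
    """Group per-program mean tumor ratios into k tumor-ratio clusters.

    Exact 1-D k-means (optimal contiguous partition of the sorted ratios),
    relabeled so cluster 1 has the lowest mean ratio and cluster k the
    highest — reading off as normal-leaning / boundary / tumor-leaning for
    the default k=3.  With fewer programs than k, each program gets its own
    cluster ordered by ratio; with fewer distinct ratios than k, only the
    leading labels are used (warning).

    ``seed`` is accepted for interface stability; the solver is exact and
    does not use it.
    """
    values = means.to_numpy(dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("no programs to cluster")
    distinct = np.unique(values)
    if n <= k or len(distinct) < k:
        if len(distinct) < min(k, n):
            warnings.warn(
                f"cluster_tumor_ratios: only {len(distinct)} distinct ratio(s); "
                f"{min(k, n) - len(distinct)} label(s) left empty"
            )
        ranks = {v: i + 1 for i, v in enumerate(distinct)}
        labels = np.array([ranks[v] for v in values])
    else:
        raw = _kmeans_1d(values, k)
        order = np.argsort([values[raw == c].mean() for c in range(k)], kind="stable")
        relabel = {int(c): i + 1 for i, c in enumerate(order)}
        labels = np.array([relabel[int(c)] for c in raw])
    s = pd.Series(labels, index=means.index, name="trc")
    s.index.name = "program"
    return s


def tumor_association(gmap: GradientMap, tumor_flag: np.ndarray,
                      k: int = 3, seed: int = 0) -> TumorAssociation:
    """Convenience wrapper: window ratios -> program means -> TRC labels."""
    ratios = window_tumor_ratio(gmap.windows, tumor_flag)
    means = program_mean_tumor_ratio(gmap, ratios)
    trc = cluster_tumor_ratios(means, k=k, seed=seed)
    return TumorAssociation(window_ratio=ratios, program_mean=means, trc=trc)
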