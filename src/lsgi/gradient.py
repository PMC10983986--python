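"""Local spatial gradient inference: the sliding-window regression engine.

The slide is tiled into P = round(N/S) overlapping windows: spots are
grouped into P equal-size spatial clusters, each cluster's centroid becomes
a grid point, and the window at a grid point is the Q spots nearest to it
(Euclidean).  With the defaults S=5, Q=25 every spot belongs to Q/S = 5
windows on average — an exact identity, since total membership is P*Q.

In every window, each program's spot loadings F are regressed on the
coordinates, F ~ X + Y (ordinary least squares with intercept).  The
coefficients (beta_x, beta_y) point in the direction of increasing program
activity; R-squared measures how much of the local loading variation space
explains, and gates whether a gradient is called (R2 >= 0.6 by default).
Programs with passing fits in fewer than 5% of grid points are discarded
as noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "GridWindow",
    "LocalFit",
    "GradientMap",
    "build_windows",
    "fit_local_gradient",
    "fit_all",
    "filter_gradients",
]


@dataclass
class GridWindow:
    """One sliding window: a grid point and the Q spots nearest to it."""

    grid_id: int
    grid_xy: np.ndarray
    members: np.ndarray  # spot indices, length Q

    def __post_init__(self) -> None:
        self.grid_xy = np.asarray(self.grid_xy, dtype=float)
        self.members = np.asarray(self.members, dtype=int)
        if len(np.unique(self.members)) != len(self.members):
            raise ValueError("window members must be unique")


@dataclass
class LocalFit:
    """One program's fitted local gradient in one window."""

    grid_id: int
    program: object
    beta_x: float
    beta_y: float
    intercept: float
    r2: float
    degenerate: bool = False

    @property
    def direction(self) -> np.ndarray:
        """Unit vector toward increasing loading; zero if undefined."""
        v = np.array([self.beta_x, self.beta_y], dtype=float)
        n = np.linalg.norm(v)
        if self.degenerate or n == 0:
            return np.zeros(2)
        return v / n


@dataclass
class GradientMap:
    """All local fits plus the R2/retention filtering outcome.

    ``fits`` is the full (grid x program) table with a boolean ``passing``
    column; ``retained`` lists the programs with enough passing grid points.
    """

    windows: list
    fits: pd.DataFrame
    retained: list
    params: dict
    P: int

    @property
    def passing(self) -> pd.DataFrame:
        return self.fits[self.fits["passing"]]

    def passing_grid_xy(self, program) -> np.ndarray:
        """Coordinates of grid points where ``program`` passes the gate."""
        sub = self.passing
        sub = sub[sub["program"] == program]
        return sub[["x", "y"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

def build_windows(coords: np.ndarray, S: int = 5, Q: int = 25,
                  seed: int = 0) -> list:
    """Tile the slide into P = round(N/S) overlapping Q-spot windows.

    Spots are clustered into P balanced spatial groups (seeded k-means
    followed by greedy reassignment until cluster sizes differ by at most
    one); each group's member centroid is a grid point, and the window is
    the Q spots nearest to it, distance ties broken by spot index.
    """
    coords = np.asarray(coords, dtype=float)
    N = coords.shape[0]
    if N < Q:
        raise ValueError(f"N={N} < Q={Q}; choose a smaller window size Q")
    P = int(math.floor(N / S + 0.5))
    if P < 1:
        raise ValueError(f"round(N/S) = round({N}/{S}) < 1; decrease S")
    if P > N:
        P = N
    if P == 1:
        labels = np.zeros(N, dtype=int)
    else:
        km = KMeans(n_clusters=P, n_init=1, random_state=seed).fit(coords)
        labels = _balance_clusters(coords, km.labels_.copy(), P)
    windows = []
    for g in range(P):
        members_g = np.flatnonzero(labels == g)
        centroid = coords[members_g].mean(axis=0)
        d = np.linalg.norm(coords - centroid[None, :], axis=1)
        order = np.lexsort((np.arange(N), d))  # ties -> smaller spot index
        windows.append(GridWindow(grid_id=g, grid_xy=centroid, members=order[:Q]))
    return windows


def _balance_clusters(coords: np.ndarray, labels: np.ndarray, P: int) -> np.ndarray:
    """Greedy capacity-constrained rebalancing: sizes end up differing <= 1.

    Repeatedly moves, from the largest cluster, the member closest to the
    smallest cluster's centroid. Deterministic (index tie-breaks).
    """
    sizes = np.bincount(labels, minlength=P)
    # guard against empty kmeans clusters on adversarial inputs
    centroids = np.zeros((P, 2))
    for g in range(P):
        if sizes[g]:
            centroids[g] = coords[labels == g].mean(axis=0)
    while sizes.max() - sizes.min() > 1:
        big = int(np.argmax(sizes))
        small = int(np.argmin(sizes))
        members = np.flatnonzero(labels == big)
        d = np.linalg.norm(coords[members] - centroids[small][None, :], axis=1)
        mover = members[int(np.lexsort((members, d))[0])]
        labels[mover] = small
        sizes[big] -= 1
        sizes[small] += 1
        for g in (big, small):
            centroids[g] = coords[labels == g].mean(axis=0)
    return labels


# ---------------------------------------------------------------------------
# local regression
# ---------------------------------------------------------------------------

def _design(coords_window: np.ndarray) -> np.ndarray:
    Q = coords_window.shape[0]
    return np.column_stack([np.ones(Q), coords_window])


def _fit_window(F: np.ndarray, X: np.ndarray, degenerate_design: bool):
    """OLS of loadings on [1, x, y] via pseudoinverse; returns coefs, r2."""
    beta = np.linalg.pinv(X) @ F  # 3 x k (or length 3)
    resid = F - X @ beta
    ssres = (resid * resid).sum(axis=0)
    centered = F - F.mean(axis=0)
    sstot = (centered * centered).sum(axis=0)
    # exactly constant loadings: define SStot = 0 despite rounding in the mean
    sstot = np.where(F.max(axis=0) == F.min(axis=0), 0.0, sstot)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sstot > 0, 1.0 - ssres / np.maximum(sstot, 1e-300), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    if degenerate_design:
        r2 = np.zeros_like(r2)
    return beta, r2, sstot


def fit_local_gradient(F_window: np.ndarray, coords_window: np.ndarray,
                       grid_id: int = 0, program: object = 0) -> LocalFit:
    """Fit one program's local gradient in one window.

    OLS with intercept of loadings on (x, y).  If the loadings are constant
    (zero variance) R2 is defined as 0 and the direction as the zero vector;
    a rank-deficient design (collinear coordinates) is fit through the
    pseudoinverse and flagged degenerate with R2 = 0.
    """
    F = np.asarray(F_window, dtype=float)
    C = np.asarray(coords_window, dtype=float)
    if F.shape[0] != C.shape[0]:
        raise ValueError("loadings and coordinates disagree in length")
    if F.shape[0] < 4:
        raise ValueError("need Q >= 4 spots for a 3-parameter fit")
    X = _design(C)
    rank_deficient = np.linalg.matrix_rank(X) < 3
    beta, r2, sstot = _fit_window(F[:, None], X, rank_deficient)
    degenerate = bool(rank_deficient or sstot[0] == 0)
    bx, by = float(beta[1, 0]), float(beta[2, 0])
    if sstot[0] == 0 and not rank_deficient:
        bx = by = 0.0  # constant loadings: no gradient by definition
    return LocalFit(
        grid_id=grid_id, program=program,
        beta_x=bx, beta_y=by, intercept=float(beta[0, 0]),
        r2=0.0 if degenerate else float(r2[0]),
        degenerate=degenerate,
    )


def fit_all(W: np.ndarray, windows: Sequence[GridWindow], coords: np.ndarray,
            programs: Optional[Sequence] = None) -> pd.DataFrame:
    """Fit every program in every window; returns the long fit table.

    Row order is deterministic: grid-major, then program.  Columns:
    grid_id, x, y, program, beta_x, beta_y, intercept, r2, dx, dy,
    degenerate.
    """
    W = np.asarray(W, dtype=float)
    coords = np.asarray(coords, dtype=float)
    k = W.shape[1]
    if programs is None:
        programs = list(range(k))
    if len(programs) != k:
        raise ValueError("programs labels must match W columns")
    rows = []
    for win in windows:
        C = coords[win.members]
        X = _design(C)
        rank_deficient = np.linalg.matrix_rank(X) < 3
        F = W[win.members]  # Q x k
        beta, r2, sstot = _fit_window(F, X, rank_deficient)
        for j in range(k):
            degenerate = bool(rank_deficient or sstot[j] == 0)
            bx, by = float(beta[1, j]), float(beta[2, j])
            if degenerate and sstot[j] == 0:
                bx = by = 0.0
            norm = math.hypot(bx, by)
            dx, dy = (bx / norm, by / norm) if norm > 0 and not degenerate else (0.0, 0.0)
            rows.append((win.grid_id, win.grid_xy[0], win.grid_xy[1], programs[j],
                         bx, by, float(beta[0, j]),
                         0.0 if degenerate else float(r2[j]),
                         dx, dy, degenerate))
    return pd.DataFrame(rows, columns=[
        "grid_id", "x", "y", "program", "beta_x", "beta_y", "intercept",
        "r2", "dx", "dy", "degenerate",
    ])


def filter_gradients(fits: pd.DataFrame, windows: Sequence[GridWindow],
                     r2_min: float = 0.6, min_frac: float = 0.05,
                     params: Optional[dict] = None) -> GradientMap:
    """Gate fits by R2 and retain programs with enough passing grid points.

    A fit passes iff ``r2 >= r2_min`` (inclusive) and is not degenerate; a
    program is retained iff it passes in at least ``ceil(min_frac * P)``
    grid points.  Fits of non-retained programs stay in the table but are
    not marked passing.  An empty map (nothing retained) is a valid result.
    """
    P = len(windows)
    fits = fits.copy()
    gate = (fits["r2"] >= r2_min) & (~fits["degenerate"].astype(bool))
    need = math.ceil(min_frac * P)
    counts = fits.loc[gate, "program"].value_counts()
    retained = sorted(
        (p for p in counts.index if counts[p] >= need),
        key=lambda p: str(p),
    )
    fits["passing"] = gate & fits["program"].isin(retained)
    base = {"S": None, "Q": None, "r2_min": r2_min, "min_frac": min_frac}
    if params:
        base.update(params)
    return GradientMap(windows=list(windows), fits=fits, retained=retained,
                       params=base, P=P)
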