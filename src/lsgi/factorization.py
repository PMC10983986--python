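"""Count normalization and non-negative program discovery.

Spots-by-genes counts are depth-normalized and log-transformed, then
factorized with non-negative matrix factorization (NMF) into k programs:
spot loadings ``W`` (N x k, per-spot program activity) and gene loadings
``H`` (k x G, per-gene attribution).  The rank k is chosen by Wold-style
cross-validation: a random subset of matrix entries is held out, the model
is fit on the observed entries only, and k minimizing held-out squared
error wins.

The solver is deliberately simple and fully deterministic: NNDSVDa
initialization (SVD-based, with a fixed sign convention) followed by
multiplicative Frobenius updates, optionally under an observation mask.
Determinism matters more here than the last digit of the objective —
downstream gradient fits are invariant to per-program scale anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "FactorModel",
    "ProgramSignature",
    "RankSelection",
    "normalize_counts",
    "factorize",
    "select_rank",
    "top_genes",
]

_EPS = 1e-10


@dataclass
class FactorModel:
    """Non-negative factor model: W (spots x k) and H (k x genes).

    Scale convention: every H row is normalized to unit maximum, with the
    scale absorbed into the matching W column, so loadings are comparable
    across programs.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    seed: int
    gene_ids: Optional[list] = None
    spot_ids: Optional[list] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.W.shape[1] != self.H.shape[0]:
            raise ValueError("W columns != H rows")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("factor matrices must be non-negative")

    @property
    def programs(self) -> list:
        return list(range(self.W.shape[1]))

    @property
    def n_spots(self) -> int:
        return self.W.shape[0]


@dataclass
class ProgramSignature:
    """Top genes of one program, ordered by descending gene loading."""

    program: object
    genes: list
    loadings: np.ndarray

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if len(self.genes) != len(self.loadings):
            raise ValueError("genes and loadings length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes not unique")
        if np.any(np.diff(self.loadings) > 0):
            raise ValueError("loadings must be non-increasing")


@dataclass
class RankSelection:
    k: int
    ks: list
    errors: list  # mean held-out MSE per candidate k


def normalize_counts(counts, scale: float = 1e4):
    """Depth-normalize and log-transform counts.

    Each entry becomes ``log(1 + count / spot_depth * scale)`` with
    ``spot_depth`` the spot's total count — the standard library-size
    normalization of the single-cell toolkits.  All-zero spots are dropped
    with a warning (their depth is undefined).

    Returns ``(X, kept)`` where ``kept`` is a boolean mask over input spots.
    Sparse input stays sparse.
    """
    sparse = sp.issparse(counts)
    if sparse:
        counts = counts.tocsr().astype(float)
        depths = np.asarray(counts.sum(axis=1)).ravel()
    else:
        counts = np.asarray(counts, dtype=float)
        depths = counts.sum(axis=1)
    if (counts < 0).sum() if not sparse else (counts.data < 0).sum():
        raise ValueError("counts must be non-negative")
    kept = depths > 0
    if not kept.any():
        raise ValueError("all spots have zero total counts")
    if not kept.all():
        warnings.warn(f"normalize_counts: dropping {int((~kept).sum())} all-zero spot(s)")
    if sparse:
        X = counts[kept]
        d = depths[kept]
        X = sp.diags(scale / d) @ X
        X.data = np.log1p(X.data)
        X = sp.csr_matrix(X)
    else:
        X = counts[kept]
        X = np.log1p(X / depths[kept, None] * scale)
    return X, kept


# ---------------------------------------------------------------------------
# solver internals
# ---------------------------------------------------------------------------

def _nndsvda(X: np.ndarray, k: int) -> tuple:
    """Deterministic NNDSVDa initialization (zeros filled with the mean).

    Singular-vector signs are fixed by the sign of each vector's
    largest-magnitude left entry so the result is invariant to the
    sign ambiguity of the underlying SVD.
    """
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for j in range(k):
        s = np.sign(U[np.argmax(np.abs(U[:, j])), j]) or 1.0
        U[:, j] *= s
        Vt[j] *= s
    W = np.zeros((X.shape[0], k))
    H = np.zeros((k, X.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            norm = n_up * n_vp
            uu, vv = up / max(n_up, _EPS), vp / max(n_vp, _EPS)
        else:
            norm = n_un * n_vn
            uu, vv = un / max(n_un, _EPS), vn / max(n_vn, _EPS)
        W[:, j] = np.sqrt(S[j] * norm) * uu
        H[j] = np.sqrt(S[j] * norm) * vv
    mean = X.mean()
    W[W < _EPS] = mean
    H[H < _EPS] = mean
    return W, H


def _mu_solve(X, W, H, max_iter: int, tol: float, mask=None):
    """Multiplicative-update Frobenius NMF, optionally masked.

    With a 0/1 ``mask`` the objective is the squared error over observed
    (mask==1) entries only — the fitting rule used for cross-validated
    rank selection.  Returns (W, H, error_trace, converged).
    """
    errs = []
    if mask is not None:
        Xo = mask * X
    for it in range(max_iter):
        if mask is None:
            H *= (W.T @ X) / (W.T @ W @ H + _EPS)
            W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
            R = X - W @ H
            err = float(np.sqrt((R * R).sum()))
        else:
            H *= (W.T @ Xo) / (W.T @ (mask * (W @ H)) + _EPS)
            W *= (Xo @ H.T) / ((mask * (W @ H)) @ H.T + _EPS)
            R = mask * (X - W @ H)
            err = float(np.sqrt((R * R).sum()))
        errs.append(err)
        if it > 0 and abs(errs[-2] - errs[-1]) <= tol * max(errs[0], _EPS):
            return W, H, errs, True
    return W, H, errs, False


def factorize(X, k: int, seed: int = 0, max_iter: int = 500,
              tol: float = 1e-6, gene_ids=None, spot_ids=None) -> FactorModel:
    """Fit a rank-k non-negative factorization of ``X`` (spots x genes).

    Deterministic for fixed inputs: NNDSVDa init, then multiplicative
    updates until the Frobenius error trace flattens (relative change
    below ``tol``) or ``max_iter`` sweeps.  Non-convergence is reported
    in ``provenance['converged']``, not raised.  Degenerate (all-zero)
    programs are dropped with a warning.
    """
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    if not k < min(X.shape):
        raise ValueError(f"k={k} must be < min(N, G)={min(X.shape)}")
    W, H = _nndsvda(X, k)
    W, H, errs, converged = _mu_solve(X, W, H, max_iter=max_iter, tol=tol)
    if not converged:
        warnings.warn(f"factorize: not converged after {max_iter} iterations")
    # drop degenerate programs, then fix the scale convention (H rows unit max)
    alive = (W.sum(axis=0) > _EPS) & (H.sum(axis=1) > _EPS)
    if not alive.all():
        warnings.warn(f"factorize: dropping {int((~alive).sum())} degenerate program(s)")
        W, H = W[:, alive], H[alive]
    hmax = H.max(axis=1)
    H = H / hmax[:, None]
    W = W * hmax[None, :]
    return FactorModel(
        W=W, H=H, k=k, seed=seed, gene_ids=gene_ids, spot_ids=spot_ids,
        provenance={
            "solver": "mu-frobenius/nndsvda",
            "max_iter": max_iter, "tol": tol,
            "converged": converged, "error_trace": errs,
        },
    )


def select_rank(X, k_min: int = 6, k_max: int = 10, seed: int = 0,
                holdout_frac: float = 0.05, n_repeats: int = 3,
                max_iter: int = 200, tol: float = 1e-5) -> RankSelection:
    """Choose the NMF rank by Wold-style cross-validation.

    For each repeat a random ``holdout_frac`` of matrix entries is masked,
    the model is fit on the remaining entries per candidate k, and the
    mean squared error on held-out entries is recorded.  Returns the k
    with the smallest mean held-out error (ties go to the smaller k,
    favoring parsimony) together with the full error curve.
    """
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    if not k_max < min(X.shape):
        raise ValueError(f"k_max={k_max} must be < min(N, G)={min(X.shape)}")
    if k_min > k_max:
        raise ValueError("k_min > k_max")
    ks = list(range(k_min, k_max + 1))
    errors = np.zeros((len(ks), n_repeats))
    for r in range(n_repeats):
        rng = np.random.default_rng([seed, r])
        mask = (rng.random(X.shape) >= holdout_frac).astype(float)
        held = mask == 0
        if not held.any():  # degenerate tiny matrix: hold out one entry
            held = np.zeros(X.shape, bool)
            held[tuple(rng.integers(0, X.shape))] = True
            mask = 1.0 - held
        for i, k in enumerate(ks):
            W0, H0 = _nndsvda(mask * X, k)
            W, H, _, _ = _mu_solve(X, W0, H0, max_iter=max_iter, tol=tol, mask=mask)
            R = (X - W @ H)[held]
            errors[i, r] = float(np.mean(R * R))
    curve = errors.mean(axis=1)
    best = int(np.argmin(curve))  # argmin takes the first index: smaller k on ties
    return RankSelection(k=ks[best], ks=ks, errors=curve.tolist())


def top_genes(model: FactorModel, program: int, n: int = 50) -> ProgramSignature:
    """The n genes with largest loading for one program.

    Ties are broken by lexicographic gene id; if fewer than n genes exist,
    all are returned with a warning.
    """
    if program not in model.programs:
        raise ValueError(f"program {program} not in model")
    if model.gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(model.H.shape[1])]
    else:
        gene_ids = list(model.gene_ids)
    h = model.H[program]
    if n > len(gene_ids):
        warnings.warn(f"top_genes: n={n} > {len(gene_ids)} genes; returning all")
        n = len(gene_ids)
    # sort by loading desc, then gene id asc
    order = sorted(range(len(gene_ids)), key=lambda i: (-h[i], gene_ids[i]))[:n]
    return ProgramSignature(
        program=program,
        genes=[gene_ids[i] for i in order],
        loadings=h[order],
    )
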