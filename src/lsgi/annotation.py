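"""Functional annotation of programs and meta-programs.

Top-gene signatures are tested for over-representation in curated gene
sets by the hypergeometric upper tail, P(X >= m) with X ~ HG(M, K, n):
m overlapping genes, n query genes, K set genes (after intersection with
the universe), M universe genes.  P-values are Benjamini-Hochberg adjusted
per query (across the sets tested for that query), and reported as
E = -log10(p_adj).

Because related programs enrich the same broad sets, annotation terms are
picked in two stages: the top 40 sets per target by adjusted p-value, then
the top 5 of those by cross-program specificity,
spec(p, i) = E[p, i] - mean of E[p', i] over the other programs p',
which rewards sets enriched in this program above the cohort background.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = [
    "hypergeometric_p",
    "enrich",
    "enrich_many",
    "specificity",
    "select_annotations",
]

ENRICH_COLUMNS = ["target", "gene_set", "m", "K", "n", "M", "p", "p_adj", "E"]


def hypergeometric_p(m: int, n: int, K: int, M: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    X counts the overlap when n genes are drawn without replacement from a
    universe of M genes containing K set members.  ``m = 0`` gives exactly
    1; configurations outside the feasible support raise.
    """
    if not (0 <= K <= M and 0 <= n <= M):
        raise ValueError(f"need 0 <= K, n <= M; got K={K}, n={n}, M={M}")
    if m > min(n, K):
        raise ValueError(f"m={m} exceeds min(n={n}, K={K})")
    if m < max(0, n + K - M):
        raise ValueError(
            f"m={m} below the feasible minimum overlap {max(0, n + K - M)} "
            f"(n={n}, K={K}, M={M})"
        )
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, M, K, n))


def enrich(query_genes: Sequence[str], collection: GeneSetCollection,
           universe: Sequence[str], target: str = "query",
           log_base: float = 10.0) -> pd.DataFrame:
    """Hypergeometric enrichment of one query against every set.

    Gene sets are intersected with the universe before testing; sets with
    empty intersection are skipped (counted in a warning).  BH adjustment
    runs across the sets tested for this query; ``E = -log_base(p_adj)``,
    floored at 0.
    """
    uni = set(universe)
    M = len(uni)
    q = set(query_genes)
    stray = q - uni
    if stray:
        raise ValueError(
            f"{len(stray)} query genes are not in the universe: {sorted(stray)[:10]}"
        )
    n = len(q)
    rows = []
    skipped = 0
    for name, genes in collection.items():
        s = set(genes) & uni
        if not s:
            skipped += 1
            continue
        m = len(q & s)
        rows.append((target, name, m, len(s), n, M, hypergeometric_p(m, n, len(s), M)))
    if skipped:
        warnings.warn(f"enrich: skipped {skipped} set(s) with no universe overlap")
    df = pd.DataFrame(rows, columns=["target", "gene_set", "m", "K", "n", "M", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["E"] = np.maximum(-np.log(df["p_adj"].to_numpy()) / np.log(log_base), 0.0)
    else:
        df["p_adj"] = []
        df["E"] = []
    return df[ENRICH_COLUMNS]


def enrich_many(queries: Dict[str, Sequence[str]], collection: GeneSetCollection,
                universe: Sequence[str], log_base: float = 10.0) -> pd.DataFrame:
    """Enrichment for several targets; FDR stays per-target (per test family)."""
    parts = [
        enrich(genes, collection, universe, target=t, log_base=log_base)
        for t, genes in sorted(queries.items())
    ]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=ENRICH_COLUMNS)


def specificity(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Cross-program specificity per (target, gene set).

    spec(p, i) = E[p, i] - mean over the other targets p' of E[p', i];
    undefined (all-NaN) with a single target.  Returned as a wide
    targets x sets frame.  Sets untested for a target contribute E = 0.
    """
    E = enrichment.pivot_table(index="target", columns="gene_set", values="E",
                               fill_value=0.0)
    nprog = E.shape[0]
    if nprog < 2:
        warnings.warn("specificity undefined with a single target")
        return E * np.nan
    total = E.sum(axis=0)
    others_mean = (total - E) / (nprog - 1)
    return E - others_mean


def select_annotations(enrichment: pd.DataFrame, spec: Optional[pd.DataFrame] = None,
                       top_by_p: int = 40, top_by_spec: int = 5) -> pd.DataFrame:
    """Two-stage annotation pick per target.

    Stage 1 keeps the ``top_by_p`` sets by ascending adjusted p (ties by
    larger overlap m, then set name); stage 2 keeps the ``top_by_spec`` of
    those by descending specificity (ties by set name).  Smaller tables
    pass through whole.  Deterministic under row shuffling.
    """
    if spec is None:
        spec = specificity(enrichment)
    out = []
    for target, grp in enrichment.groupby("target", sort=True):
        grp = grp.sort_values(["p_adj", "m", "gene_set"],
                              ascending=[True, False, True], kind="stable")
        stage1 = grp.head(top_by_p).copy()
        sp = spec.loc[target] if target in spec.index else pd.Series(dtype=float)
        stage1["spec"] = [float(sp.get(g, np.nan)) for g in stage1["gene_set"]]
        stage1 = stage1.sort_values(["spec", "gene_set"], ascending=[False, True],
                                    kind="stable", na_position="last")
        out.append(stage1.head(top_by_spec))
    return pd.concat(out, ignore_index=True) if out else enrichment.iloc[0:0]
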