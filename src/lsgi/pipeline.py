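"""Single-sample and multi-sample orchestration.

``run_single_sample`` wires the whole per-slide chain: normalization, NMF
(rank fixed or cross-validated), window construction, per-window fits,
R2/retention filtering, gradient proximity, and tumor association when
labels are present.  All outputs are plain TSV plus a JSON manifest; a
rerun with the same config and seed reproduces every table byte for byte.

``run_meta`` clusters program catalogs from several samples into
meta-programs and scores their label specificity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    FLOAT_FORMAT,
    SpatialDataset,
    write_arrow_field,
    write_gradient_table,
    write_run_manifest,
)
from .factorization import FactorModel, factorize, normalize_counts, select_rank, top_genes
from .gradient import GradientMap, build_windows, filter_gradients, fit_all
from .meta import (
    ProgramCatalog,
    cluster_meta_programs,
    entropy_report,
    write_meta_tables,
)
from .spatial_stats import proximity_matrix, tumor_association

log = logging.getLogger("lsgi")

__all__ = ["RunConfig", "SampleResult", "run_single_sample", "run_meta"]


@dataclass
class RunConfig:
    """All knobs of a run; serialized verbatim into the manifest.

    Defaults follow the method's standard settings: S=5 spots per window
    center (P = round(N/S) windows), window size Q=25, gradient gate
    R2 >= 0.6, retention in >= 5% of grid points, NMF rank scanned 6-10 by
    cross-validation (or fixed via ``k``), 50-gene signatures, founder /
    merge overlap thresholds 21 / 20, 10 entropy shuffles, 3 tumor-ratio
    clusters.
    """

    S: int = 5
    Q: int = 25
    r2_min: float = 0.6
    min_frac: float = 0.05
    k: Optional[int] = None
    k_min: int = 6
    k_max: int = 10
    signature_n: int = 50
    founder_overlap: int = 21
    merge_overlap: int = 20
    n_shuffle: int = 10
    trc_k: int = 3
    seed: int = 0
    scale: float = 1e4
    nmf_max_iter: int = 300
    nmf_tol: float = 1e-5

    def validate(self) -> None:
        if self.S < 1 or self.Q < 4:
            raise ValueError("need S >= 1 and Q >= 4")
        if not 0 <= self.r2_min <= 1 or not 0 <= self.min_frac <= 1:
            raise ValueError("r2_min and min_frac must lie in [0, 1]")
        if self.k is not None and self.k < 2:
            raise ValueError("k must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    def param_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SampleResult:
    model: FactorModel
    gradient_map: GradientMap
    proximity: Optional[object]
    tumor: Optional[object]
    rank_selection: Optional[object]
    manifest: dict


def _write_factor_model(model: FactorModel, outdir: Path) -> None:
    spot_ids = model.spot_ids or [f"spot_{i}" for i in range(model.W.shape[0])]
    gene_ids = model.gene_ids or [f"gene_{j}" for j in range(model.H.shape[1])]
    progs = [f"NMF_{j + 1}" for j in range(model.W.shape[1])]
    pd.DataFrame(model.W, index=spot_ids, columns=progs).to_csv(
        outdir / "W.tsv", sep="\t", float_format=FLOAT_FORMAT, index_label="spot_id")
    pd.DataFrame(model.H, index=progs, columns=gene_ids).to_csv(
        outdir / "H.tsv", sep="\t", float_format=FLOAT_FORMAT, index_label="program")
    side = {
        "k": model.k, "seed": model.seed,
        "solver": model.provenance.get("solver"),
        "converged": model.provenance.get("converged"),
        "n_iter": len(model.provenance.get("error_trace", [])),
        "final_error": (model.provenance.get("error_trace") or [None])[-1],
    }
    (outdir / "factor_model.json").write_text(json.dumps(side, indent=2, sort_keys=True) + "\n")


def run_single_sample(dataset: SpatialDataset, config: Optional[RunConfig] = None,
                      outdir=None, loadings: Optional[np.ndarray] = None,
                      program_labels: Optional[Sequence[str]] = None) -> SampleResult:
    """The full per-slide analysis.

    ``loadings`` (an N x k non-negative matrix) bypasses normalization and
    NMF entirely — any external phenotype quantification is pluggable.
    Zero programs retained is a valid outcome, not an error: many slides
    simply carry no salient gradient.
    """
    config = config or RunConfig()
    config.validate()
    if dataset.n_spots < config.Q:
        raise ValueError(
            f"slide has {dataset.n_spots} spots < Q={config.Q}; decrease Q")
    t0 = time.perf_counter()
    rank_sel = None
    if loadings is not None:
        W = np.asarray(loadings, dtype=float)
        if W.shape[0] != dataset.n_spots:
            raise ValueError("loadings rows != number of spots")
        model = FactorModel(W=W, H=np.ones((W.shape[1], 1)), k=W.shape[1],
                            seed=config.seed, spot_ids=list(dataset.spot_ids),
                            provenance={"solver": "external-loadings"})
        coords, tumor = dataset.coords, dataset.tumor_flag
        spot_ids = list(dataset.spot_ids)
    else:
        X, kept = normalize_counts(dataset.counts, scale=config.scale)
        if not kept.all():
            dataset = dataset.subset_spots(kept)
        coords, tumor = dataset.coords, dataset.tumor_flag
        spot_ids = list(dataset.spot_ids)
        k = config.k
        if k is None:
            rank_sel = select_rank(X, k_min=config.k_min, k_max=config.k_max,
                                   seed=config.seed)
            k = rank_sel.k
            log.info("rank selection: k=%d, curve=%s", k, rank_sel.errors)
        model = factorize(X, k=k, seed=config.seed, max_iter=config.nmf_max_iter,
                          tol=config.nmf_tol, gene_ids=list(dataset.gene_ids),
                          spot_ids=spot_ids)
    if program_labels is None:
        program_labels = [f"NMF_{j + 1}" for j in range(model.W.shape[1])]

    windows = build_windows(coords, S=config.S, Q=config.Q, seed=config.seed)
    fits = fit_all(model.W, windows, coords, programs=program_labels)
    gmap = filter_gradients(fits, windows, r2_min=config.r2_min,
                            min_frac=config.min_frac,
                            params={"S": config.S, "Q": config.Q})
    log.info("windows P=%d, programs k=%d, retained=%s",
             len(windows), model.W.shape[1], gmap.retained)

    prox = proximity_matrix(gmap) if gmap.retained else None
    tumor_assoc = None
    if tumor is not None and gmap.retained:
        tumor_assoc = tumor_association(gmap, tumor, k=config.trc_k, seed=config.seed)

    manifest = {
        "lsgi_version": __version__,
        "config": config.to_dict(),
        "param_hash": config.param_hash(),
        "n_spots": int(coords.shape[0]),
        "n_windows": len(windows),
        "k": int(model.W.shape[1]),
        "retained_programs": list(map(str, gmap.retained)),
        "n_passing_fits": int(gmap.fits["passing"].sum()),
        "loadings_source": model.provenance.get("solver"),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gradient_table(gmap, outdir / "gradient_table.tsv")
        write_arrow_field(gmap, outdir / "arrow_field.tsv")
        if loadings is None:
            _write_factor_model(model, outdir)
        if prox is not None:
            prox.distance.to_csv(outdir / "proximity.tsv", sep="\t",
                                 float_format=FLOAT_FORMAT, index_label="from_program")
            prox.log_distance.to_csv(outdir / "proximity_log.tsv", sep="\t",
                                     float_format=FLOAT_FORMAT, index_label="from_program")
        if tumor_assoc is not None:
            df = pd.DataFrame({
                "program": tumor_assoc.program_mean.index,
                "mean_tumor_ratio": tumor_assoc.program_mean.to_numpy(),
                "trc": tumor_assoc.trc.to_numpy(),
            })
            df.to_csv(outdir / "tumor_association.tsv", sep="\t", index=False,
                      float_format=FLOAT_FORMAT)
        if rank_sel is not None:
            (outdir / "rank_selection.json").write_text(
                json.dumps({"k": rank_sel.k, "ks": rank_sel.ks,
                            "errors": rank_sel.errors}, indent=2) + "\n")
        write_run_manifest(manifest, outdir / "manifest.json")
    log.info("single-sample run finished in %.2fs", time.perf_counter() - t0)
    return SampleResult(model=model, gradient_map=gmap, proximity=prox,
                        tumor=tumor_assoc, rank_selection=rank_sel,
                        manifest=manifest)


def build_catalog(result: SampleResult, sample: str,
                  signature_n: int = 50, study: Optional[str] = None,
                  tumor_type: Optional[str] = None) -> pd.DataFrame:
    """Per-sample catalog rows (retained programs only) for the meta layer."""
    from .meta import CatalogEntry  # local import to avoid cycle at import time

    model = result.model
    labels = sorted(result.gradient_map.retained, key=str)
    rows = []
    name_to_idx = {f"NMF_{j + 1}": j for j in range(model.W.shape[1])}
    for name in labels:
        j = name_to_idx.get(str(name))
        if j is None:
            continue
        sig = top_genes(model, j, n=signature_n)
        for r, (g, l) in enumerate(zip(sig.genes, sig.loadings), start=1):
            rows.append((sample, str(name), r, g, float(l), study, tumor_type))
    return pd.DataFrame(rows, columns=[
        "sample", "program", "rank", "gene", "loading", "study", "tumor_type"])


def run_meta(catalogs: Sequence[pd.DataFrame], config: Optional[RunConfig] = None,
             outdir=None):
    """Cluster per-sample program catalogs into meta-programs.

    ``catalogs`` are long-format frames (sample, program, rank, gene,
    loading, study, tumor_type).  Returns
    ``(meta_programs, unclustered, entropy_reports)``.
    """
    config = config or RunConfig()
    if len(catalogs) < 2:
        raise ValueError("run_meta needs at least two catalogs")
    frames = [pd.DataFrame(c) for c in catalogs]
    gene_spaces = [set(f["gene"]) for f in frames]
    inter = set.intersection(*gene_spaces)
    union = set.union(*gene_spaces)
    if union and len(inter) < 0.5 * min(len(g) for g in gene_spaces):
        import warnings
        warnings.warn(
            f"run_meta: gene namespaces overlap weakly across samples "
            f"(intersection {len(inter)} genes)")
    combined = pd.concat(frames, ignore_index=True)
    catalog = ProgramCatalog.from_frame(combined)
    mps, unclustered = cluster_meta_programs(
        catalog, founder_overlap_min=config.founder_overlap,
        merge_overlap_min=config.merge_overlap)
    reports = {}
    for scheme in ("study", "tumor_type"):
        if all(getattr(e, scheme) is not None for e in catalog.entries) and mps:
            reports[scheme] = entropy_report(mps, catalog, scheme=scheme,
                                             n_shuffle=config.n_shuffle,
                                             seed=config.seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_meta_tables(mps, unclustered, outdir)
        for scheme, rep in reports.items():
            rep.rows.to_csv(outdir / f"entropy_{scheme}.tsv", sep="\t",
                            index=False, float_format=FLOAT_FORMAT)
        write_run_manifest({
            "lsgi_version": __version__,
            "config": config.to_dict(),
            "n_catalog_programs": len(catalog),
            "n_meta_programs": len(mps),
            "n_unclustered": len(unclustered),
        }, outdir / "meta_manifest.json")
    return mps, unclustered, reports
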