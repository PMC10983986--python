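"""Readers and writers for the standard on-disk formats.

Counts arrive as MatrixMarket triplets with separate gene/barcode id files
(10x-style), coordinates as Visium ``tissue_positions`` CSV or a generic
``spot_id, x, y`` TSV, tumor labels as a two-column TSV, and gene sets as GMT.
Result tables are plain TSV with floats at six significant digits.

No science lives here: orientation detection, joining and validation only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpatialDataset",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_positions",
    "write_positions",
    "read_tumor_labels",
    "write_tumor_labels",
    "read_gmt",
    "write_gmt",
    "load_spatial_dataset",
    "write_gradient_table",
    "read_gradient_table",
    "write_arrow_field",
    "FLOAT_FORMAT",
]

#: float serialization used by every table writer (6 significant digits)
FLOAT_FORMAT = "%.6g"

GRADIENT_TABLE_COLUMNS = [
    "grid_id", "x", "y", "program", "beta_x", "beta_y",
    "intercept", "r2", "dx", "dy", "passing",
]


@dataclass
class SpatialDataset:
    """One slide: spot ids, coordinates, counts, optional tumor flags.

    ``counts`` is spots x genes and may be dense or scipy sparse;
    ``coords`` is an N x 2 array of (x, y) in the input's units.
    """

    spot_ids: list
    coords: np.ndarray
    counts: object  # N x G, ndarray or scipy.sparse
    gene_ids: list
    tumor_flag: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.spot_ids)
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({n}, 2) spots"
            )
        if self.counts.shape != (n, len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{n} spots x {len(self.gene_ids)} genes"
            )
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        mn = self.counts.min() if sp.issparse(self.counts) else np.min(self.counts)
        if mn < 0:
            raise ValueError("counts contain negative entries")
        if self.tumor_flag is not None:
            self.tumor_flag = np.asarray(self.tumor_flag, dtype=bool)
            if self.tumor_flag.shape != (n,):
                raise ValueError("tumor_flag length != number of spots")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_spots(self, mask: np.ndarray) -> "SpatialDataset":
        """Return a copy restricted to ``mask`` (boolean over spots)."""
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        counts = self.counts[idx] if sp.issparse(self.counts) else np.asarray(self.counts)[idx]
        return SpatialDataset(
            spot_ids=[self.spot_ids[i] for i in idx],
            coords=self.coords[idx],
            counts=counts,
            gene_ids=list(self.gene_ids),
            tumor_flag=None if self.tumor_flag is None else self.tumor_flag[idx],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO BP, Hallmark) keyed by set name."""

    sets: dict
    source: Optional[str] = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str):
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# counts (MatrixMarket triplet + id files)
# ---------------------------------------------------------------------------

def read_counts(matrix_path, genes_path, barcodes_path):
    """Read a 10x-style MTX triplet plus gene/barcode id files.

    Orientation is detected from the id-file lengths, so both genes x spots
    (the 10x convention) and spots x genes matrices load identically; the
    returned matrix is always spots x genes (CSR, integer values preserved).

    Returns ``(counts, spot_ids, gene_ids)``.
    """
    mat = scipy.io.mmread(str(matrix_path))
    genes = _read_id_file(genes_path)
    barcodes = _read_id_file(barcodes_path)
    shape = mat.shape
    if shape == (len(genes), len(barcodes)) and shape != (len(barcodes), len(genes)):
        mat = mat.T
    elif shape == (len(barcodes), len(genes)):
        pass
    elif shape == (len(genes), len(barcodes)):
        # square and both readings agree in shape: 10x convention, genes first
        mat = mat.T
    else:
        raise ValueError(
            f"MTX shape {shape[0]}x{shape[1]} matches neither "
            f"{len(genes)} genes x {len(barcodes)} barcodes nor its transpose"
        )
    counts = sp.csr_matrix(mat)
    return counts, barcodes, genes


def write_counts(counts, spot_ids, gene_ids, matrix_path, genes_path, barcodes_path):
    """Write counts as genes x spots MTX (10x convention) plus id files."""
    counts = sp.coo_matrix(counts)
    scipy.io.mmwrite(str(matrix_path), counts.T)
    Path(genes_path).write_text("".join(f"{g}\n" for g in gene_ids))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in spot_ids))


def _read_id_file(path) -> list:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln.split("\t")[0] for ln in lines if ln]
    return ids


# ---------------------------------------------------------------------------
# spot positions
# ---------------------------------------------------------------------------

_VISIUM_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col",
    "pxl_row_in_fullres", "pxl_col_in_fullres",
]


def read_positions(path, dialect: str = "visium_positions") -> pd.DataFrame:
    """Read spot coordinates.

    dialect ``visium_positions``: 6-column tissue_positions CSV, headered or
    legacy headerless; only ``in_tissue == 1`` spots are kept and
    ``(x, y) = (pxl_col, pxl_row)``.  dialect ``generic_xy``: TSV with
    columns ``spot_id, x, y``.

    Returns a DataFrame indexed by spot_id with columns ``x`` and ``y``.
    """
    if dialect == "visium_positions":
        first = Path(path).open().readline()
        has_header = "barcode" in first.lower()
        df = pd.read_csv(path, header=0 if has_header else None)
        if df.shape[1] < 6:
            raise ValueError(f"visium positions file needs 6 columns, got {df.shape[1]}")
        df = df.iloc[:, :6]
        df.columns = _VISIUM_COLUMNS
        df = df[df["in_tissue"] == 1]
        out = pd.DataFrame(
            {
                "x": df["pxl_col_in_fullres"].astype(float).to_numpy(),
                "y": df["pxl_row_in_fullres"].astype(float).to_numpy(),
            },
            index=pd.Index(df["barcode"].astype(str), name="spot_id"),
        )
    elif dialect == "generic_xy":
        first = Path(path).open().readline().rstrip("\n").split("\t")
        has_header = not _is_number(first[1]) if len(first) > 1 else True
        df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
        df = df.iloc[:, :3]
        df.columns = ["spot_id", "x", "y"]
        out = df.set_index(df["spot_id"].astype(str))[["x", "y"]].astype(float)
        out.index.name = "spot_id"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if out.index.duplicated().any():
        dups = sorted(set(out.index[out.index.duplicated()]))
        raise ValueError(f"duplicate spot ids in positions file: {dups[:10]}")
    return out


def write_positions(coords: pd.DataFrame, path, dialect: str = "generic_xy") -> None:
    if dialect == "generic_xy":
        coords[["x", "y"]].to_csv(path, sep="\t", index=True, index_label="spot_id")
    elif dialect == "visium_positions":
        df = pd.DataFrame(
            {
                "barcode": coords.index,
                "in_tissue": 1,
                "array_row": 0,
                "array_col": 0,
                "pxl_row_in_fullres": coords["y"].to_numpy(),
                "pxl_col_in_fullres": coords["x"].to_numpy(),
            }
        )
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_tumor_labels(path) -> pd.Series:
    """Read a two-column TSV ``spot_id<TAB>tumor`` (0/1) -> boolean Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["spot_id", "tumor"],
                     skiprows=1 if _has_label_header(path) else 0)
    s = df.set_index(df["spot_id"].astype(str))["tumor"].astype(int).astype(bool)
    s.index.name = "spot_id"
    if s.index.duplicated().any():
        raise ValueError("duplicate spot ids in tumor label file")
    return s


def _has_label_header(path) -> bool:
    first = Path(path).open().readline().rstrip("\n").split("\t")
    return len(first) > 1 and not _is_number(first[1])


def write_tumor_labels(flags: pd.Series, path) -> None:
    pd.DataFrame({"spot_id": flags.index, "tumor": flags.astype(int).to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def load_spatial_dataset(matrix_path, genes_path, barcodes_path, positions_path,
                         positions_dialect: str = "visium_positions",
                         tumor_labels_path=None) -> SpatialDataset:
    """Assemble a SpatialDataset, joining counts to coordinates by spot id.

    Spots present in counts but missing coordinates are a hard error (the ids
    are listed); spots with coordinates but no counts are dropped silently,
    which is the normal situation for a tissue_positions file covering the
    whole capture area.
    """
    counts, spot_ids, gene_ids = read_counts(matrix_path, genes_path, barcodes_path)
    pos = read_positions(positions_path, dialect=positions_dialect)
    missing = [s for s in spot_ids if s not in pos.index]
    if missing:
        raise ValueError(
            f"{len(missing)} spots in counts lack coordinates: {missing[:10]}"
        )
    coords = pos.loc[spot_ids, ["x", "y"]].to_numpy(dtype=float)
    tumor = None
    if tumor_labels_path is not None:
        labels = read_tumor_labels(tumor_labels_path)
        missing = [s for s in spot_ids if s not in labels.index]
        if missing:
            raise ValueError(
                f"{len(missing)} spots lack tumor labels: {missing[:10]}"
            )
        tumor = labels.loc[spot_ids].to_numpy()
    return SpatialDataset(spot_ids=list(spot_ids), coords=coords, counts=counts,
                          gene_ids=list(gene_ids), tumor_flag=tumor)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, source: Optional[str] = None) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are de-duplicated keeping first occurrence;
    lines with fewer than three fields are skipped with a warning.
    """
    sets: dict = {}
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            skipped += 1
            continue
        name = fields[0]
        genes = list(dict.fromkeys(g for g in fields[2:] if g))
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = genes
    if skipped:
        warnings.warn(f"read_gmt: skipped {skipped} malformed line(s) (<3 fields)")
    return GeneSetCollection(sets=sets, source=source)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# gradient map tables
# ---------------------------------------------------------------------------

def write_gradient_table(gradient_map, path, passing_only: bool = False) -> None:
    """Serialize a GradientMap's fit table as TSV (fixed column order).

    One row per (grid point, program) fit; ``passing`` marks fits surviving
    the R-squared gate with their program retained.
    """
    df = gradient_map.fits.copy()
    df["passing"] = df["passing"].astype(int)
    if passing_only:
        df = df[df["passing"] == 1]
    df[GRADIENT_TABLE_COLUMNS].to_csv(path, sep="\t", index=False,
                                      float_format=FLOAT_FORMAT)


def read_gradient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["passing"] = df["passing"].astype(bool)
    return df


def write_arrow_field(gradient_map, path) -> None:
    """Write the arrow-field layer: passing fits only, one unit arrow per row.

    Columns: grid_id, x, y, program, dx, dy, r2 — the minimal content needed
    to draw the gradient arrows over the slide.
    """
    df = gradient_map.fits
    df = df[df["passing"]]
    df[["grid_id", "x", "y", "program", "dx", "dy", "r2"]].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def write_run_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
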