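"""Export the spatial count matrix to standard containers.

The MatrixMarket directory follows the 10x-style convention (genes as
rows, locations as columns, ``features.tsv``/``barcodes.tsv`` sidecars
plus ``positions.csv``) and is the interchange path to R ecosystems; the
h5ad file follows the AnnData convention (locations x genes, coordinates
in ``obsm['spatial']``).  All formats carry identical counts.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dedup import CountMatrix
from .locations import SpatialCounts, positions_frame

__all__ = ["write_mtx_dir", "read_mtx_dir", "write_h5ad", "read_h5ad", "export"]

POSITIONS_HEADER = (
    "# x_um increases rightward (column direction), "
    "y_um increases downward (row direction)\n"
)


def write_mtx_dir(sc: SpatialCounts, out_dir: str | Path) -> Path:
    """Write matrix.mtx (genes x locations, 1-based, column-major order),
    features.tsv, barcodes.tsv and positions.csv."""
    if sc.counts.matrix.nnz == 0 and sc.n_genes == 0:
        raise ValueError("refusing to export an empty matrix")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # CSC ordering gives the column-major entry order the format promises
    scipy.io.mmwrite(
        out_dir / "matrix.mtx", sp.csc_matrix(sc.counts.matrix), field="integer"
    )
    (out_dir / "features.tsv").write_text("".join(f"{g}\n" for g in sc.counts.genes))
    (out_dir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in sc.counts.barcodes))
    with open(out_dir / "positions.csv", "w") as fh:
        fh.write(POSITIONS_HEADER)
        positions_frame(sc).to_csv(fh, index=False)
    return out_dir


def read_mtx_dir(out_dir: str | Path) -> SpatialCounts:
    out_dir = Path(out_dir)
    matrix = sp.csr_matrix(scipy.io.mmread(out_dir / "matrix.mtx")).astype(np.int64)
    genes = (out_dir / "features.tsv").read_text().splitlines()
    barcodes = (out_dir / "barcodes.tsv").read_text().splitlines()
    pos = pd.read_csv(out_dir / "positions.csv", comment="#", dtype={"barcode": str})
    locations = pd.DataFrame(
        {
            "barcode": pos["barcode"],
            "x_um": pos["x_um"],
            "y_um": pos["y_um"],
            "array_row": pos["array_row"],
            "array_col": pos["array_col"],
            "qc_pass": pos["in_tissue"].astype(bool),
        }
    )
    return SpatialCounts(CountMatrix(matrix, genes, barcodes), locations)


def write_h5ad(sc: SpatialCounts, path: str | Path, metrics: dict | None = None) -> Path:
    """Write an AnnData file: locations x genes, spatial coordinates in
    ``obsm['spatial']``, qc_pass in ``obs``, metrics in ``uns``."""
    obs = sc.locations.set_index("barcode")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(
        X=sp.csr_matrix(sc.counts.matrix.T),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(sc.counts.genes, name="gene_id")),
    )
    adata.obsm["spatial"] = sc.locations[["x_um", "y_um"]].to_numpy()
    if metrics:
        adata.uns["stprep_metrics"] = metrics
    adata.write_h5ad(Path(path))
    return Path(path)


def read_h5ad(path: str | Path) -> SpatialCounts:
    adata = ad.read_h5ad(str(path))
    matrix = sp.csr_matrix(adata.X.T).astype(np.int64)
    locations = adata.obs.reset_index(names="barcode")
    locations["x_um"] = adata.obsm["spatial"][:, 0]
    locations["y_um"] = adata.obsm["spatial"][:, 1]
    return SpatialCounts(
        CountMatrix(matrix, list(adata.var_names), list(adata.obs_names)), locations
    )


def export(
    sc: SpatialCounts,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("mtx_dir", "h5ad"),
    metrics: dict | None = None,
) -> dict[str, Path]:
    """Write the selected formats under ``out_dir``; at least one required."""
    if not formats:
        raise ValueError("select at least one export format")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "mtx_dir":
            written[fmt] = write_mtx_dir(sc, out_dir / "mtx")
        elif fmt == "h5ad":
            written[fmt] = write_h5ad(sc, out_dir / "counts.h5ad", metrics=metrics)
        elif fmt == "csv":
            path = out_dir / "counts.csv"
            sc.counts.to_frame().to_csv(path)
            written[fmt] = path
        else:
            raise ValueError(f"unknown export format {fmt!r}")
    return written
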