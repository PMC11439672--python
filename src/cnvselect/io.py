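"""Readers and writers for the on-disk formats.

Single-cell counts travel as the 10x MatrixMarket triplet (``matrix.mtx`` in
genes x cells orientation plus ``features.tsv`` / ``barcodes.tsv``, plain or
gzipped), per-cell metadata and bulk cohorts as TSV, gene positions as the
header-less 4-column TSV dialect used by inferCNV, and gene sets as GMT.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .simulate import BulkCohort

__all__ = [
    "read_10x",
    "write_10x",
    "read_cell_meta",
    "write_cell_meta",
    "read_positions",
    "write_positions",
    "read_bulk",
    "write_bulk",
]

META_COLUMNS = ["sample", "group", "is_reference", "is_HT", "cell_type"]


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dirpath}")


def _read_tsv_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_10x(directory) -> ad.AnnData:
    """Read a 10x MTX triplet into an AnnData (cells x genes)."""
    directory = Path(directory)
    mtx = scipy.io.mmread(str(_find(directory, "matrix.mtx")))
    features = [line.split("\t")[0] for line in _read_tsv_lines(_find(directory, "features.tsv"))]
    barcodes = [line.split("\t")[0] for line in _read_tsv_lines(_find(directory, "barcodes.tsv"))]
    n_genes, n_cells = mtx.shape
    if n_genes != len(features) or n_cells != len(barcodes):
        raise ValueError(
            f"dimension mismatch: matrix is {n_genes} x {n_cells} but features.tsv has "
            f"{len(features)} rows and barcodes.tsv has {len(barcodes)} rows"
        )
    data = mtx.tocoo().data
    if data.size and not np.allclose(data, np.round(data)):
        raise ValueError("non-integer entries in matrix.mtx: counts must be integral")
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcodes.tsv")
    if len(set(features)) != len(features):
        raise ValueError("duplicate gene ids in features.tsv")
    X = sp.csr_matrix(mtx.T.astype(np.int64))
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
    )


def write_10x(adata: ad.AnnData, directory) -> None:
    """Write the genes x cells MTX triplet (plain text, integer field)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T).astype(np.int64)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in adata.var_names)
    )
    (directory / "barcodes.tsv").write_text("".join(f"{b}\n" for b in adata.obs_names))


def write_cell_meta(adata: ad.AnnData, path) -> None:
    cols = [c for c in META_COLUMNS if c in adata.obs]
    meta = adata.obs[cols].copy()
    meta.index.name = "barcode"
    meta.to_csv(path, sep="\t")


def read_cell_meta(path, adata: ad.AnnData | None = None) -> pd.DataFrame:
    """Read the metadata TSV; if ``adata`` is given, attach it to ``obs``."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("is_reference", "is_HT"):
        if col in meta:
            meta[col] = meta[col].astype(bool)
    if meta.index.duplicated().any():
        raise ValueError("duplicate barcodes in metadata")
    if adata is not None:
        missing = set(adata.obs_names) - set(meta.index)
        if missing:
            raise ValueError(
                f"{len(missing)} cells lack metadata rows, e.g. {sorted(missing)[:3]}"
            )
        for col in meta.columns:
            adata.obs[col] = meta.loc[adata.obs_names, col].to_numpy()
    return meta


def write_positions(positions: pd.DataFrame, path) -> None:
    positions[["gene_id", "chromosome", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_positions(path) -> pd.DataFrame:
    pos = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "chromosome", "start", "end"]
    )
    if pos["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in position table")
    if (pos["start"] > pos["end"]).any():
        raise ValueError("position table has start > end")
    return pos


def write_bulk(cohort: BulkCohort, path) -> None:
    out = cohort.values.copy()
    out.insert(0, "label", cohort.labels)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_bulk(path) -> BulkCohort:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "label" not in df.columns:
        raise ValueError("bulk TSV needs a 'label' column")
    labels = df.pop("label").astype(str)
    df = df.astype(float)
    df.index.name = None
    labels.index.name = None
    return BulkCohort(values=df, labels=labels)
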