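"""In-memory containers and disk I/O for spot-level spatial expression data.

The central container couples an ``N x M`` expression matrix with an ``N x 2``
coordinate table (platform units) and optional ground-truth domain labels.
Three on-disk layouts are supported:

* ``h5ad`` — AnnData with coordinates in ``obsm["spatial"]``;
* ``mtx_dir`` — a directory with ``matrix.mtx``, ``genes.tsv``,
  ``barcodes.tsv`` and ``coords.csv`` (columns ``barcode,x,y``);
* ``csv`` — a directory with dense ``expression.csv`` (spots x genes, spot ids
  as index), ``coords.csv`` (columns ``x,y``) and optional ``labels.csv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import AlignmentError, DataError, NoSpatialInformationError

__all__ = [
    "SpatialExpressionDataset",
    "FeatureMatrix",
    "load_dataset",
    "save_dataset",
]


def _make_unique(names: list[str]) -> list[str]:
    """Disambiguate duplicated identifiers by suffixing ``-1``, ``-2``, ..."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}-{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


@dataclass
class SpatialExpressionDataset:
    """Expression matrix, spatial coordinates and optional domain labels.

    Attributes
    ----------
    X
        ``N x M`` non-negative expression matrix. Raw counts on load;
        transformed in place by the preprocessing chain.
    S
        ``N x 2`` spatial coordinates.
    gene_names, spot_ids
        Row/column identifiers, kept aligned with ``X`` by every operation.
    labels
        Optional length-``N`` ground-truth domain labels.
    provenance
        Ordered record of preprocessing steps applied so far.
    X_lognorm
        Log-normalized matrix (post ``log1p``, pre per-gene scaling); filled by
        :func:`hyperspot.preprocess.normalize_log_scale` and consumed by the
        marker-gene test, which needs directional effects.
    """

    X: np.ndarray
    S: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]
    labels: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)
    X_lognorm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.X.ndim != 2 or self.S.ndim != 2 or self.S.shape[1] != 2:
            raise DataError("X must be 2-D and S must be N x 2")
        n, m = self.X.shape
        if n < 2 or m < 1:
            raise DataError(f"need at least 2 spots and 1 gene, got {n} x {m}")
        if self.S.shape[0] != n:
            raise AlignmentError(
                f"coordinate table has {self.S.shape[0]} rows but matrix has {n} spots"
            )
        if not np.all(np.isfinite(self.S)):
            raise NoSpatialInformationError("no spatial information: non-finite coordinates")
        if len(self.gene_names) != m:
            raise AlignmentError("gene_names length does not match matrix columns")
        if len(self.spot_ids) != n:
            raise AlignmentError("spot_ids length does not match matrix rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise AlignmentError("labels length does not match matrix rows")
        self.gene_names = _make_unique([str(g) for g in self.gene_names])
        self.spot_ids = [str(s) for s in self.spot_ids]

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def with_X(self, X: np.ndarray, step: str, **extra) -> "SpatialExpressionDataset":
        """Copy with a new matrix and one provenance entry appended."""
        return replace(
            self,
            X=X,
            provenance=self.provenance + [step],
            **extra,
        )


@dataclass
class FeatureMatrix:
    """Model-ready feature matrix: preprocessed expression, optionally PCA-reduced."""

    values: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature matrix contains non-finite entries")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _load_h5ad(path: Path, label_key: str | None) -> SpatialExpressionDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise NoSpatialInformationError(
            "no spatial information: obsm['spatial'] missing from h5ad"
        )
    X = adata.X
    if sparse.issparse(X):
        X = X.toarray()
    labels = None
    if label_key is not None:
        if label_key not in adata.obs:
            raise DataError(f"label column {label_key!r} not found in obs")
        labels = adata.obs[label_key].to_numpy()
    return SpatialExpressionDataset(
        X=np.asarray(X),
        S=np.asarray(adata.obsm["spatial"])[:, :2],
        gene_names=list(adata.var_names),
        spot_ids=list(adata.obs_names),
        labels=labels,
    )


def _load_mtx_dir(path: Path) -> SpatialExpressionDataset:
    for fname in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "coords.csv"):
        if not (path / fname).exists():
            raise DataError(f"mtx_dir is missing {fname}")
    X = spio.mmread(path / "matrix.mtx")
    if sparse.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    if X.shape == (len(genes), len(barcodes)) and X.shape[0] != X.shape[1]:
        X = X.T  # genes x barcodes orientation (CellRanger convention)
    if X.shape != (len(barcodes), len(genes)):
        raise AlignmentError(
            f"matrix shape {X.shape} inconsistent with {len(barcodes)} barcodes "
            f"x {len(genes)} genes"
        )
    coords = pd.read_csv(path / "coords.csv")
    if not {"x", "y"} <= set(coords.columns):
        raise NoSpatialInformationError("no spatial information: coords.csv lacks x,y columns")
    if len(coords) != len(barcodes):
        raise AlignmentError(
            f"coords.csv has {len(coords)} rows but matrix has {len(barcodes)} spots"
        )
    if "barcode" in coords.columns:
        coords = coords.set_index("barcode").loc[barcodes]
    return SpatialExpressionDataset(
        X=X,
        S=coords[["x", "y"]].to_numpy(),
        gene_names=genes,
        spot_ids=barcodes,
    )


def _load_csv_dir(path: Path) -> SpatialExpressionDataset:
    expr_path = path / "expression.csv"
    coords_path = path / "coords.csv"
    if not expr_path.exists():
        raise DataError(f"{expr_path} not found")
    if not coords_path.exists():
        raise NoSpatialInformationError("no spatial information: coords.csv not found")
    expr = pd.read_csv(expr_path, index_col=0, float_precision="round_trip")
    coords = pd.read_csv(coords_path, index_col=0, float_precision="round_trip")
    if not {"x", "y"} <= set(coords.columns):
        raise NoSpatialInformationError("no spatial information: coords.csv lacks x,y columns")
    if len(coords) != len(expr):
        raise AlignmentError(
            f"coords.csv has {len(coords)} rows but expression has {len(expr)} spots"
        )
    labels = None
    labels_path = path / "labels.csv"
    if labels_path.exists():
        lab = pd.read_csv(labels_path, index_col=0)
        if len(lab) != len(expr):
            raise AlignmentError("labels.csv row count does not match expression")
        labels = lab.iloc[:, 0].to_numpy()
    return SpatialExpressionDataset(
        X=expr.to_numpy(),
        S=coords[["x", "y"]].to_numpy(),
        gene_names=list(expr.columns),
        spot_ids=[str(i) for i in expr.index],
        labels=labels,
    )


def load_dataset(
    path: str | Path,
    format: str = "csv",
    label_key: str | None = None,
) -> SpatialExpressionDataset:
    """Read a dataset from disk.

    Parameters
    ----------
    path
        File (``h5ad``) or directory (``mtx_dir``, ``csv``) to read.
    format
        One of ``"h5ad"``, ``"mtx_dir"``, ``"csv"``.
    label_key
        For ``h5ad``: name of the ``obs`` column holding ground-truth labels.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input path {path} does not exist")
    if format == "h5ad":
        return _load_h5ad(path, label_key)
    if format == "mtx_dir":
        return _load_mtx_dir(path)
    if format == "csv":
        return _load_csv_dir(path)
    raise DataError(f"unknown format {format!r}")


def save_dataset(ds: SpatialExpressionDataset, path: str | Path, format: str = "csv") -> Path:
    """Write a dataset as a CSV bundle or h5ad; returns the path written."""
    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(ds.X, index=ds.spot_ids, columns=ds.gene_names).to_csv(
            path / "expression.csv"
        )
        pd.DataFrame(ds.S, index=ds.spot_ids, columns=["x", "y"]).to_csv(path / "coords.csv")
        if ds.labels is not None:
            pd.DataFrame({"label": ds.labels}, index=ds.spot_ids).to_csv(path / "labels.csv")
        (path / "provenance.json").write_text(json.dumps(ds.provenance))
        return path
    if format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(X=ds.X.copy())
        adata.obs_names = ds.spot_ids
        adata.var_names = ds.gene_names
        adata.obsm["spatial"] = ds.S.copy()
        if ds.labels is not None:
            adata.obs["domain"] = pd.Categorical([str(x) for x in ds.labels])
        adata.write_h5ad(path)
        return path
    raise DataError(f"unknown format {format!r}")
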