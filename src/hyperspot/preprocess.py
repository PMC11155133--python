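"""Preprocessing chain: gene filtering, normalization, log transform, scaling, PCA.

The fixed order is filter -> normalize -> log1p -> scale -> (optional PCA).
Each step records itself in the dataset's provenance; re-applying a step that
is already recorded raises, which guards against accidental double transforms.

Normalization divides each spot by its total so that row sums equal 1 (not the
1e4 target common elsewhere); log transform is ``log(1+x)``; scaling is per
gene to zero mean and unit variance, with zero-variance genes set to all-zeros
so column indices stay stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datasets import FeatureMatrix, SpatialExpressionDataset
from .exceptions import ConfigError, DataError, EmptyGeneSetError, EmptySpotError

__all__ = [
    "filter_genes",
    "normalize_log_scale",
    "reduce_pca",
    "preprocess",
    "save_features",
    "load_features",
]


def _guard(ds: SpatialExpressionDataset, step: str) -> None:
    if any(p.startswith(step) for p in ds.provenance):
        raise DataError(f"step {step!r} already applied (provenance: {ds.provenance})")


def filter_genes(ds: SpatialExpressionDataset, min_spots: int = 5) -> SpatialExpressionDataset:
    """Drop genes expressed (nonzero) in fewer than ``min_spots`` spots."""
    if min_spots < 1:
        raise ConfigError("min_spots must be >= 1")
    _guard(ds, "filter_genes")
    keep = (ds.X != 0).sum(axis=0) >= min_spots
    if not keep.any():
        raise EmptyGeneSetError(
            f"empty gene set: no gene is expressed in >= {min_spots} spots"
        )
    return ds.with_X(
        ds.X[:, keep],
        f"filter_genes(min_spots={min_spots})",
        gene_names=[g for g, k in zip(ds.gene_names, keep) if k],
    )


def normalize_log_scale(ds: SpatialExpressionDataset) -> SpatialExpressionDataset:
    """Total-count normalize each spot to 1, log1p, then scale each gene to
    zero mean / unit variance (population SD; zero-variance genes -> zeros).

    The intermediate log-normalized matrix is retained on the result
    (``X_lognorm``) for marker-gene testing, where per-gene scaling would
    destroy effect directionality.
    """
    _guard(ds, "normalize_log_scale")
    X = ds.X
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise DataError("raw counts must be finite and non-negative")
    totals = X.sum(axis=1)
    empty = totals == 0
    if empty.any():
        ids = [ds.spot_ids[i] for i in np.flatnonzero(empty)[:5]]
        raise EmptySpotError(f"empty spot(s) with zero total counts: {ids}; drop them first")
    X = X / totals[:, None]
    X = np.log1p(X)
    lognorm = X.copy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    X = X - mu
    nz = sd > 0
    X[:, nz] /= sd[nz]
    X[:, ~nz] = 0.0
    return ds.with_X(X, "normalize_log_scale", X_lognorm=lognorm)


def reduce_pca(
    ds: SpatialExpressionDataset,
    n_components: int = 200,
    seed: int = 0,
) -> FeatureMatrix:
    """Project the scaled matrix onto its top principal components.

    Skipped entirely (features returned unchanged) when the gene count is
    already at or below ``n_components`` — low-plex panels such as a 33-gene
    osmFISH run need no reduction. Component signs follow the convention that
    the largest-magnitude loading of each component is positive, so results
    are reproducible across runs.
    """
    if n_components < 1:
        raise ConfigError("n_components must be >= 1")
    if not any(p.startswith("normalize_log_scale") for p in ds.provenance):
        raise DataError("reduce_pca requires normalize_log_scale to have been applied")
    if ds.n_genes <= n_components:
        return FeatureMatrix(
            values=ds.X.copy(),
            provenance=ds.provenance + [f"pca(skipped: M={ds.n_genes} <= {n_components})"],
        )
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(ds.X)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip[None, :]
    return FeatureMatrix(
        values=scores,
        provenance=ds.provenance + [f"pca(n_components={n_components})"],
    )


def preprocess(
    ds: SpatialExpressionDataset,
    min_spots: int = 5,
    n_components: int = 200,
    seed: int = 0,
) -> tuple[SpatialExpressionDataset, FeatureMatrix]:
    """Full chain; returns the (log-normalized, scaled) dataset and features."""
    ds = filter_genes(ds, min_spots=min_spots)
    ds = normalize_log_scale(ds)
    feats = reduce_pca(ds, n_components=n_components, seed=seed)
    return ds, feats


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Persist features as a compressed array + provenance JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), values=fm.values)
    path.with_suffix(".json").write_text(json.dumps({"provenance": fm.provenance}))


def load_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    values = np.load(path.with_suffix(".npz"))["values"]
    prov = json.loads(path.with_suffix(".json").read_text())["provenance"]
    return FeatureMatrix(values=values, provenance=prov)
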