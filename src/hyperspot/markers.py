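"""Domain marker-gene ranking by one-vs-rest Welch t-tests.

Tests run on the log-normalized matrix *before* per-gene scaling: scaling to
zero mean / unit variance destroys the direction and magnitude of expression
differences that define a marker. Genes are ranked per cluster by ascending
p-value, ties broken by descending mean-difference effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import Partition
from .datasets import SpatialExpressionDataset
from .exceptions import DataError

__all__ = ["MarkerTable", "rank_marker_genes"]


@dataclass
class MarkerTable:
    """Ranked marker lists, one DataFrame (gene, p_value, effect, rank) per cluster."""

    per_cluster: dict[int, pd.DataFrame]

    def top(self, cluster: int, n: int = 1) -> list[str]:
        return self.per_cluster[cluster]["gene"].head(n).tolist()

    def top1(self) -> dict[int, str]:
        """Top-ranked gene per cluster, for spatial expression-heatmap export."""
        return {c: df["gene"].iloc[0] for c, df in self.per_cluster.items()}

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for c, df in self.per_cluster.items():
            d = df.copy()
            d.insert(0, "cluster", c)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


def rank_marker_genes(
    ds: SpatialExpressionDataset,
    P,
    top_n: int = 200,
) -> MarkerTable:
    """Welch t-test of each gene, cluster vs rest, on log-normalized values.

    Requires the dataset to have passed through normalization (``X_lognorm``
    filled). Clusters of size 1 are skipped with a warning. Effect size is the
    in-cluster minus out-of-cluster mean.
    """
    labels = P.assignments if isinstance(P, Partition) else np.asarray(P)
    if len(labels) != ds.n_spots:
        raise DataError("partition length does not match dataset")
    if ds.X_lognorm is None:
        raise DataError(
            "dataset has no log-normalized layer; run normalize_log_scale first"
        )
    X = ds.X_lognorm
    genes = np.asarray(ds.gene_names)
    out: dict[int, pd.DataFrame] = {}
    for c in np.unique(labels):
        mask = labels == c
        if mask.sum() < 2 or (~mask).sum() < 2:
            warnings.warn(f"cluster {c} has fewer than 2 spots; skipped", stacklevel=2)
            continue
        a, b = X[mask], X[~mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            _, pvals = stats.ttest_ind(a, b, axis=0, equal_var=False)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # zero-variance genes: no evidence
        effect = a.mean(axis=0) - b.mean(axis=0)
        order = np.lexsort((-effect, pvals))[:top_n]
        out[int(c)] = pd.DataFrame(
            {
                "gene": genes[order],
                "p_value": pvals[order],
                "effect": effect[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )
    return MarkerTable(per_cluster=out)
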