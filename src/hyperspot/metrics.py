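"""Clustering evaluation: ARI, NMI and a label-based Moran's index.

ARI is the pair-counting adjusted Rand index; NMI normalizes mutual
information by the geometric mean of the two label entropies. Both require
ground truth. The label Moran's index does not: on the spatial kNN graph
(k=20) it is the fraction of directed neighbor edges joining same-label
spots,

    I_label = sum_ij A_ij B_ij / sum_ij A_ij,   B_ij = 1[y_i = y_j],

which rewards spatially coherent segmentations and equals 1 when every
neighborhood is uniformly labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import Partition
from .exceptions import DataError
from .hypergraph import knn_graph

__all__ = ["MetricsReport", "ari", "nmi", "moran_label", "evaluate_partition"]


def _labels(p) -> np.ndarray:
    if isinstance(p, Partition):
        return p.assignments
    return np.asarray(p)


def _check_lengths(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) != len(b):
        raise DataError(f"partitions have different lengths: {len(a)} vs {len(b)}")


def ari(G, P) -> float:
    """Adjusted Rand index between two partitions (pair-counting form)."""
    from sklearn.metrics import adjusted_rand_score

    g, p = _labels(G), _labels(P)
    _check_lengths(g, p)
    return float(adjusted_rand_score(g, p))


def nmi(G, P) -> float:
    """Mutual information normalized by the geometric mean of entropies."""
    from sklearn.metrics import normalized_mutual_info_score

    g, p = _labels(G), _labels(P)
    _check_lengths(g, p)
    return float(normalized_mutual_info_score(g, p, average_method="geometric"))


def moran_label(P, S: np.ndarray, k: int = 20) -> float:
    """Fraction of spatial kNN edges whose endpoints share a label; in [0, 1]."""
    y = _labels(P)
    S = np.asarray(S, dtype=np.float64)
    if len(y) != S.shape[0]:
        raise DataError("labels and coordinates have different lengths")
    A = knn_graph(S, k=k).tocoo()
    same = y[A.row] == y[A.col]
    return float(same.sum() / A.nnz)


@dataclass
class MetricsReport:
    """Evaluation bundle; ARI/NMI are None when no ground truth is available."""

    moran_label: float
    ari: float | None = None
    nmi: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"moran_label": self.moran_label, "ari": self.ari, "nmi": self.nmi}
        out.update(self.metadata)
        return out


def evaluate_partition(
    P,
    S: np.ndarray,
    G=None,
    k: int = 20,
) -> MetricsReport:
    """Compute the label Moran's index and, when truth ``G`` is given, ARI/NMI."""
    report = MetricsReport(
        moran_label=moran_label(P, S, k=k),
        metadata={"moran_k": k},
    )
    if G is not None:
        report.ari = ari(G, P)
        report.nmi = nmi(G, P)
    return report
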