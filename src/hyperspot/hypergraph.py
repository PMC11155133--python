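"""Spatial hypergraph construction and its normalized operators.

Each spot spawns one hyperedge containing itself plus its k nearest spatial
neighbors (Euclidean), so the incidence matrix P is N x N with unit diagonal —
the self-inclusion keeps vertex degrees strictly positive and the spectrum
well-behaved. With hyperedge weights W_e (identity by default), vertex degrees
d(v) = sum_e w(e) p(v,e) and hyperedge degrees delta(e) = |e|, the normalized
adjacency is

    A_hp = D_v^{-1/2} P W_e D_e^{-1} P^T D_v^{-1/2}

and the normalized Laplacian is L_hp = I - A_hp. A_hp is symmetric positive
semidefinite with spectrum in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

from .exceptions import DegenerateVertexError, GraphError, TooFewSpotsError

__all__ = ["Hypergraph", "knn_graph", "incidence_from_knn", "normalized_adjacency", "build_hypergraph"]


def knn_graph(S: np.ndarray, k: int = 20, chunk: int = 2048) -> sparse.csr_matrix:
    """Binary N x N matrix marking each spot's k nearest distinct neighbors.

    Self is excluded; distance ties are broken by ascending spot index, so the
    result is fully deterministic (duplicated coordinates are allowed and pick
    each other at distance zero). Works in row chunks to bound memory.
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if k < 1:
        raise GraphError("k must be >= 1")
    if n <= k:
        raise TooFewSpotsError(f"too few spots for k: N={n} <= k={k}")
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=np.int64)
    sq = (S**2).sum(axis=1)
    idx = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (S[start:stop] @ S.T)
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf  # exclude self
        for i in range(stop - start):
            order = np.lexsort((idx, d2[i]))
            cols[(start + i) * k : (start + i + 1) * k] = order[:k]
    data = np.ones(n * k, dtype=np.float64)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


@dataclass
class Hypergraph:
    """Incidence structure plus cached normalized operators.

    ``P`` is |V| x |E|; here |E| = |V| because hyperedges are per-spot stars.
    ``W_e``, ``d_v`` and ``delta_e`` are the diagonal entries of the weight and
    degree matrices.
    """

    P: sparse.csr_matrix
    W_e: np.ndarray
    d_v: np.ndarray
    delta_e: np.ndarray
    k: int | None = None
    _A: sparse.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.P.shape[0]

    @property
    def n_hyperedges(self) -> int:
        return self.P.shape[1]


def incidence_from_knn(neighbors: sparse.spmatrix, include_self: bool = True) -> Hypergraph:
    """One hyperedge per spot: e_j = {j} U kNN(j); P[v, j] = 1 iff v in e_j."""
    nb = sparse.csr_matrix(neighbors, dtype=np.float64)
    if nb.shape[0] != nb.shape[1]:
        raise GraphError("neighbor matrix must be square")
    n = nb.shape[0]
    row_deg = np.asarray(nb.sum(axis=1)).ravel()
    if include_self:
        P = (nb + sparse.identity(n, format="csr")).T.tocsr()
    else:
        if np.any(row_deg == 0):
            raise GraphError("malformed input: empty neighbor row without self-inclusion")
        P = nb.T.tocsr()
    P.data[:] = 1.0
    W_e = np.ones(n)
    delta_e = np.asarray(P.sum(axis=0)).ravel()
    d_v = np.asarray(P.multiply(W_e[None, :]).sum(axis=1)).ravel()
    k = int(row_deg[0]) if np.all(row_deg == row_deg[0]) else None
    return Hypergraph(P=P, W_e=W_e, d_v=d_v, delta_e=delta_e, k=k)


def normalized_adjacency(hg: Hypergraph) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """Return (A_hp, L_hp) as sparse matrices."""
    if np.any(hg.d_v <= 0):
        raise DegenerateVertexError("degenerate vertex degree: isolated vertex with d(v)=0")
    if np.any(hg.delta_e <= 0):
        raise GraphError("hyperedge with zero degree")
    dv_isqrt = sparse.diags(1.0 / np.sqrt(hg.d_v))
    we_over_de = sparse.diags(hg.W_e / hg.delta_e)
    half = dv_isqrt @ hg.P  # D_v^{-1/2} P
    A = (half @ we_over_de @ half.T).tocsr()
    L = (sparse.identity(hg.n_vertices, format="csr") - A).tocsr()
    hg._A = A
    return A, L


def build_hypergraph(S: np.ndarray, k: int = 20) -> tuple[Hypergraph, sparse.csr_matrix]:
    """Convenience: coordinates -> kNN -> hypergraph -> normalized adjacency."""
    hg = incidence_from_knn(knn_graph(S, k=k))
    A, _ = normalized_adjacency(hg)
    return hg, A


def export_hypergraph(hg: Hypergraph, path: str | Path) -> None:
    """Write the incidence matrix as MTX plus a JSON sidecar of metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(path / "incidence.mtx", hg.P)
    (path / "hypergraph.json").write_text(
        json.dumps(
            {
                "k": hg.k,
                "hyperedge_weights": hg.W_e.tolist(),
                "vertex_degrees": hg.d_v.tolist(),
                "hyperedge_degrees": hg.delta_e.tolist(),
            }
        )
    )
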