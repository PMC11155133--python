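"""Build the spatial hypergraph for random coordinates and inspect its operators.

Each spot spawns a hyperedge containing itself and its k nearest neighbors;
the normalized adjacency A_hp = D_v^{-1/2} P W_e D_e^{-1} P^T D_v^{-1/2} is
symmetric with spectrum in [0, 1], and L_hp = I - A_hp is the corresponding
Laplacian. These bounds are what keep repeated hypergraph convolutions
numerically stable.
"""

import numpy as np

from hyperspot import incidence_from_knn, knn_graph, normalized_adjacency

rng = np.random.default_rng(0)
S = rng.uniform(size=(300, 2))

hg = incidence_from_knn(knn_graph(S, k=20))
A, L = normalized_adjacency(hg)

eigenvalues = np.linalg.eigvalsh(A.toarray())
print(f"vertices={hg.n_vertices}, hyperedges={hg.n_hyperedges} (one per spot)")
print(f"hyperedge size delta(e): all equal to {int(hg.delta_e[0])} (spot + k neighbors)")
print(f"A_hp symmetric: {np.allclose(A.toarray(), A.toarray().T)}")
print(f"spectrum of A_hp in [{eigenvalues.min():.3e}, {eigenvalues.max():.6f}] (expected [0, 1])")
print(f"L_hp = I - A_hp: {np.allclose(L.toarray(), np.eye(300) - A.toarray())}")
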