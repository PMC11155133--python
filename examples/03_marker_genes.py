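"""Rank domain markers with one-vs-rest Welch t-tests on a simulated tissue.

Uses the known domain labels directly (no training) to show the marker-ranking
machinery in isolation: each domain's planted markers should occupy the top
ranks, with p-values reflecting the +3 SD mean shift.
"""

from hyperspot import SyntheticSpec, filter_genes, generate, normalize_log_scale, rank_marker_genes

ds = generate(SyntheticSpec(n_spots=400, n_genes=100, seed=3))
ds = normalize_log_scale(filter_genes(ds, min_spots=1))

table = rank_marker_genes(ds, ds.labels, top_n=5)
for domain, frame in table.per_cluster.items():
    top = frame.iloc[0]
    print(
        f"domain {domain}: top marker {top.gene:16s} "
        f"p={top.p_value:.2e} effect={top.effect:+.4f} (log-normalized mean diff)"
    )
print("\nA planted marker (marker_d<domain>_*) ranking first for its own domain "
      "confirms the test recovers the simulated ground truth.")
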