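"""Build a UPGMA tree over synthetic RNA families and check recovery.

Four planted families (20 members each, length 60, 5% per-site divergence
from each family ancestor) are generated, all pairwise structural distances
computed, and the UPGMA tree cut into four clusters. The adjusted Rand
index compares the cut against the planted labels (1.0 = perfect).
"""

from sklearn.metrics import adjusted_rand_score

from tvcurve import (
    NussinovBackend,
    generate_families,
    pairwise_distance_matrix,
    planted_family_labels,
    to_newick,
    upgma,
)

backend = NussinovBackend()
records = generate_families(n_families=4, members=20, length=60,
                            mutation_rate=0.05, seed=1, backend=backend)
truth = planted_family_labels(records)

matrix = pairwise_distance_matrix(records, backend)
tree = upgma(matrix)
assignment = tree.cut(4)
predicted = [assignment[r.id] for r in records]

print(f"records           : {len(records)} ({len(set(truth))} planted families)")
print(f"distance range    : {matrix.values.max():.4f} max off-diagonal")
print(f"root merge height : {tree.root.height:.4f}")
print(f"adjusted Rand     : {adjusted_rand_score(truth, predicted):.3f}")
print("newick (truncated):", to_newick(tree)[:90], "...")
# ARI 1.0 means every member joined the branch of its own family — the
# structural distance separates the planted families completely.
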