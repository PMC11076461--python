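"""Spanning-tree topology metrics on the two extreme network shapes.

Builds connectivity matrices whose strongest edges form a star and a path,
extracts the maximum spanning tree from each, and prints the metric set.
"""

import numpy as np

from eegmst import (
    ConnectivityMatrix,
    RegionSpec,
    build_mst,
    mst_metrics_tree,
)

n = 10
labels = tuple(f"CH{i:02d}" for i in range(n))
region = RegionSpec(anterior=frozenset(labels[:5]), posterior=frozenset(labels[5:]))


def matrix_with_backbone(edges):
    v = np.full((n, n), 0.1)
    np.fill_diagonal(v, 0.0)
    for a, b in edges:
        v[a, b] = v[b, a] = 0.9
    return ConnectivityMatrix("AEC-c", None, v, labels)


star = matrix_with_backbone([(0, i) for i in range(1, n)])
path = matrix_with_backbone([(i, i + 1) for i in range(n - 1)])

print(f"{'metric':<18}{'star':>8}{'path':>8}")
for name in ("diameter", "leaf_fraction", "max_degree_norm", "max_bc",
             "mean_bc_global", "assortativity"):
    row = []
    for m in (star, path):
        ms = mst_metrics_tree(build_mst(m), region)
        row.append(getattr(ms, name))
    print(f"{name:<18}{row[0]:>8.3f}{row[1]:>8.3f}")

print("\nThe star (one hub) minimizes diameter and maximizes leaf fraction, "
      "max degree and betweenness; the chain is the opposite extreme. Real "
      "functional networks sit between these bounds, and shifts toward the "
      "star pole indicate a more centralized topology.")
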