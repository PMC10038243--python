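"""Independent brute-force oracles used by unit and acceptance tests."""

from itertools import combinations

import numpy as np


def brute_average_linkage_retain(vectors: np.ndarray, ids, n_clusters: int):
    """Reference deduplication: naive average-linkage agglomeration.

    Starts from singletons and repeatedly merges the pair of clusters with the
    smallest average pairwise euclidean distance until ``n_clusters`` remain;
    from each cluster the member nearest the cluster mean is retained (ties by
    smallest id).  O(n^4) — only for small instances.
    """
    ids = list(ids)
    clusters = [[i] for i in range(len(ids))]

    def avg(a, b):
        return float(
            np.mean([np.linalg.norm(vectors[i] - vectors[j]) for i in a for j in b])
        )

    while len(clusters) > n_clusters:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = avg(clusters[a], clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]

    retained = []
    for cl in clusters:
        centre = vectors[cl].mean(axis=0)
        dists = np.linalg.norm(vectors[cl] - centre, axis=1)
        best = min(zip(dists, (ids[i] for i in cl)), key=lambda t: (t[0], t[1]))
        retained.append(best[1])
    return sorted(retained)
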