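"""Decision-boundary diagnostics: is a second dataset domain-shifted?

Trains a linear probe on one synthetic embedding set and compares the signed
distances of both datasets to the probe's six pairwise class boundaries: a
shifted dataset sits closer to the boundaries and crosses them more often.
"""

import numpy as np

from xtalcurate.diagnostics import (
    boundary_distances,
    domain_shift_summary,
    project_2d,
    train_linear_probe,
)
from xtalcurate.embedding import EmbeddingSet
from xtalcurate.manifest import CLASS_LABELS
from xtalcurate.synthetic import EmbeddingSynthConfig, generate_embeddings

e, labels, _ = generate_embeddings(
    EmbeddingSynthConfig(n_per_class=150, dim=8, class_separation=5.0, seed=3)
)
probe = train_linear_probe(e, labels, seed=0)
report_train = boundary_distances(probe, e, labels)

# a deliberately shifted copy: class centres pulled 60% toward the global mean
shifted = e.vectors.copy()
global_mean = e.vectors.mean(axis=0)
for c in range(4):
    mask = labels == c
    shifted[mask] -= 0.6 * (e.vectors[mask].mean(axis=0) - global_mean)
e_shift = EmbeddingSet(vectors=shifted,
                       record_ids=[f"s{i}" for i in range(e.n)],
                       provider_name="shifted")
report_shift = boundary_distances(probe, e_shift, labels)

print("pair              mean|d| train  mean|d| shifted  crossing train/shifted")
for (i, j), s in domain_shift_summary(report_train, report_shift).items():
    pair = f"{CLASS_LABELS[i]}-{CLASS_LABELS[j]}"
    print(f"{pair:<18}{s['mean_abs_a']:>12.3f}{s['mean_abs_b']:>16.3f}"
          f"{s['crossing_a']:>12.3f} / {s['crossing_b']:.3f}")

xy = project_2d(e, method="pca-like")
print(f"\n2-D projection computed for {len(xy)} points "
      f"(x range {xy[:, 0].min():.1f}..{xy[:, 0].max():.1f})")
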