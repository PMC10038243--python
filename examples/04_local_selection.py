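"""Select local images to supplement a training set.

Two strategies: match a target class distribution with a random per-class
sample, or pick the images a reference model finds hardest (highest
prediction entropy).
"""

import numpy as np

from xtalcurate.curation import (
    ProbabilityTable,
    SelectionRequest,
    entropy_score,
    select_local,
)
from xtalcurate.manifest import CLASS_LABELS, DatasetManifest, ImageRecord, get_preset

rng = np.random.default_rng(0)
records = [
    ImageRecord(f"{c}{i:03d}", "x.png", c, "local-lab", f"w{c}{i:03d}", 0)
    for c in CLASS_LABELS
    for i in range(200)
]
pool = DatasetManifest(records=records, root=".")

req = SelectionRequest(n_total=240, mode="match_distribution",
                       target_dist=get_preset("marco"))
picked = select_local(pool, req, seed=0)
counts = {c: sum(pool.by_id(r).label == c for r in picked) for c in CLASS_LABELS}
print(f"distribution-matched selection of {len(picked)}: {counts}")

probs = ProbabilityTable(record_ids=pool.record_ids,
                         probs=rng.dirichlet(np.ones(4), size=len(pool)))
hard = select_local(pool, SelectionRequest(n_total=5, mode="hardest"),
                    probs=probs, seed=0)
print("five hardest images by prediction entropy:")
for rid in hard:
    print(f"  {rid}: entropy {entropy_score(probs.row(rid)):.4f} nats")
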