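"""Screen a collection for a minority contaminant image type.

Generates a dataset where 15% of wells contain an LCP-like bolus instead of
an aqueous drop, trains a binary screen from a labelled subset, and scans the
remainder of the pool.
"""

import tempfile

import numpy as np

from xtalcurate.diagnostics import screen_binary
from xtalcurate.embedding import baseline_embed
from xtalcurate.manifest import get_preset
from xtalcurate.synthetic import SynthConfig, generate_dataset

with tempfile.TemporaryDirectory() as out:
    cfg = SynthConfig(n_images=300, class_dist=get_preset("uniform"),
                      contaminant_fraction=0.15, seed=12)
    m = generate_dataset(cfg, out)
    e = baseline_embed(m)

    contaminants = (f"{out}/contaminants.txt",)
    with open(contaminants[0]) as fh:
        all_pos = fh.read().split()
    clean = [r.record_id for r in m if r.record_id not in set(all_pos)]

    # label half of each group, scan the rest of the pool
    pos, neg = all_pos[::2], clean[: len(all_pos)]
    flagged, held_out = screen_binary(m, e, pos, neg, threshold=0.5, seed=0)

    truth = set(all_pos)
    hits = sum(rid in truth for rid in flagged)
    acc = np.trace(held_out.counts) / held_out.counts.sum()
    print(f"held-out screen accuracy: {acc:.3f}")
    print(f"flagged {len(flagged)} images; {hits} are true contaminants "
          f"of {len(truth) - len(pos)} hidden in the scanned pool")
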