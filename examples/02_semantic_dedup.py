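"""Semantic deduplication: remove redundant near-duplicate inspections.

Embeds a generated dataset with the baseline embedder, then deduplicates to a
quarter of its size — the retain fraction matching the 4-image timecourses —
and shows that exactly one image per well survives.  Finally runs a small
redundancy curve: probe accuracy as a function of the retained fraction.
"""

import tempfile

from xtalcurate.dedup import build_dedup_plan, redundancy_curve
from xtalcurate.embedding import baseline_embed
from xtalcurate.manifest import get_preset
from xtalcurate.synthetic import SynthConfig, generate_dataset

with tempfile.TemporaryDirectory() as train_dir, \
        tempfile.TemporaryDirectory() as eval_dir:
    uniform = get_preset("uniform")
    m = generate_dataset(
        SynthConfig(n_images=400, class_dist=uniform, duplicate_group_size=4,
                    duplicate_jitter=0.01, seed=7),
        train_dir,
    )
    m_eval = generate_dataset(
        SynthConfig(n_images=200, class_dist=uniform, seed=99), eval_dir
    )
    e = baseline_embed(m)
    e_eval = baseline_embed(m_eval, stats=e.stats)

    plan = build_dedup_plan(m, e, retain_fraction=0.25, seed=7)
    kept_wells = [m.by_id(rid).well_id for rid in plan.retained_ids]
    print(f"retained {len(plan.retained_ids)} of {len(m)} images")
    print(f"unique wells among retained: {len(set(kept_wells))} "
          f"(one per well = {len({r.well_id for r in m})})")

    curve = redundancy_curve(
        m, e, [("eval", m_eval, e_eval)], fractions=[1.0, 0.5, 0.25],
        replicates=2, seed=0,
    )
    for f, acc, sd in zip(curve.fractions, curve.accuracies["eval"],
                          curve.replicate_sd["eval"]):
        print(f"  fraction {f:4.2f}: accuracy {acc:.3f} (sd {sd:.3f})")
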