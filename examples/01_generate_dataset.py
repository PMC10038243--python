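"""Generate a synthetic droplet-image dataset and inspect its composition.

Each image is a styled microscope-like view of one crystallisation drop; a
"well" is a timecourse of near-duplicate inspections of the same drop.
"""

import tempfile

from xtalcurate.manifest import CLASS_LABELS, class_distribution, get_preset
from xtalcurate.synthetic import SynthConfig, generate_dataset

with tempfile.TemporaryDirectory() as out:
    cfg = SynthConfig(
        n_images=200,
        class_dist=get_preset("marco"),
        duplicate_group_size=4,   # 4 inspections per well
        duplicate_jitter=0.01,    # small re-imaging translation/brightness shift
        contaminant_fraction=0.05,
        seed=0,
    )
    manifest = generate_dataset(cfg, out)

    print(f"generated {len(manifest)} images under {out}")
    dist = class_distribution(manifest)
    for cls, p in zip(CLASS_LABELS, dist.as_array()):
        print(f"  {cls:<12} {p:.3f}")
    wells = {r.well_id for r in manifest}
    contam = [r.record_id for r in manifest if r.source.endswith("+lcp")]
    print(f"wells: {len(wells)}, contaminant images: {len(contam)}")
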