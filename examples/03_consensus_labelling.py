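"""Two-round consensus labelling of a multi-annotator image set.

Two annotators score every image; agreement fixes the label, disagreement
sends the image to a third annotator, and a three-way disagreement excludes
the image as ambiguous.
"""

from xtalcurate.curation import AnnotationSet, build_consensus_manifest
from xtalcurate.manifest import DatasetManifest, ImageRecord

records = [ImageRecord(f"img{i}", f"img{i}.png", None, "lab", f"w{i}", 0)
           for i in range(4)]
manifest = DatasetManifest(records=records, root=".")

ann = AnnotationSet()
# img0: both agree -> crystal
ann.add("img0", "alice", "crystal")
ann.add("img0", "bob", "crystal")
# img1: disagreement resolved by a third score -> precipitate
ann.add("img1", "alice", "precipitate")
ann.add("img1", "bob", "clear")
ann.add("img1", "carol", "precipitate")
# img2: three distinct labels -> ambiguous, excluded
ann.add("img2", "alice", "clear")
ann.add("img2", "bob", "crystal")
ann.add("img2", "carol", "other")
# img3: both agree -> clear
ann.add("img3", "alice", "clear")
ann.add("img3", "bob", "clear")

kept, excluded = build_consensus_manifest(manifest, ann)
for rec in kept:
    print(f"{rec.record_id}: {rec.label}")
print(f"excluded as ambiguous: {excluded}")
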