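# Methods

This note records the scientific model implemented by `xtalcurate`, the
defaults, and the reasoning behind the numerical choices.

## Vocabulary and data model

Crystallisation outcomes use a fixed four-class vocabulary in canonical
(alphabetical) order: **clear, crystal, precipitate, other**. All probability
vectors, confusion matrices and count arrays follow this order. A *well* is
one crystallisation experiment; its *timecourse* is the sequence of
inspection images taken of it over time, which are near-duplicates of each
other. Manifests are UTF-8 CSV files with header
`record_id,image_path,label,source,well_id,timepoint`; an empty label cell
means "unlabelled".

Class-distribution presets (fractions of clear/crystal/precipitate/other):

| preset  | clear | crystal | precipitate | other |
|---------|-------|---------|-------------|-------|
| marco   | 0.336 | 0.128   | 0.480       | 0.056 |
| cinder  | 0.270 | 0.110   | 0.500       | 0.120 |
| c3      | 0.235 | 0.283   | 0.400       | 0.082 |
| uniform | 0.25  | 0.25    | 0.25        | 0.25  |

The `c3` preset's published class percentages sum to 99.9%; the missing 0.1%
is folded into `other` so the distribution is a valid probability vector.

## Baseline embedding

`baseline_embed` is a deterministic, CPU-only stand-in for a deep network's
penultimate-layer features. Per image (converted to luminance in [0, 1]):

1. an 8×8 mean-pooled intensity grid (64 dims; coarse spatial layout),
2. a 32-bin intensity histogram over [0, 1] (tonal content),
3. a 16-bin gradient-magnitude histogram over [0, 0.5] (texture/edge energy),

concatenated to d = 112. **Each block is standardised to zero mean and unit
variance across the embedded set using one scalar mean/sd per block**, not
per column: the extreme histogram bins are nearly empty in any natural
collection, and per-column standardisation would divide them by a near-zero
standard deviation, amplifying one-pixel fluctuations into dominant
distances. Block-level statistics keep every feature on a comparable scale
while preserving the relative structure within a block.

Standardisation statistics are stored with the embedding and can be reapplied
to new images (`baseline_embed(manifest, stats=...)`), making the train/apply
asymmetry explicit. Embeddings are *not* L2-normalised before clustering;
whether normalisation helps is representation-dependent and left to the
provider. Any external embedder is accepted downstream as long as it yields a
finite `n × d` matrix aligned to record ids.

## Semantic deduplication

Two images are treated as semantic duplicates when they are close in
embedding space under euclidean distance. Deduplication to retain fraction
`f` on `n` images:

1. **Cluster count.** `num_clusters(f, n) = round(f·n)` (half away from
   zero, minimum 1) — the number of clusters equals the number of images to
   retain, e.g. removing 10% of 100 images forms 90 clusters.
2. **Pseudo-classes.** Each true class of `m` members is partitioned by
   k-means into `max(1, ceil(m / 10000))` pseudo-classes (target size 10 000,
   configurable), keeping the O(m²) hierarchical step tractable.
3. **Budget allocation.** The cluster budget is apportioned over
   pseudo-classes proportionally to their sizes by the largest-remainder
   rule, minimum one each (and never more clusters than members), so the
   global retained count is exact.
4. **Agglomeration and retention.** Within each pseudo-class,
   average-linkage agglomerative clustering on euclidean distance is cut at
   the allocated cluster count; from each cluster the member nearest the
   cluster mean survives, ties broken by lexicographically smallest
   record_id (determinism across platforms).

Average linkage was chosen as a middle ground between single linkage (prone
to chaining) and complete linkage (prone to fragmenting compact duplicate
groups). The implementation is verified against a brute-force agglomeration
oracle on small instances.

`redundancy_curve` re-runs the full procedure *from scratch* at each fraction
of a strictly decreasing ladder (no nesting of subsets), trains the linear
probe on the retained records, and reports held-out accuracy mean ± sd over
replicate seeds. A fraction whose retained set covers fewer than all four
classes is skipped with a warning.

## Consensus labelling and timecourse uniqueness

The two-round protocol: a record with two agreeing annotations gets that
label; two disagreeing annotations require a third; with three annotations
any label held by at least two wins, and three distinct labels exclude the
record as ambiguous. Exactly 40 of the 4³ = 64 ordered label triples yield a
label. A two-annotation disagreement with no third score is a protocol
violation, not a silent exclusion.

`one_per_timecourse` keeps one image per well: the default rule is `last`
(the final inspection carries the most outcome information), with `first` and
seeded `random` alternatives.

## Local selection and hardness

`allocate_counts` apportions `n` images over the four classes by largest
remainder: counts always sum to `n` and each is within 1 of its real-valued
quota. `select_local` draws per-class random samples realising those counts
(`match_distribution`, `uniform`), or takes the top-n by prediction entropy
(`hardest`; `hardest_stratified` constrains the class composition). Hardness
scores use natural logarithms (nats): entropy `−Σ p ln p` with `0·ln 0 = 0`,
and cross-entropy `−ln p_true` with `p_true` floored at 1e-12 so confident
mistakes get large but finite scores. The log base only rescales rankings,
so selection is unaffected by the choice.

## Linear probe and boundary diagnostics

The probe is multinomial logistic regression with L2 penalty (default
`l2 = 1e-4`), trained by deterministic full-batch gradient descent for up to
3000 epochs with early stopping at an objective change below 1e-10. The step
size is `1 / (0.5·λ_max(XᵀX)/n + l2)` — the curvature bound of the softmax
loss — which makes the training loss monotonically decreasing without tuning.
Weights start from a small seed-derived Gaussian, so replicate seeds give
slightly different but individually bit-reproducible solutions.

For classes i and j the signed distance of sample x to their pairwise linear
boundary is

```
d(x) = ((w_i − w_j)·x + (b_i − b_j)) / ‖w_i − w_j‖
```

positive when the pairwise score favours class i. For a linear head this is
exact; for deep heads it is a first-order surrogate, and it is computed in
representation (embedding) space. On the probe's own training data the
boundary-crossing fraction of a pair equals its pairwise misclassification
rate. Datasets that sit systematically closer to the boundaries, or cross
them more often, than the training data are domain-shifted;
`domain_shift_summary` reports per-pair mean |d| and crossing fractions for
two datasets under the same probe.

`project_2d` provides UMAP (seeded) or a deterministic variance-maximising
linear projection for visual inspection; `screen_binary` trains a two-class
probe from ≥ 20 labelled positives/negatives (80/20 seeded split), reports
the held-out confusion matrix, and flags pool records at a configurable
probability threshold (default 0.5).

## Synthetic data

The image generator draws geometric caricatures, not photorealistic drops:
the curation algorithms need separable, controllable structure, and
caricatures keep everything desk-scale. Class signatures inside a circular
drop on a styled background: *clear* = drop only; *crystal* = 1–5 bright
elongated polygons (the first always sizeable); *precipitate* = granular
darkening plus coarse blotches; *other* = ring and dark blob; contaminants
are a large bolus filling >60% of the drop with internal swirls, tagged
`+lcp` in the source column and listed in a `contaminants.txt` sidecar.

Three imaging styles (background level, vignette strength, noise level)
model source variation. Every well additionally gets an appearance
fingerprint — background offset, illumination ramp, coarse plate mottle,
contrast factor, radial drop shading — drawn once per well. This implements
the generator's core contract: re-imaging jitter within a timecourse
(translation ≤ jitter·image size, brightness ± jitter) moves an image far
less in embedding space than the distance between any two wells. Rendering
is anti-aliased (soft ~1-pixel coverage masks) so sub-pixel translations
change pixels smoothly rather than flipping them; textures are biased away
from single-grey-level regions so histogram features degrade gracefully under
small brightness shifts.

Determinism: every well and image derives its own random stream by hashing
the global seed with a stable string key, so generation is a pure function of
(config, seed) and inserting records never re-randomises existing ones. The
per-well noise field is shared across the timecourse — re-imaging the same
drop does not resample the sensor pattern — which both matches the
near-duplicate semantics and keeps within-well distances small. Class counts
follow the largest-remainder rule exactly; when a class count is not
divisible by the timecourse length the final timecourse of that class is
truncated (exact class counts take precedence over uniform well sizes).

The embedding generator draws isotropic Gaussian clusters at class centre +
source offset, with mutual class separation and mutual source separation set
independently — the knob for emulating collections where imaging origin
dominates semantic content (with source separation ≫ class separation, a
clustering of the vectors agrees with sources, not classes).

## What the generator does not model

No photorealism, optical simulation, UV channels, plate-edge artefacts
beyond vignette, annotator error models, or database backends. The toolkit
reimplements curation *procedures*; reproducing published deep-network
accuracies on real collections is out of scope.
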