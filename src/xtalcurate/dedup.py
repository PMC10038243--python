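"""Semantic-redundancy estimation and removal.

Two inspection images are *semantic duplicates* when they contribute
essentially the same information to a classifier — operationalised as
proximity in an embedding space under euclidean distance.  Deduplication to a
retain fraction f proceeds in three steps:

1. each true class is partitioned into *pseudo-classes* of roughly
   ``pseudo_class_target`` members by k-means, keeping hierarchical
   clustering tractable on large collections;
2. within each pseudo-class, agglomerative clustering (average linkage on
   euclidean distance) is cut at the number of images to be retained there;
3. from every cluster the member closest to the cluster mean is retained and
   all others are dropped.

The number of clusters formed equals the number of images to be retained: to
remove 10% of a 100-image set, 90 clusters are formed.  The cluster budget is
spread over pseudo-classes proportionally to their sizes (largest remainder,
minimum one each).

:func:`redundancy_curve` re-runs the whole procedure at a decreasing ladder
of retain fractions, trains a classifier probe on each reduced set and
reports accuracy on held-out evaluation sets — the harness for estimating
how much of a collection is redundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, floor
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from xtalcurate.apportion import largest_remainder
from xtalcurate.embedding import EmbeddingSet
from xtalcurate.manifest import DatasetManifest, labels_array


@dataclass
class DedupPlan:
    """Outcome of planning a deduplication pass."""

    retain_fraction: float
    pseudo_class_target: int
    #: record_id -> (true class label, pseudo-class index within that class)
    pseudo_assignments: dict[str, tuple[str, int]]
    #: (class label, pseudo index) -> number of clusters formed there
    clusters_per_pseudo: dict[tuple[str, int], int]
    retained_ids: list[str] = field(default_factory=list)


def num_clusters(retain_fraction: float, n: int) -> int:
    """Number of agglomerative clusters for a retain fraction on n images.

    Equals the number of images to be retained: round(retain_fraction * n)
    with half rounded away from zero, and at least 1.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError(f"retain fraction must lie in (0, 1], got {retain_fraction}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(1, int(floor(retain_fraction * n + 0.5)))


def make_pseudo_classes(
    e: EmbeddingSet,
    labels: Sequence[str],
    target_size: int = 10_000,
    seed: int = 0,
) -> dict[str, tuple[str, int]]:
    """Partition each true class into pseudo-classes of ~``target_size`` members.

    A class of m members gets k = max(1, ceil(m / target_size)) k-means
    partitions computed in embedding space.  Returns record_id ->
    (class, pseudo index); assignment is deterministic given the seed.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    labels = list(labels)
    if len(labels) != e.n:
        raise ValueError("labels must align with embedding rows")
    assignments: dict[str, tuple[str, int]] = {}
    for cls in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        m = len(idx)
        k = max(1, ceil(m / target_size))
        if k == 1:
            for i in idx:
                assignments[e.record_ids[i]] = (cls, 0)
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        part = km.fit_predict(e.vectors[idx])
        for i, p in zip(idx, part):
            assignments[e.record_ids[i]] = (cls, int(p))
    return assignments


def _retain_from_clusters(
    vectors: np.ndarray, ids: Sequence[str], cluster_of: np.ndarray
) -> list[str]:
    """Per cluster, keep the member nearest the cluster mean (ties: smallest id)."""
    retained = []
    for c in np.unique(cluster_of):
        members = np.flatnonzero(cluster_of == c)
        centre = vectors[members].mean(axis=0)
        dists = np.linalg.norm(vectors[members] - centre, axis=1)
        best = min(zip(dists, (ids[i] for i in members)), key=lambda t: (t[0], t[1]))
        retained.append(best[1])
    return sorted(retained)


def dedup_within(e: EmbeddingSet, ids: Sequence[str], n_clusters: int) -> list[str]:
    """Deduplicate one pseudo-class: agglomerative clustering, keep one per cluster.

    Average-linkage agglomerative clustering on euclidean distance is cut at
    ``n_clusters``; from each cluster the member minimising distance to the
    cluster mean vector survives, ties broken by lexicographically smallest
    record_id.  Exactly ``n_clusters`` ids are returned (sorted).
    """
    ids = list(ids)
    if n_clusters > len(ids):
        raise ValueError(f"cannot form {n_clusters} clusters from {len(ids)} images")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    vectors = e.rows(ids)
    if n_clusters == len(ids):
        return sorted(ids)
    z = linkage(pdist(vectors), method="average")
    cluster_of = fcluster(z, t=n_clusters, criterion="maxclust")
    return _retain_from_clusters(vectors, ids, cluster_of)


def build_dedup_plan(
    manifest: DatasetManifest,
    e: EmbeddingSet,
    retain_fraction: float,
    target_size: int = 10_000,
    seed: int = 0,
) -> DedupPlan:
    """Plan a full deduplication pass over a labelled manifest.

    The total retained count is ``num_clusters(retain_fraction, n)``; the
    cluster budget is allocated to pseudo-classes proportionally to their
    sizes by largest remainder with a minimum of one cluster each (and never
    more clusters than members).
    """
    labels = [rec.label for rec in manifest]
    if any(lab is None for lab in labels):
        raise ValueError("deduplication requires a fully labelled manifest")
    n = len(manifest)
    budget = num_clusters(retain_fraction, n)
    assignments = make_pseudo_classes(e, labels, target_size=target_size, seed=seed)

    groups: dict[tuple[str, int], list[str]] = {}
    for rid, key in assignments.items():
        groups.setdefault(key, []).append(rid)
    keys = sorted(groups)
    sizes = np.array([len(groups[k]) for k in keys])
    if budget < len(keys):
        raise ValueError(
            f"cluster budget {budget} is below the number of pseudo-classes "
            f"({len(keys)}); use a larger retain fraction"
        )
    alloc = np.clip(largest_remainder(sizes, budget), 1, sizes)
    # re-balance after clipping: budget is feasible since
    # #pseudo-classes <= budget <= n = sum(sizes)
    diff = budget - int(alloc.sum())
    while diff != 0:
        if diff > 0:
            room = sizes - alloc
            i = int(np.argmax(room))
            give = min(diff, int(room[i]))
            alloc[i] += give
            diff -= give
        else:
            excess = alloc - 1
            i = int(np.argmax(excess))
            take = min(-diff, int(excess[i]))
            alloc[i] -= take
            diff += take

    retained: list[str] = []
    clusters_per_pseudo: dict[tuple[str, int], int] = {}
    for key, k_clusters in zip(keys, alloc):
        clusters_per_pseudo[key] = int(k_clusters)
        retained.extend(dedup_within(e, sorted(groups[key]), int(k_clusters)))
    # preserve manifest order in the retained list
    retained_set = set(retained)
    retained_ordered = [rid for rid in manifest.record_ids if rid in retained_set]
    return DedupPlan(
        retain_fraction=retain_fraction,
        pseudo_class_target=target_size,
        pseudo_assignments=assignments,
        clusters_per_pseudo=clusters_per_pseudo,
        retained_ids=retained_ordered,
    )


@dataclass
class RedundancyCurve:
    """Probe accuracy as a function of the retained data fraction."""

    fractions: list[float]
    #: evaluation-set name -> per-fraction mean accuracy over replicates
    accuracies: dict[str, list[float]]
    #: evaluation-set name -> per-fraction accuracy sd over replicates
    replicate_sd: dict[str, list[float]]
    replicates: int = 1


def redundancy_curve(
    train_manifest: DatasetManifest,
    e: EmbeddingSet,
    eval_sets: Sequence[tuple[str, DatasetManifest, EmbeddingSet]],
    fractions: Sequence[float],
    classifier_spec: Optional[Callable] = None,
    replicates: int = 3,
    target_size: int = 10_000,
    seed: int = 0,
) -> RedundancyCurve:
    """Stepwise redundancy experiment over a ladder of retain fractions.

    For each fraction the training set is re-deduplicated from scratch, the
    classifier (default: the package's linear probe) is trained on the
    retained records and evaluated on each named evaluation set; means and
    standard deviations over ``replicates`` distinct seeds are reported.
    ``fractions`` must be strictly decreasing (e.g. 1.0, 0.9, ... 0.4).
    A fraction whose retained training data covers fewer than all four
    classes is skipped with a warning.
    """
    from xtalcurate.diagnostics import accuracy, predict_probs, train_linear_probe

    fractions = [float(f) for f in fractions]
    if any(b >= a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly decreasing")

    if classifier_spec is None:
        def classifier_spec(train_e, train_labels, rep_seed):
            probe = train_linear_probe(train_e, train_labels, seed=rep_seed)
            return lambda eval_e: predict_probs(probe, eval_e)

    names = [name for name, _, _ in eval_sets]
    acc: dict[str, list[float]] = {name: [] for name in names}
    sd: dict[str, list[float]] = {name: [] for name in names}
    kept_fractions: list[float] = []
    for fi, frac in enumerate(fractions):
        per_rep: dict[str, list[float]] = {name: [] for name in names}
        skipped = False
        for rep in range(replicates):
            rep_seed = seed + 1000 * fi + rep
            plan = build_dedup_plan(
                train_manifest, e, frac, target_size=target_size, seed=rep_seed
            )
            sub = train_manifest.subset(plan.retained_ids)
            train_labels = labels_array(sub)
            if len(np.unique(train_labels)) < 4:
                import warnings

                warnings.warn(
                    f"fraction {frac}: fewer than 4 classes retained; skipped",
                    stacklevel=2,
                )
                skipped = True
                break
            predict = classifier_spec(e.subset(plan.retained_ids), train_labels, rep_seed)
            for name, ev_manifest, ev_e in eval_sets:
                probs = predict(ev_e)
                per_rep[name].append(accuracy(probs, labels_array(ev_manifest)))
        if skipped:
            continue
        kept_fractions.append(frac)
        for name in names:
            vals = np.asarray(per_rep[name])
            acc[name].append(float(vals.mean()))
            sd[name].append(float(vals.std(ddof=0)))
    return RedundancyCurve(
        fractions=kept_fractions, accuracies=acc, replicate_sd=sd, replicates=replicates
    )
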