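"""Consensus labelling, timecourse uniqueness, and local-image selection.

Consensus labels follow a two-round protocol: an image's label is robust when
two independent annotators agree; on disagreement a third annotator scores
the image and any label held by at least two of the three wins; three-way
disagreement leaves the image ambiguous and it is excluded from the curated
set.

Local-image selection supplements a general training collection with images
from a local pool, either matching a target class distribution (or a uniform
one), or preferring "hard" images — those a reference model is least certain
about, scored by prediction entropy or by cross-entropy against a weak label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from xtalcurate.apportion import largest_remainder
from xtalcurate.manifest import (
    CLASS_INDEX,
    CLASS_LABELS,
    ClassDistribution,
    DatasetManifest,
    validate_label,
)

#: sentinel: two annotators disagreed, a third score is required
NEEDS_THIRD = "NEEDS_THIRD"
#: sentinel: three annotators all disagreed; the image is excluded
AMBIGUOUS = "AMBIGUOUS"

PROB_FLOOR = 1e-12  # clamp before logs: finite scores for confident mistakes


class ProtocolError(ValueError):
    """Annotation set violating the two-round labelling protocol."""


@dataclass
class AnnotationSet:
    """Ordered annotations per record: record_id -> [(annotator_id, label), ...]."""

    annotations: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def add(self, record_id: str, annotator_id: str, label: str) -> None:
        validate_label(label)
        entries = self.annotations.setdefault(record_id, [])
        if any(a == annotator_id for a, _ in entries):
            raise ProtocolError(
                f"annotator {annotator_id!r} scored record {record_id!r} twice"
            )
        entries.append((annotator_id, label))

    def __getitem__(self, record_id: str) -> list[tuple[str, str]]:
        return self.annotations[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.annotations


@dataclass
class ProbabilityTable:
    """Per-record predicted class probabilities (rows in canonical class order)."""

    record_ids: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(CLASS_LABELS):
            raise ValueError(f"probs must be n x {len(CLASS_LABELS)}")
        if self.probs.shape[0] != len(self.record_ids):
            raise ValueError("probs rows must align with record_ids")
        if self.probs.size:
            if (self.probs < -1e-12).any() or (self.probs > 1 + 1e-12).any():
                raise ValueError("probabilities must lie in [0, 1]")
            if np.abs(self.probs.sum(axis=1) - 1.0).max() > 1e-6:
                raise ValueError("probability rows must sum to 1 within 1e-6")
        self._index = {rid: i for i, rid in enumerate(self.record_ids)}

    def row(self, record_id: str) -> np.ndarray:
        return self.probs[self._index[record_id]]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index


def consensus_label(annotations: Sequence[tuple[str, str]]) -> str:
    """Merge 2 or 3 annotations of one record into a consensus label.

    Two agreeing annotations give that label; two disagreeing give
    :data:`NEEDS_THIRD`.  With three annotations, any label held by at least
    two annotators wins; three distinct labels give :data:`AMBIGUOUS`.
    """
    labels = [lab for _, lab in annotations]
    if not 2 <= len(labels) <= 3:
        raise ProtocolError(
            f"protocol expects 2 or 3 annotations per record, got {len(labels)}"
        )
    for lab in labels:
        validate_label(lab)
    if len(labels) == 2:
        return labels[0] if labels[0] == labels[1] else NEEDS_THIRD
    for lab in labels:
        if labels.count(lab) >= 2:
            return lab
    return AMBIGUOUS


def build_consensus_manifest(
    manifest: DatasetManifest, annotations: AnnotationSet
) -> tuple[DatasetManifest, list[str]]:
    """Apply the consensus protocol to every record of a manifest.

    Records gaining a consensus label keep it; ambiguous records are excluded
    and their ids returned separately.  A record with two disagreeing
    annotations but no third score is a protocol violation.
    """
    kept = []
    excluded = []
    for rec in manifest:
        if rec.record_id not in annotations:
            raise ProtocolError(f"record {rec.record_id!r} has no annotations")
        verdict = consensus_label(annotations[rec.record_id])
        if verdict == NEEDS_THIRD:
            raise ProtocolError(
                f"record {rec.record_id!r}: two annotators disagreed and no "
                "third annotation was provided"
            )
        if verdict == AMBIGUOUS:
            excluded.append(rec.record_id)
        else:
            kept.append(
                type(rec)(
                    record_id=rec.record_id,
                    image_path=rec.image_path,
                    label=verdict,
                    source=rec.source,
                    well_id=rec.well_id,
                    timepoint=rec.timepoint,
                )
            )
    return DatasetManifest(records=kept, root=manifest.root), excluded


def one_per_timecourse(
    manifest: DatasetManifest, rule: str = "last", seed: int = 0
) -> DatasetManifest:
    """Keep exactly one image per well (timecourse).

    ``rule`` picks the earliest (``first``), latest (``last``, the default —
    the final inspection carries the most outcome information) or a seeded
    random timepoint per well.  Output preserves manifest order and is
    deterministic given the seed.
    """
    if rule not in ("first", "last", "random"):
        raise ValueError(f"unknown timecourse rule {rule!r}")
    by_well: dict[str, list] = {}
    for rec in manifest:
        by_well.setdefault(rec.well_id, []).append(rec)
    rng = np.random.default_rng(seed)
    keep_ids = set()
    for well_id in sorted(by_well):
        recs = sorted(by_well[well_id], key=lambda r: (r.timepoint, r.record_id))
        if rule == "first":
            chosen = recs[0]
        elif rule == "last":
            chosen = recs[-1]
        else:
            chosen = recs[int(rng.integers(len(recs)))]
        keep_ids.add(chosen.record_id)
    return DatasetManifest(
        records=[r for r in manifest if r.record_id in keep_ids], root=manifest.root
    )


def allocate_counts(dist: ClassDistribution, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n images over the four classes."""
    return largest_remainder(dist.as_array(), n)


def entropy_score(prob_row: Sequence[float]) -> float:
    """Shannon entropy (nats) of one probability row; high = hard image."""
    p = np.asarray(prob_row, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("not a valid probability row")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def cross_entropy_score(prob_row: Sequence[float], true_label: str) -> float:
    """Cross-entropy (nats) of one row against a (possibly weak) label.

    Equals -ln p_true, with p_true clamped at 1e-12 so confident mistakes get
    large but finite scores.
    """
    p = np.asarray(prob_row, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("not a valid probability row")
    validate_label(true_label)
    return float(-np.log(max(p[CLASS_INDEX[true_label]], PROB_FLOOR)))


@dataclass(frozen=True)
class SelectionRequest:
    """What to select from a local pool.

    Modes: ``match_distribution`` draws a per-class random sample realising
    ``target_dist``; ``uniform`` draws equal per-class counts; ``hardest``
    takes the top-n by prediction entropy regardless of class;
    ``hardest_stratified`` takes per-class hardest images at the
    ``target_dist`` class counts.
    """

    n_total: int
    mode: str
    target_dist: Optional[ClassDistribution] = None
    exclude_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")
        if self.mode not in ("match_distribution", "uniform", "hardest", "hardest_stratified"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode in ("match_distribution", "hardest_stratified") and self.target_dist is None:
            raise ValueError(f"mode {self.mode!r} requires target_dist")


class SelectionShortfallError(ValueError):
    """The pool cannot supply the requested per-class counts."""

    def __init__(self, shortfalls: Mapping[str, int]):
        self.shortfalls = dict(shortfalls)
        detail = ", ".join(f"{cls}: short {k}" for cls, k in self.shortfalls.items())
        super().__init__(f"pool cannot satisfy selection ({detail})")


def _pool_by_class(pool: DatasetManifest, exclude: frozenset[str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {c: [] for c in CLASS_LABELS}
    for rec in pool:
        if rec.record_id in exclude:
            continue
        if rec.label is None:
            raise ValueError(f"pool record {rec.record_id!r} is unlabelled")
        out[rec.label].append(rec.record_id)
    return out


def select_local(
    pool: DatasetManifest,
    req: SelectionRequest,
    probs: Optional[ProbabilityTable] = None,
    seed: int = 0,
) -> list[str]:
    """Select record ids from a local pool per the request.

    Never returns duplicates and never intersects ``req.exclude_ids``.  A
    per-class shortfall raises :class:`SelectionShortfallError` naming each
    deficient class; hardness modes without a probability table raise a
    precondition error.
    """
    rng = np.random.default_rng(seed)
    if req.mode in ("hardest", "hardest_stratified") and probs is None:
        raise ValueError(f"mode {req.mode!r} requires a probability table")

    if req.mode == "hardest":
        candidates = [
            rec.record_id for rec in pool if rec.record_id not in req.exclude_ids
        ]
        missing = [rid for rid in candidates if rid not in probs]
        if missing:
            raise ValueError(f"probability table does not cover pool ids {missing[:5]}")
        if len(candidates) < req.n_total:
            raise SelectionShortfallError({"<any>": req.n_total - len(candidates)})
        scored = sorted(
            candidates, key=lambda rid: (-entropy_score(probs.row(rid)), rid)
        )
        return scored[: req.n_total]

    by_class = _pool_by_class(pool, req.exclude_ids)
    if req.mode == "uniform":
        dist = ClassDistribution((0.25, 0.25, 0.25, 0.25))
    else:
        dist = req.target_dist
    counts = allocate_counts(dist, req.n_total)

    shortfalls = {
        cls: int(counts[i]) - len(by_class[cls])
        for i, cls in enumerate(CLASS_LABELS)
        if len(by_class[cls]) < counts[i]
    }
    if shortfalls:
        raise SelectionShortfallError(shortfalls)

    selected: list[str] = []
    for i, cls in enumerate(CLASS_LABELS):
        k = int(counts[i])
        if k == 0:
            continue
        ids = sorted(by_class[cls])
        if req.mode == "hardest_stratified":
            missing = [rid for rid in ids if rid not in probs]
            if missing:
                raise ValueError(
                    f"probability table does not cover pool ids {missing[:5]}"
                )
            ids = sorted(ids, key=lambda rid: (-entropy_score(probs.row(rid)), rid))
            selected.extend(ids[:k])
        else:
            pick = rng.choice(len(ids), size=k, replace=False)
            selected.extend(ids[j] for j in sorted(pick))
    return selected
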