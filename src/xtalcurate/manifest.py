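"""Dataset manifests for crystallisation-outcome image collections.

A manifest is a UTF-8 CSV with a mandatory header
``record_id,image_path,label,source,well_id,timepoint`` describing one
inspection image per row.  Labels use the four-way outcome vocabulary
``clear, crystal, precipitate, other``; this order is canonical project-wide
and every probability vector or confusion matrix follows it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

#: Canonical, fixed class order used by every vector/matrix in the package.
CLASS_LABELS: tuple[str, str, str, str] = ("clear", "crystal", "precipitate", "other")

#: label -> index in CLASS_LABELS
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASS_LABELS)}

MANIFEST_COLUMNS = ("record_id", "image_path", "label", "source", "well_id", "timepoint")


class ManifestFormatError(ValueError):
    """Malformed manifest file (missing column, bad field value)."""


class ManifestIntegrityError(ValueError):
    """Structurally valid manifest violating an integrity invariant."""


def validate_label(label: str) -> str:
    if label not in CLASS_INDEX:
        raise ManifestFormatError(
            f"unknown class label {label!r}; expected one of {CLASS_LABELS}"
        )
    return label


@dataclass(frozen=True)
class ImageRecord:
    """One inspection image.

    ``well_id`` groups the images of a single timecourse (the repeated
    inspections of one droplet); ``timepoint`` is the non-negative inspection
    index within that timecourse.  ``source`` is a free-form tag for the
    laboratory / imager style the image came from.
    """

    record_id: str
    image_path: str
    label: Optional[str] = None
    source: str = ""
    well_id: str = ""
    timepoint: int = 0

    def __post_init__(self) -> None:
        if self.label is not None:
            validate_label(self.label)
        if self.timepoint < 0:
            raise ManifestFormatError(
                f"record {self.record_id!r}: timepoint must be >= 0, got {self.timepoint}"
            )


@dataclass
class DatasetManifest:
    """Ordered collection of :class:`ImageRecord` rooted at a directory."""

    records: list[ImageRecord] = field(default_factory=list)
    root: Optional[Path] = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ManifestIntegrityError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def by_id(self, record_id: str) -> ImageRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def resolve(self, rec: ImageRecord) -> Path:
        """Absolute path of a record's image under the manifest root."""
        base = self.root if self.root is not None else Path(".")
        return Path(base) / rec.image_path

    def subset(self, ids: Sequence[str]) -> "DatasetManifest":
        """Manifest restricted to ``ids``, preserving the original order."""
        keep = set(ids)
        missing = keep - set(self.record_ids)
        if missing:
            raise KeyError(f"ids not in manifest: {sorted(missing)[:5]}")
        return DatasetManifest(
            records=[r for r in self.records if r.record_id in keep], root=self.root
        )


@dataclass(frozen=True)
class ClassDistribution:
    """Probability vector over the four outcome classes, in canonical order."""

    p: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=float)
        if arr.shape != (4,):
            raise ValueError("class distribution must have exactly 4 entries")
        if (arr < 0).any():
            raise ValueError("class distribution entries must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"class distribution must sum to 1, got {arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)

    def __getitem__(self, i: int) -> float:
        return self.p[i]


# Published label distributions of the public collections, reordered to the
# canonical (clear, crystal, precipitate, other) order.
DISTRIBUTION_PRESETS: dict[str, ClassDistribution] = {
    "marco": ClassDistribution((0.336, 0.128, 0.48, 0.056)),
    "c3": ClassDistribution((0.235, 0.283, 0.40, 0.081 + 0.001)),
    "cinder": ClassDistribution((0.27, 0.11, 0.50, 0.12)),
    "uniform": ClassDistribution((0.25, 0.25, 0.25, 0.25)),
}
# The printed C3 row (23.5/28.3/40.0/8.1) sums to 99.9%; the missing 0.1% is
# folded into "other" so the preset is a valid probability vector.


def get_preset(name: str) -> ClassDistribution:
    try:
        return DISTRIBUTION_PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown distribution preset {name!r}; "
            f"choose from {sorted(DISTRIBUTION_PRESETS)}"
        ) from None


def read_manifest(path: str | Path, root: Optional[str | Path] = None) -> DatasetManifest:
    """Read a manifest CSV, preserving row order.

    Empty ``label`` cells become absent labels.  A missing header column raises
    :class:`ManifestFormatError` naming the column; a duplicated ``record_id``
    raises :class:`ManifestIntegrityError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in MANIFEST_COLUMNS:
            if col not in header:
                raise ManifestFormatError(f"manifest {path} is missing column {col!r}")
        records = []
        for row in reader:
            label = row["label"].strip() or None
            try:
                timepoint = int(row["timepoint"]) if row["timepoint"].strip() else 0
            except ValueError:
                raise ManifestFormatError(
                    f"record {row['record_id']!r}: timepoint {row['timepoint']!r} "
                    "is not an integer"
                ) from None
            records.append(
                ImageRecord(
                    record_id=row["record_id"],
                    image_path=row["image_path"],
                    label=label,
                    source=row["source"],
                    well_id=row["well_id"],
                    timepoint=timepoint,
                )
            )
    if root is None:
        root = path.parent
    return DatasetManifest(records=records, root=Path(root))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest CSV; absent labels become empty cells.

    ``read_manifest(write_manifest(m))`` reproduces every record field.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec in manifest.records:
            writer.writerow(
                [
                    rec.record_id,
                    rec.image_path,
                    rec.label or "",
                    rec.source,
                    rec.well_id,
                    rec.timepoint,
                ]
            )


def class_distribution(manifest: DatasetManifest) -> ClassDistribution:
    """Empirical class frequencies of a fully labelled manifest.

    The result is an exact rational count ratio, so it sums to 1 exactly.
    """
    if len(manifest) == 0:
        raise ValueError("class distribution of an empty manifest is undefined")
    counts = np.zeros(4, dtype=np.int64)
    for rec in manifest:
        if rec.label is None:
            raise ValueError(f"record {rec.record_id!r} is unlabelled")
        counts[CLASS_INDEX[rec.label]] += 1
    frac = counts / counts.sum()
    # Renormalise the float ratios so the tuple sums to 1 within 1e-9.
    frac = frac / frac.sum()
    return ClassDistribution(tuple(frac))


def labels_array(manifest: DatasetManifest) -> np.ndarray:
    """Integer class indices of a fully labelled manifest, in record order."""
    out = np.empty(len(manifest), dtype=np.int64)
    for i, rec in enumerate(manifest):
        if rec.label is None:
            raise ValueError(f"record {rec.record_id!r} is unlabelled")
        out[i] = CLASS_INDEX[rec.label]
    return out
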