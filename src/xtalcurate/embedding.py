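"""Image embeddings: fixed-length vectors in which euclidean distance measures
semantic similarity.

The provider contract is deliberately loose: any embedder — including the
penultimate layer of a convolutional network — is accepted downstream as long
as it yields an :class:`EmbeddingSet` (finite ``n x d`` matrix aligned to
record ids).  The built-in :func:`baseline_embed` is a hand-crafted,
deterministic, CPU-only provider: an 8x8 mean-pooled luminance grid, a 32-bin
intensity histogram and a 16-bin gradient-magnitude histogram, each block
standardised across the embedded set (d = 112).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from scipy.spatial.distance import cdist

BASELINE_DIM = 112
_BLOCKS = ((0, 64), (64, 96), (96, 112))  # grid, intensity hist, gradient hist


@dataclass
class EmbeddingSet:
    """A dense ``n x d`` embedding matrix aligned row-wise to record ids."""

    vectors: np.ndarray
    record_ids: list[str]
    provider_name: str = "unknown"
    #: per-feature standardisation statistics (mean, sd) captured at embed
    #: time; reused when a stored embedder is applied to new images
    stats: Optional[tuple[np.ndarray, np.ndarray]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if self.vectors.shape[0] != len(self.record_ids):
            raise ValueError(
                f"{self.vectors.shape[0]} rows but {len(self.record_ids)} record ids"
            )
        if self.vectors.size and not np.isfinite(self.vectors).all():
            raise ValueError("embedding matrix contains non-finite entries")
        if len(set(self.record_ids)) != len(self.record_ids):
            raise ValueError("record ids must be unique")
        self._index = {rid: i for i, rid in enumerate(self.record_ids)}

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        """Sub-matrix for ``ids`` in the given order; unknown id -> KeyError."""
        try:
            idx = [self._index[i] for i in ids]
        except KeyError as exc:
            raise KeyError(f"record id {exc.args[0]!r} not in embedding set") from None
        return self.vectors[idx]

    def subset(self, ids: Sequence[str]) -> "EmbeddingSet":
        return EmbeddingSet(
            vectors=self.rows(ids),
            record_ids=list(ids),
            provider_name=self.provider_name,
            stats=self.stats,
        )


def _load_luminance(path: Path) -> np.ndarray:
    """Read an 8-bit PNG/JPEG as a float luminance array in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


def _image_features(lum: np.ndarray) -> np.ndarray:
    """Raw (unstandardised) 112-dim feature vector of one luminance image."""
    h, w = lum.shape
    # 8x8 mean-pooled grid; crop to a multiple of 8 so pooling is exact
    hc, wc = (h // 8) * 8, (w // 8) * 8
    if hc == 0 or wc == 0:
        raise ValueError("image smaller than 8x8 cannot be embedded")
    grid = lum[:hc, :wc].reshape(8, hc // 8, 8, wc // 8).mean(axis=(1, 3)).ravel()
    hist, _ = np.histogram(lum, bins=32, range=(0.0, 1.0))
    hist = hist / lum.size
    gy, gx = np.gradient(lum)
    gmag = np.hypot(gx, gy)
    ghist, _ = np.histogram(gmag, bins=16, range=(0.0, 0.5))
    ghist = ghist / gmag.size
    return np.concatenate([grid, hist, ghist])


def _standardise(features: np.ndarray, stats=None):
    """Standardise each feature *block* to zero mean / unit variance.

    One scalar mean and sd per block (grid, intensity histogram, gradient
    histogram), computed over all entries of the block across the set.  Block
    statistics keep sparsely populated histogram bins from being blown up by
    a near-zero per-bin variance.  ``stats`` are stored per column (the block
    scalar broadcast over its columns) so they can be reapplied directly.
    """
    if stats is None:
        mean = np.empty(features.shape[1])
        sd = np.empty(features.shape[1])
        for lo, hi in _BLOCKS:
            block = features[:, lo:hi]
            mean[lo:hi] = block.mean() if block.size else 0.0
            s = block.std() if block.size else 0.0
            sd[lo:hi] = s if s > 0 else 1.0
        stats = (mean, sd)
    mean, sd = stats
    return (features - mean) / sd, stats


def baseline_embed(manifest, stats=None) -> EmbeddingSet:
    """Embed every image of a manifest with the baseline provider.

    Standardisation statistics are computed on the set being embedded unless
    ``stats`` from a previous embedding is supplied (the train/apply
    asymmetry: applying a stored embedder to new images reuses its stored
    statistics).  Raises an error naming the record whose image cannot be
    read.
    """
    feats = np.empty((len(manifest), BASELINE_DIM))
    ids = []
    for i, rec in enumerate(manifest):
        path = manifest.resolve(rec)
        try:
            feats[i] = _image_features(_load_luminance(path))
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot embed record {rec.record_id!r}: {exc}") from exc
        ids.append(rec.record_id)
    vectors, stats = _standardise(feats, stats)
    return EmbeddingSet(vectors=vectors, record_ids=ids, provider_name="baseline", stats=stats)


def pairwise_distance(
    e: EmbeddingSet, ids_a: Sequence[str], ids_b: Sequence[str]
) -> np.ndarray:
    """Euclidean distance matrix between two id lists of an embedding set."""
    a, b = e.rows(ids_a), e.rows(ids_b)
    d = cdist(a, b, metric="euclidean")
    if list(ids_a) == list(ids_b):
        np.fill_diagonal(d, 0.0)  # exact zeros on the diagonal
    return d


def save_embeddings(e: EmbeddingSet, path: str | Path) -> None:
    """Save an embedding set as ``<path>.npy`` + ``<path>.ids.txt``.

    The matrix round-trips bit-exactly (binary float storage); the id list is
    one id per line in row order.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), e.vectors)
    with path.with_suffix(".ids.txt").open("w", encoding="utf-8") as fh:
        fh.write(f"# provider: {e.provider_name}\n")
        for rid in e.record_ids:
            fh.write(rid + "\n")


def load_embeddings(path: str | Path) -> EmbeddingSet:
    """Load an embedding set saved by :func:`save_embeddings`."""
    path = Path(path)
    vectors = np.load(path.with_suffix(".npy"))
    provider = "file"
    ids: list[str] = []
    with path.with_suffix(".ids.txt").open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# provider:"):
                provider = line.split(":", 1)[1].strip()
            elif line:
                ids.append(line)
    if vectors.shape[0] != len(ids):
        raise ValueError(
            f"embedding matrix has {vectors.shape[0]} rows but id file lists {len(ids)} ids"
        )
    return EmbeddingSet(vectors=vectors, record_ids=ids, provider_name=provider)
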