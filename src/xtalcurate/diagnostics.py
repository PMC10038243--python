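"""Classifier probe, evaluation metrics and domain-shift diagnostics.

The linear probe is a multinomial logistic regression trained by
deterministic full-batch gradient descent on embedding vectors.  It stands in
for the final affine layer of a deep classifier: cheap, bit-reproducible and
sufficient for the curation procedures, which depend on *relative* model
behaviour (confusion structure, prediction uncertainty, boundary geometry)
rather than absolute deep-network accuracy.

Decision-boundary diagnostics measure, for each of the six class pairs, the
signed euclidean distance of every sample to the pairwise linear boundary.
For a linear head this distance is exact:

    d(x) = ((w_i - w_j) . x + (b_i - b_j)) / ||w_i - w_j||

with positive sign meaning the pairwise score favours class i.  Samples of a
dataset that sit systematically closer to the boundaries — or on the wrong
side — than the training data indicate domain shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from xtalcurate.curation import ProbabilityTable
from xtalcurate.embedding import EmbeddingSet
from xtalcurate.manifest import CLASS_LABELS, DatasetManifest


@dataclass
class LinearProbe:
    """Affine classifier over embeddings: scores = W x + b, softmax over rows."""

    weights: np.ndarray  # k x d
    biases: np.ndarray  # k
    class_names: tuple[str, ...] = CLASS_LABELS
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.biases = np.asarray(self.biases, dtype=np.float64)
        if self.weights.ndim != 2 or self.biases.shape != (self.weights.shape[0],):
            raise ValueError("weights must be k x d with k biases")
        if not (np.isfinite(self.weights).all() and np.isfinite(self.biases).all()):
            raise ValueError("probe parameters must be finite")

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def scores(self, e: EmbeddingSet) -> np.ndarray:
        if e.dim != self.dim:
            raise ValueError(f"probe expects {self.dim}-dim embeddings, got {e.dim}")
        return e.vectors @ self.weights.T + self.biases

    def predict_proba(self, e: EmbeddingSet) -> np.ndarray:
        s = self.scores(e)
        s = s - s.max(axis=1, keepdims=True)  # shift-invariant, overflow-safe
        ex = np.exp(s)
        return ex / ex.sum(axis=1, keepdims=True)


def _softmax_loss_grad(w, b, x, y_onehot, l2):
    n = x.shape[0]
    s = x @ w.T + b
    s = s - s.max(axis=1, keepdims=True)
    ex = np.exp(s)
    p = ex / ex.sum(axis=1, keepdims=True)
    ll = -np.log(np.maximum(p[y_onehot.astype(bool)], 1e-300)).mean()
    loss = ll + 0.5 * l2 * float((w * w).sum())
    diff = (p - y_onehot) / n
    gw = diff.T @ x + l2 * w
    gb = diff.sum(axis=0)
    return loss, gw, gb


def train_linear_probe(
    e: EmbeddingSet,
    labels: Sequence[int],
    l2: float = 1e-4,
    epochs: int = 3000,
    tol: float = 1e-10,
    seed: int = 0,
    n_classes: Optional[int] = None,
    class_names: Optional[tuple[str, ...]] = None,
) -> LinearProbe:
    """Fit a multinomial logistic probe by full-batch gradient descent.

    ``labels`` are integer class indices.  The step size is set from the
    curvature bound of the softmax loss (largest eigenvalue of the feature
    Gram matrix), which makes the training loss decrease monotonically.
    Weights start from a small seed-derived Gaussian so replicate seeds give
    slightly different (but each bit-reproducible) solutions.
    """
    y = np.asarray(labels, dtype=np.int64)
    if y.shape[0] != e.n:
        raise ValueError("labels must align with embedding rows")
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("probe training needs at least 2 classes present")
    if n_classes is None:
        n_classes = len(class_names) if class_names is not None else len(CLASS_LABELS)
    if class_names is None:
        class_names = CLASS_LABELS if n_classes == len(CLASS_LABELS) else tuple(
            f"class{i}" for i in range(n_classes)
        )
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError("label index outside class range")

    x = e.vectors
    n, d = x.shape
    y_onehot = np.zeros((n, n_classes))
    y_onehot[np.arange(n), y] = 1.0

    # curvature bound: 0.5 * lambda_max(X^T X)/n for softmax CE, plus l2
    gram_eig = float(np.linalg.eigvalsh((x.T @ x) / n)[-1]) if d else 1.0
    lipschitz = 0.5 * gram_eig + l2 + 1e-12
    lr = 1.0 / lipschitz

    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 0.01, size=(n_classes, d))
    b = np.zeros(n_classes)
    loss_history = []
    prev = np.inf
    for _ in range(epochs):
        loss, gw, gb = _softmax_loss_grad(w, b, x, y_onehot, l2)
        loss_history.append(loss)
        if prev - loss < tol:
            break
        prev = loss
        w -= lr * gw
        b -= lr * gb
    return LinearProbe(
        weights=w,
        biases=b,
        class_names=class_names,
        training_meta={
            "seed": seed,
            "epochs": epochs,
            "l2": l2,
            "lr": lr,
            "loss_history": loss_history,
        },
    )


def predict_probs(probe: LinearProbe, e: EmbeddingSet) -> ProbabilityTable:
    """Softmax class probabilities of a four-class probe as a ProbabilityTable."""
    if probe.n_classes != len(CLASS_LABELS):
        raise ValueError("predict_probs requires a probe over the four outcome classes")
    return ProbabilityTable(record_ids=list(e.record_ids), probs=probe.predict_proba(e))


def accuracy(probs: ProbabilityTable, labels: Sequence[int]) -> float:
    """Fraction of rows whose argmax matches the true label (ties -> lower index)."""
    y = np.asarray(labels, dtype=np.int64)
    if y.shape[0] != probs.probs.shape[0]:
        raise ValueError("labels must align with probability rows")
    pred = probs.probs.argmax(axis=1)  # argmax breaks ties toward lower index
    return float((pred == y).mean())


@dataclass
class ConfusionMatrix:
    """Confusion counts (rows = true class, columns = predicted class)."""

    counts: np.ndarray
    class_names: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k} x {k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def normalised(self) -> np.ndarray:
        """Rows divided by row sums (per-class recall layout); zero-support rows are NaN."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.counts / sums, np.nan)


def confusion(probs: ProbabilityTable, labels: Sequence[int]) -> ConfusionMatrix:
    """Confusion matrix of argmax predictions against true labels."""
    y = np.asarray(labels, dtype=np.int64)
    pred = probs.probs.argmax(axis=1)
    k = len(CLASS_LABELS)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y, pred), 1)
    return ConfusionMatrix(counts=counts)


@dataclass
class BoundaryDistanceReport:
    """Signed boundary distances for each of the six class pairs.

    ``pairs[(i, j)]`` (i < j) holds the signed distances of every sample whose
    true class is i or j, plus those samples' true labels.  Positive distance
    means the pairwise score favours class i.
    """

    pairs: dict[tuple[int, int], dict]
    class_names: tuple[str, ...] = CLASS_LABELS

    def summary(self) -> dict[tuple[int, int], dict]:
        out = {}
        for key, bucket in self.pairs.items():
            d = bucket["distances"]
            out[key] = {
                "n": int(d.size),
                "mean": float(d.mean()) if d.size else float("nan"),
                "sd": float(d.std(ddof=0)) if d.size else float("nan"),
                "mean_abs": float(np.abs(d).mean()) if d.size else float("nan"),
            }
        return out


def boundary_distances(
    probe: LinearProbe, e: EmbeddingSet, labels: Sequence[int]
) -> BoundaryDistanceReport:
    """Signed distance of every sample to each pairwise decision boundary.

    For pair (i, j) with i < j only samples of true class i or j enter the
    pair's bucket.  A degenerate pair (identical weight rows) raises an error.
    """
    y = np.asarray(labels, dtype=np.int64)
    if y.shape[0] != e.n:
        raise ValueError("labels must align with embedding rows")
    pairs = {}
    for i, j in combinations(range(probe.n_classes), 2):
        dw = probe.weights[i] - probe.weights[j]
        db = probe.biases[i] - probe.biases[j]
        norm = float(np.linalg.norm(dw))
        if norm == 0.0:
            raise ValueError(
                f"degenerate boundary between classes {i} and {j}: identical weights"
            )
        mask = (y == i) | (y == j)
        d = (e.vectors[mask] @ dw + db) / norm
        pairs[(i, j)] = {"distances": d, "labels": y[mask]}
    return BoundaryDistanceReport(pairs=pairs, class_names=probe.class_names)


def crossing_fraction(bucket: dict, pair: tuple[int, int]) -> Optional[float]:
    """Fraction of a pair bucket classified on the wrong side of its boundary.

    Sample of true class i crosses when d < 0; of true class j when d >= 0
    (a tied pairwise score resolves to the earlier class, i).
    """
    i, j = pair
    d, lab = bucket["distances"], bucket["labels"]
    if d.size == 0:
        return None
    crossed = np.where(lab == i, d < 0, d >= 0)
    return float(crossed.mean())


def domain_shift_summary(
    report_a: BoundaryDistanceReport, report_b: BoundaryDistanceReport
) -> dict[tuple[int, int], dict]:
    """Compare two boundary-distance reports from the same probe, pair by pair.

    For each pair: mean |d| in each dataset, each dataset's boundary-crossing
    fraction, and the a-minus-b differences.  Smaller mean |d| and a larger
    crossing fraction in one dataset indicate it sits closer to — and more
    often on the wrong side of — the model's boundaries: domain shift.
    An empty pair bucket is reported as absent (None statistics).
    """
    if report_a.pairs.keys() != report_b.pairs.keys():
        raise ValueError("reports must come from the same probe (same class pairs)")
    out = {}
    for pair in sorted(report_a.pairs):
        da = report_a.pairs[pair]["distances"]
        db = report_b.pairs[pair]["distances"]
        stats = {
            "mean_abs_a": float(np.abs(da).mean()) if da.size else None,
            "mean_abs_b": float(np.abs(db).mean()) if db.size else None,
            "crossing_a": crossing_fraction(report_a.pairs[pair], pair),
            "crossing_b": crossing_fraction(report_b.pairs[pair], pair),
        }
        if da.size and db.size:
            stats["mean_abs_diff"] = stats["mean_abs_a"] - stats["mean_abs_b"]
            stats["crossing_diff"] = stats["crossing_a"] - stats["crossing_b"]
        else:
            stats["mean_abs_diff"] = None
            stats["crossing_diff"] = None
        out[pair] = stats
    return out


def project_2d(e: EmbeddingSet, method: str = "umap", seed: int = 0) -> np.ndarray:
    """Project embeddings to 2-D for scatter inspection (colour by label/source).

    ``umap`` gives a non-linear layout that tends to expose global dataset
    structure such as per-source clumping; ``pca-like`` is the deterministic
    variance-maximising linear projection.  If UMAP is unavailable or fails,
    the linear projection is used with a warning.  Deterministic given seed.
    """
    if e.n < 3:
        raise ValueError("projection needs at least 3 points")
    if method not in ("umap", "pca-like"):
        raise ValueError(f"unknown projection method {method!r}")
    if method == "umap":
        try:
            from umap import UMAP

            reducer = UMAP(n_components=2, random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return np.asarray(reducer.fit_transform(e.vectors), dtype=np.float64)
        except Exception as exc:  # pragma: no cover - environment dependent
            warnings.warn(
                f"UMAP unavailable ({exc}); falling back to linear projection",
                stacklevel=2,
            )
    centred = e.vectors - e.vectors.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    comps = vt[:2]
    # sign convention: largest-|loading| coordinate of each component positive
    for c in comps:
        if c[np.argmax(np.abs(c))] < 0:
            c *= -1
    return centred @ comps.T


def screen_binary(
    pool: DatasetManifest,
    e: EmbeddingSet,
    positives: Sequence[str],
    negatives: Sequence[str],
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[list[str], ConfusionMatrix]:
    """Train a binary screen from labelled examples and scan the rest of a pool.

    Typical use: flag a minority contaminant image type hiding inside a large
    collection.  The labelled positives/negatives (>= 20 each) are split
    80/20 per class by seed; a two-class probe is trained on the 80% and its
    confusion matrix measured on the held-out 20%; every unlabelled pool
    record with positive-class probability >= ``threshold`` is flagged.
    """
    pos, neg = list(positives), list(negatives)
    if set(pos) & set(neg):
        raise ValueError("positives and negatives must be disjoint")
    for name, ids in (("positives", pos), ("negatives", neg)):
        if len(ids) < 20:
            raise ValueError(f"need at least 20 {name}, got {len(ids)}")
    rng = np.random.default_rng(seed)

    def split(ids):
        ids = sorted(ids)
        perm = rng.permutation(len(ids))
        n_train = int(round(0.8 * len(ids)))
        return [ids[i] for i in perm[:n_train]], [ids[i] for i in perm[n_train:]]

    neg_tr, neg_te = split(neg)
    pos_tr, pos_te = split(pos)
    train_ids = neg_tr + pos_tr
    train_y = np.array([0] * len(neg_tr) + [1] * len(pos_tr))
    probe = train_linear_probe(
        e.subset(train_ids),
        train_y,
        n_classes=2,
        class_names=("negative", "positive"),
        seed=seed,
    )

    test_ids = neg_te + pos_te
    test_y = np.array([0] * len(neg_te) + [1] * len(pos_te))
    test_p = probe.predict_proba(e.subset(test_ids))
    pred = test_p.argmax(axis=1)
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (test_y, pred), 1)
    held_out = ConfusionMatrix(counts=counts, class_names=("negative", "positive"))

    labelled = set(pos) | set(neg)
    scan_ids = [rec.record_id for rec in pool if rec.record_id not in labelled]
    flagged = []
    if scan_ids:
        p_pos = probe.predict_proba(e.subset(scan_ids))[:, 1]
        flagged = [rid for rid, p in zip(scan_ids, p_pos) if p >= threshold]
    return flagged, held_out
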