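import numpy as np
import pytest

from xtalcurate import synthetic
from xtalcurate.curation import ProbabilityTable
from xtalcurate.diagnostics import (
    ConfusionMatrix,
    LinearProbe,
    accuracy,
    boundary_distances,
    confusion,
    crossing_fraction,
    domain_shift_summary,
    predict_probs,
    project_2d,
    screen_binary,
    train_linear_probe,
)
from xtalcurate.embedding import EmbeddingSet, baseline_embed
from xtalcurate.manifest import CLASS_LABELS, ClassDistribution


def _eset(vectors, prefix="x"):
    return EmbeddingSet(
        vectors=np.asarray(vectors, dtype=float),
        record_ids=[f"{prefix}{i:04d}" for i in range(len(vectors))],
        provider_name="t",
    )


class TestTrainLinearProbe:
    def test_deterministic(self, gauss4):
        e, y, _ = gauss4
        p1 = train_linear_probe(e, y, seed=3)
        p2 = train_linear_probe(e, y, seed=3)
        assert np.array_equal(p1.weights, p2.weights)
        assert np.array_equal(p1.biases, p2.biases)

    def test_loss_monotone_and_converged(self, gauss4):
        e, y, _ = gauss4
        probe = train_linear_probe(e, y, seed=0)
        hist = np.asarray(probe.training_meta["loss_history"])
        assert np.all(np.diff(hist) <= 1e-12)
        assert hist[-2] - hist[-1] < 1e-4

    def test_separable_two_class_accuracy_one(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (40, 3)), rng.normal(0, 0.3, (40, 3)) + 5])
        y = np.array([0] * 40 + [1] * 40)
        e = _eset(x)
        probe = train_linear_probe(e, y, n_classes=2, seed=0)
        pred = probe.predict_proba(e).argmax(axis=1)
        assert (pred == y).mean() == 1.0

    def test_permutation_null(self):
        cfg = synthetic.EmbeddingSynthConfig(n_per_class=500, dim=8,
                                             class_separation=6.0, seed=0)
        e, labels, _ = synthetic.generate_embeddings(cfg)
        majority = 0.25  # balanced classes
        for s in range(10):
            perm = np.random.default_rng(s).permutation(labels)
            probe = train_linear_probe(e, perm, seed=s)
            acc = accuracy(predict_probs(probe, e), perm)
            assert abs(acc - majority) <= 0.05

    def test_single_class_rejected(self, rng):
        e = _eset(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            train_linear_probe(e, np.zeros(10, dtype=int))

    def test_regularisation_path_monotone(self, gauss4):
        """A larger L2 penalty never increases the learned weight norm."""
        e, y, _ = gauss4
        norms = [
            float(np.linalg.norm(train_linear_probe(e, y, l2=l2, seed=0).weights))
            for l2 in (1e-4, 1e-2, 1e-1, 1.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


class TestPredictProbs:
    def test_zero_probe_uniform_rows(self, rng):
        probe = LinearProbe(weights=np.zeros((4, 3)), biases=np.zeros(4))
        e = _eset(rng.normal(size=(5, 3)))
        table = predict_probs(probe, e)
        assert np.allclose(table.probs, 0.25)

    def test_bias_shift_invariance(self, rng):
        w = rng.normal(size=(4, 3))
        b = rng.normal(size=4)
        e = _eset(rng.normal(size=(10, 3)))
        p1 = LinearProbe(weights=w, biases=b).predict_proba(e)
        p2 = LinearProbe(weights=w, biases=b + 7.5).predict_proba(e)
        assert np.allclose(p1, p2)

    def test_rows_sum_to_one(self, rng):
        probe = LinearProbe(weights=rng.normal(size=(4, 6)) * 10,
                            biases=rng.normal(size=4))
        e = _eset(rng.normal(size=(50, 6)) * 10)
        table = predict_probs(probe, e)
        assert np.abs(table.probs.sum(axis=1) - 1).max() < 1e-9

    def test_argmax_matches_scores(self, rng):
        probe = LinearProbe(weights=rng.normal(size=(4, 5)), biases=rng.normal(size=4))
        e = _eset(rng.normal(size=(100, 5)))
        assert np.array_equal(
            probe.predict_proba(e).argmax(axis=1), probe.scores(e).argmax(axis=1)
        )

    def test_dimension_mismatch(self, rng):
        probe = LinearProbe(weights=np.zeros((4, 3)), biases=np.zeros(4))
        with pytest.raises(ValueError):
            probe.scores(_eset(rng.normal(size=(2, 5))))


class TestAccuracyAndConfusion:
    def _table(self, probs):
        return ProbabilityTable(
            record_ids=[f"r{i}" for i in range(len(probs))], probs=np.asarray(probs)
        )

    def test_all_correct(self):
        t = self._table(np.eye(4))
        assert accuracy(t, [0, 1, 2, 3]) == 1.0

    def test_half_correct(self):
        t = self._table(np.tile(np.eye(4)[0], (10, 1)))
        assert accuracy(t, [0] * 5 + [1] * 5) == 0.5

    def test_counting_oracle(self, rng):
        probs = rng.dirichlet(np.ones(4), size=200)
        y = rng.integers(0, 4, 200)
        t = self._table(probs)
        miscount = sum(int(np.argmax(p) != yi) for p, yi in zip(probs, y))
        assert accuracy(t, y) == pytest.approx(1 - miscount / 200)

    def test_confusion_normalised(self):
        cm = ConfusionMatrix(counts=np.array([[8, 2], [1, 9]]),
                             class_names=("a", "b"))
        assert np.allclose(cm.normalised, [[0.8, 0.2], [0.1, 0.9]])

    def test_confusion_row_sums_are_support(self, rng):
        probs = rng.dirichlet(np.ones(4), size=120)
        y = rng.integers(0, 4, 120)
        cm = confusion(self._table(probs), y)
        assert np.array_equal(cm.counts.sum(axis=1), np.bincount(y, minlength=4))

    def test_zero_support_row_is_nan(self):
        cm = ConfusionMatrix(counts=np.array([[0, 0], [1, 1]]),
                             class_names=("a", "b"))
        assert np.isnan(cm.normalised[0]).all()
        assert np.allclose(cm.normalised[1], 0.5)


class TestBoundaryDistances:
    def test_hand_example(self):
        probe = LinearProbe(weights=np.array([[1.0, 0], [-1.0, 0], [0, 1], [0, -1]]),
                            biases=np.zeros(4))
        e = _eset([[2.0, 0.0]])
        rep = boundary_distances(probe, e, [0])
        assert rep.pairs[(0, 1)]["distances"][0] == pytest.approx(2.0)

    def test_on_boundary_zero(self):
        probe = LinearProbe(weights=np.array([[1.0, 0], [-1.0, 0], [0, 1], [0, -1]]),
                            biases=np.zeros(4))
        e = _eset([[0.0, 3.0]])
        rep = boundary_distances(probe, e, [0])
        assert rep.pairs[(0, 1)]["distances"][0] == pytest.approx(0.0)

    def test_six_pairs(self, gauss4):
        e, y, _ = gauss4
        rep = boundary_distances(train_linear_probe(e, y, seed=0), e, y)
        assert sorted(rep.pairs) == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

    def test_sign_agrees_with_pairwise_argmax(self, rng):
        probe = LinearProbe(weights=rng.normal(size=(4, 6)), biases=rng.normal(size=4))
        x = rng.normal(size=(1000, 6))
        e = _eset(x)
        y = rng.integers(0, 4, 1000)
        rep = boundary_distances(probe, e, y)
        scores = x @ probe.weights.T + probe.biases
        for (i, j), bucket in rep.pairs.items():
            mask = (y == i) | (y == j)
            favours_i = scores[mask, i] >= scores[mask, j]
            assert np.array_equal(bucket["distances"] >= 0, favours_i)

    def test_crossing_equals_pairwise_misclassification(self, gauss4):
        """Counting oracle: crossings = samples whose pairwise argmax is the
        other class of the pair."""
        e, y, _ = gauss4
        probe = train_linear_probe(e, y, seed=0)
        rep = boundary_distances(probe, e, y)
        scores = e.vectors @ probe.weights.T + probe.biases
        for (i, j), bucket in rep.pairs.items():
            mask = (y == i) | (y == j)
            pair_pred = np.where(scores[mask, i] >= scores[mask, j], i, j)
            oracle = float((pair_pred != y[mask]).mean())
            assert crossing_fraction(bucket, (i, j)) == pytest.approx(oracle)

    def test_degenerate_boundary_rejected(self):
        w = np.zeros((4, 2))
        w[2] = [1, 0]
        w[3] = [0, 1]
        probe = LinearProbe(weights=w, biases=np.zeros(4))
        with pytest.raises(ValueError, match="degenerate"):
            boundary_distances(probe, _eset([[1.0, 1.0]]), [0])


class TestDomainShift:
    def test_identical_datasets_zero_difference(self, gauss4):
        e, y, _ = gauss4
        probe = train_linear_probe(e, y, seed=0)
        rep = boundary_distances(probe, e, y)
        shift = domain_shift_summary(rep, rep)
        for stats in shift.values():
            assert stats["mean_abs_diff"] == pytest.approx(0.0)
            assert stats["crossing_diff"] == pytest.approx(0.0)
            assert 0.0 <= stats["crossing_a"] <= 1.0

    def test_shifted_dataset_closer_and_more_crossed(self, gauss4):
        """Class centres moved 70% toward the global mean: every pair shows a
        smaller mean |d| and a larger crossing fraction."""
        e, y, _ = gauss4
        probe = train_linear_probe(e, y, seed=0)
        rep_a = boundary_distances(probe, e, y)
        shifted = e.vectors.copy()
        gm = e.vectors.mean(axis=0)
        for c in range(4):
            mask = y == c
            shifted[mask] -= 0.7 * (e.vectors[mask].mean(axis=0) - gm)
        e_b = _eset(shifted, prefix="s")
        rep_b = boundary_distances(probe, e_b, y)
        shift = domain_shift_summary(rep_a, rep_b)
        assert all(s["mean_abs_b"] < s["mean_abs_a"] for s in shift.values())
        assert all(s["crossing_b"] > s["crossing_a"] for s in shift.values())

    def test_mismatched_reports_rejected(self, gauss4):
        e, y, _ = gauss4
        probe = train_linear_probe(e, y, seed=0)
        rep = boundary_distances(probe, e, y)
        other = type(rep)(pairs={(0, 1): rep.pairs[(0, 1)]})
        with pytest.raises(ValueError):
            domain_shift_summary(rep, other)


class TestProject2d:
    def test_linear_method_preserves_collinearity(self):
        e = _eset([[0.0, 0, 0], [1.0, 1, 1], [2.0, 2, 2], [3.0, 3, 3]])
        xy = project_2d(e, method="pca-like")
        # all variance on the first component; second coordinate is ~0
        assert np.abs(xy[:, 1]).max() < 1e-9
        assert xy.shape == (4, 2)

    def test_deterministic(self, gauss4):
        e, _, _ = gauss4
        a = project_2d(e, method="pca-like", seed=1)
        b = project_2d(e, method="pca-like", seed=1)
        assert np.array_equal(a, b)

    def test_umap_runs_and_is_deterministic(self, gauss4):
        e, _, _ = gauss4
        sub = e.subset(e.record_ids[:60])
        a = project_2d(sub, method="umap", seed=2)
        b = project_2d(sub, method="umap", seed=2)
        assert a.shape == (60, 2)
        assert np.array_equal(a, b)

    def test_source_dominant_layout(self):
        """With dominant source structure the 2-D layout groups by source."""
        cfg = synthetic.EmbeddingSynthConfig(
            n_per_class=40, dim=10, class_separation=1.0, source_separation=10.0,
            n_sources=2, within_sd=0.3, seed=6,
        )
        e, labels, sources = synthetic.generate_embeddings(cfg)
        xy = project_2d(e, method="pca-like")

        def mean_within(groups):
            tot, cnt = 0.0, 0
            for g in np.unique(groups):
                pts = xy[groups == g]
                d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
                tot += d.sum()
                cnt += d.size - len(pts)
            return tot / cnt

        assert mean_within(sources) < mean_within(labels)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            project_2d(_eset([[0.0, 1], [1, 0]]), method="pca-like")


@pytest.fixture(scope="module")
def contaminated(tmp_path_factory):
    out = tmp_path_factory.mktemp("contam")
    cfg = synthetic.SynthConfig(
        n_images=200,
        class_dist=ClassDistribution((0.25, 0.25, 0.25, 0.25)),
        contaminant_fraction=0.25,
        seed=21,
    )
    m = synthetic.generate_dataset(cfg, out)
    e = baseline_embed(m)
    pos = (out / "contaminants.txt").read_text().split()
    neg = [r.record_id for r in m if r.record_id not in set(pos)][: len(pos)]
    return m, e, pos, neg


class TestScreenBinary:
    def test_held_out_accuracy(self, contaminated):
        m, e, pos, neg = contaminated
        _, cm = screen_binary(m, e, pos, neg, seed=0)
        acc = np.trace(cm.counts) / cm.counts.sum()
        assert acc >= 0.9

    def test_threshold_limits(self, contaminated):
        m, e, pos, neg = contaminated
        flagged_all, _ = screen_binary(m, e, pos, neg, threshold=0.0, seed=0)
        n_scan = len(m) - len(pos) - len(neg)
        assert len(flagged_all) == n_scan
        flagged_one, _ = screen_binary(m, e, pos, neg, threshold=1.0, seed=0)
        assert len(flagged_one) <= n_scan * 0.05

    def test_overlap_rejected(self, contaminated):
        m, e, pos, neg = contaminated
        with pytest.raises(ValueError):
            screen_binary(m, e, pos, pos, seed=0)

    def test_minimum_examples(self, contaminated):
        m, e, pos, neg = contaminated
        with pytest.raises(ValueError, match="at least 20"):
            screen_binary(m, e, pos[:5], neg, seed=0)
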