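"""Accuracy/confusion reports, ROC/AUC, t-SNE embeddings, throughput."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from bilinearcnn.evaluation import (
    evaluate,
    extract_embedding_features,
    measure_fps,
    roc_curves,
    tsne_embed,
)


class OracleModel:
    """Predicts the true label it is told at construction."""

    def __init__(self, y, classes):
        self.y = np.asarray(y)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        idx = {c: i for i, c in enumerate(self.classes_)}
        p = np.zeros((len(self.y), len(self.classes_)))
        for row, label in enumerate(self.y):
            p[row, idx[label]] = 1.0
        return p


class ConstantModel:
    def __init__(self, classes):
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        p = np.zeros((len(X), len(self.classes_)))
        p[:, 0] = 1.0
        return p


def auc_by_concordance(binary_labels, scores):
    """Brute-force AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[binary_labels == 1]
    neg = scores[binary_labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestEvaluate:
    def test_oracle_model_scores_one_with_diagonal_confusion(self):
        y = np.array(list("aabbcc"))
        report = evaluate(OracleModel(y, ["a", "b", "c"]),
                          np.zeros((6, 2, 2, 3)), y)
        assert report.accuracy == 1.0
        assert np.all(report.confusion == np.diag([2, 2, 2]))

    def test_constant_model_scores_chance_with_single_column(self):
        y = np.repeat(["a", "b", "c", "d"], 10)
        report = evaluate(ConstantModel(["a", "b", "c", "d"]),
                          np.zeros((40, 2, 2, 3)), y)
        assert report.accuracy == pytest.approx(0.25)
        assert np.all(report.confusion[:, 1:] == 0)

    def test_accuracy_is_mean_per_class_accuracy_when_balanced(self, rng):
        y = np.repeat(["a", "b"], 8)
        scores = rng.uniform(size=(16, 2))
        scores /= scores.sum(1, keepdims=True)

        class R:
            classes_ = np.array(["a", "b"])

            def predict_proba(self, X):
                return scores

        report = evaluate(R(), np.zeros((16, 2, 2, 3)), y)
        assert report.accuracy == pytest.approx(
            np.mean(list(report.per_class_accuracy.values())))

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            evaluate(ConstantModel(["a", "b"]), np.zeros((2, 2, 2, 3)),
                     np.array(["a", "z"]))

    def test_confusion_rows_sum_to_class_counts(self, rng):
        y = np.array(list("aaabbc"))
        scores = rng.uniform(size=(6, 3))
        scores /= scores.sum(1, keepdims=True)

        class R:
            classes_ = np.array(["a", "b", "c"])

            def predict_proba(self, X):
                return scores

        report = evaluate(R(), np.zeros((6, 2, 2, 3)), y)
        np.testing.assert_array_equal(report.confusion.sum(1), [3, 2, 1])


class TestROC:
    def test_perfect_separation_gives_unit_auc(self):
        labels = np.array(["p", "p", "n", "n"])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        _, aucs = roc_curves(scores, labels, class_names=["p", "n"])
        assert aucs["p"] == 1.0 and aucs["n"] == 1.0
        assert aucs["macro"] == 1.0

    def test_identical_scores_give_half_auc(self):
        labels = np.array(["p", "n"] * 5)
        scores = np.full((10, 2), 0.5)
        _, aucs = roc_curves(scores, labels, class_names=["p", "n"])
        assert aucs["macro"] == pytest.approx(0.5)

    def test_matches_pairwise_concordance_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 51))
            k = int(rng.integers(2, 5))
            labels = rng.integers(0, k, size=n)
            while len(np.unique(labels)) < 2:
                labels = rng.integers(0, k, size=n)
            scores = rng.uniform(size=(n, k))
            scores /= scores.sum(1, keepdims=True)
            if n >= 8:  # duplicated rows force ties through the tie path
                scores[1] = scores[0]
                scores[3] = scores[2]
            _, aucs = roc_curves(scores, labels,
                                 class_names=list(range(k)))
            for c in range(k):
                binary = (labels == c).astype(int)
                if binary.min() == binary.max():
                    assert aucs[c] is None
                    continue
                expected = auc_by_concordance(binary, scores[:, c])
                assert aucs[c] == pytest.approx(expected, abs=1e-10)

    def test_roc_points_monotone_nondecreasing(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=(30, 2))
        scores /= scores.sum(1, keepdims=True)
        roc, _ = roc_curves(scores, labels, class_names=[0, 1])
        for fpr, tpr in roc.values():
            assert np.all(np.diff(fpr) >= 0)
            assert np.all(np.diff(tpr) >= 0)

    def test_single_class_auc_reported_missing(self):
        labels = np.array(["a", "a", "a"])
        scores = np.array([[0.7, 0.3]] * 3)
        _, aucs = roc_curves(scores, labels, class_names=["a", "b"])
        assert aucs["b"] is None
        # the degenerate one-vs-rest split also voids class "a"
        assert aucs["a"] is None and aucs["macro"] is None

    def test_non_probability_scores_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            roc_curves(np.ones((4, 2)), np.array([0, 1, 0, 1]),
                       class_names=[0, 1])


class TestEmbedding:
    def test_feature_width_is_class_count(self, trained_fast,
                                          synth_dataset):
        X = synth_dataset["images"][:6]
        feats = extract_embedding_features(trained_fast, X)
        assert feats.shape == (6, len(trained_fast.classes_))
        np.testing.assert_array_equal(
            feats, extract_embedding_features(trained_fast, X))

    def test_two_tight_clusters_stay_separated(self, rng):
        a = rng.normal(size=(20, 8)) * 0.05
        b = rng.normal(size=(20, 8)) * 0.05 + 5.0
        feats = np.vstack([a, b])
        emb = tsne_embed(feats, seed=0, perplexity=10)
        labels = np.repeat([0, 1], 20)
        assert silhouette_score(emb.coords, labels) > 0.5

    def test_one_coordinate_pair_per_sample_and_seeded(self, rng):
        feats = rng.normal(size=(30, 5))
        e1 = tsne_embed(feats, seed=4)
        e2 = tsne_embed(feats, seed=4)
        assert e1.coords.shape == (30, 2)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="too few"):
            tsne_embed(rng.normal(size=(5, 3)))


class TestThroughput:
    def test_fps_positive_and_finite(self, trained_fast):
        fps = measure_fps(trained_fast, n_frames=3, input_size=64,
                          n_trials=2, warmup=1)
        assert np.isfinite(fps) and fps > 0

    def test_single_frame_measurement_finite(self, trained_fast):
        fps = measure_fps(trained_fast, n_frames=1, input_size=64,
                          n_trials=1, warmup=0)
        assert np.isfinite(fps) and fps > 0

    def test_fast_not_slower_than_two_stream(self, rng):
        from bilinearcnn.models import (BackboneSpec, assemble_bcnn,
                                        assemble_fast_bcnn, build_backbone)

        spec = BackboneSpec(output_channels=16, input_size=64)
        fast = assemble_fast_bcnn(build_backbone(spec, rng), 4, rng=rng)
        two = assemble_bcnn(build_backbone(spec, rng),
                            build_backbone(spec, rng), 4, rng=rng)
        fps_fast = measure_fps(fast, n_frames=10, input_size=64,
                               n_trials=5, warmup=5)
        fps_two = measure_fps(two, n_frames=10, input_size=64,
                              n_trials=5, warmup=5)
        # relational check only; generous slack for timer jitter
        assert fps_fast >= 0.8 * fps_two
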