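"""Tests for the cosine distance, prediction engines and jackknife."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from surrogenes import (ConfusionCounts, LabeledExpressionMatrix, accuracy,
                        confusion_counts, jackknife, jackknife_predictions,
                        pairwise_accuracy, predict_centroid, predict_nn1,
                        predict_vote5, sample_distance)
from surrogenes.classify import DegenerateVectorError, EmptyEvaluationError


class TestSampleDistance:
    def test_identical_vectors_are_at_zero(self):
        assert sample_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_orthogonal_vectors_are_at_one(self):
        assert sample_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_opposite_vectors_are_at_two(self):
        assert sample_distance([1, 1], [-1, -1]) == pytest.approx(2.0)

    def test_positive_rescaling_invariance(self):
        assert sample_distance([1, 2], [3, 6]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_norm_vector_rejected(self):
        with pytest.raises(DegenerateVectorError):
            sample_distance([0, 0], [1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sample_distance([1, 2], [1, 2, 3])

    nonzero_vec = arrays(np.float64, 4,
                         elements=st.floats(-100, 100, allow_nan=False)
                         ).filter(lambda v: np.linalg.norm(v) > 1e-6)

    @given(nonzero_vec, nonzero_vec, st.floats(0.1, 50))
    @settings(max_examples=150, deadline=None)
    def test_metric_properties(self, a, b, scale):
        d = sample_distance(a, b)
        assert 0.0 <= d <= 2.0
        assert d == pytest.approx(sample_distance(b, a), abs=1e-12)
        assert sample_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert sample_distance(a * scale, b) == pytest.approx(d, abs=1e-9)


TRAIN = np.array([[1.0, 0.1], [0.9, 0.2], [0.1, 1.0], [0.2, 0.9], [1.0, 1.0]])
TRAIN_LABELS = ["A", "A", "B", "B", "C"]


class TestEngines:
    def test_nn1_recovers_exact_training_vector(self):
        assert predict_nn1(TRAIN, TRAIN_LABELS, TRAIN[2]) == "B"

    def test_nn1_single_training_sample(self):
        assert predict_nn1(TRAIN[:1], ["A"], [5.0, 5.0]) == "A"

    def test_nn1_matches_brute_force(self):
        rng = np.random.default_rng(0)
        V = rng.normal(5, 1, size=(20, 3))
        labels = [f"L{i % 4}" for i in range(20)]
        for _ in range(20):
            q = rng.normal(5, 1, size=3)
            dists = [sample_distance(v, q) for v in V]
            assert predict_nn1(V, labels, q) == labels[int(np.argmin(dists))]

    def test_vote5_unanimous(self):
        V = np.vstack([TRAIN[:2] + 0.01 * np.arange(2)[:, None], TRAIN[:3]])
        assert predict_vote5(V, ["A"] * 5, [1.0, 0.15]) == "A"

    def test_vote5_tie_goes_to_nearest_tied_class(self):
        # 2 vs 2 vs 1: query sits closest to a B member.
        V = np.array([[0.0, 1.0], [0.05, 1.0],
                      [1.0, 0.02], [1.0, 0.3], [1.0, 1.0]])
        labels = ["A", "A", "B", "B", "C"]
        assert predict_vote5(V, labels, [1.0, 0.0]) == "B"

    def test_vote5_matches_brute_force_tally(self):
        from collections import Counter
        rng = np.random.default_rng(4)
        V = rng.normal(5, 1, size=(15, 3))
        labels = [f"L{i % 3}" for i in range(15)]
        for _ in range(20):
            q = rng.normal(5, 1, size=3)
            d = np.array([sample_distance(v, q) for v in V])
            top = [labels[i] for i in np.argsort(d, kind="stable")[:5]]
            counts = Counter(top)
            best = max(counts.values())
            expected = next(l for l in top if counts[l] == best)
            assert predict_vote5(V, labels, q) == expected

    def test_centroid_recovers_class_mean(self):
        centroid_b = TRAIN[2:4].mean(axis=0)
        assert predict_centroid(TRAIN, TRAIN_LABELS, centroid_b,
                                ("A", "B", "C")) == "B"

    def test_centroid_tie_goes_to_earlier_class(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        # Query equidistant from both centroids.
        assert predict_centroid(V, ["X", "Y"], [1.0, 1.0], ("X", "Y")) == "X"
        assert predict_centroid(V, ["X", "Y"], [1.0, 1.0], ("Y", "X")) == "Y"

    def test_centroid_matches_brute_force(self, separable_sim):
        m = separable_sim.matrix
        V = m.subset_values(separable_sim.informative_probes())
        rng = np.random.default_rng(2)
        take = rng.choice(m.n_samples, size=30, replace=False)
        for i in take:
            expected_label, expected_d = None, np.inf
            for cls in m.class_order:
                mask = (m.labels == cls)
                d = sample_distance(V[mask].mean(axis=0), V[i])
                if d < expected_d:
                    expected_d, expected_label = d, cls
            assert predict_centroid(V, m.labels, V[i], m.class_order) == \
                expected_label

    def test_engines_agree_in_trivial_limit(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        labels = ["A", "B", "C"]
        q = V[1]
        order = ("A", "B", "C")
        nn = predict_nn1(V, labels, q)
        vote = predict_vote5(V, labels, q)
        cen = predict_centroid(V, labels, q, order)
        assert nn == vote == cen == "B"


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy(ConfusionCounts(5, 5, 0, 0)) == 1.0

    def test_direct_substitution(self):
        assert accuracy(ConfusionCounts(TP=3, TN=4, FP=2, FN=1)) == 0.7

    def test_none_correct(self):
        assert accuracy(ConfusionCounts(0, 0, 1, 1)) == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(EmptyEvaluationError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


def _two_sample_matrix():
    return LabeledExpressionMatrix(
        values=np.array([[1.0, 1.0], [2.0, 2.0]]),
        probe_ids=["P0", "P1"],
        sample_ids=["S0", "S1"],
        labels=np.array(["NT", "PT"], dtype=object),
        class_order=("NT", "PT"),
    )


class TestJackknife:
    def test_identical_vectors_opposite_labels_score_zero(self):
        _, acc = jackknife(_two_sample_matrix(), ["P0", "P1"], "nn1")
        assert acc == 0.0

    def test_one_record_per_sample(self, default_sim):
        m = default_sim.matrix
        records, _ = jackknife(m, default_sim.informative_probes(), "nn1")
        assert len(records) == m.n_samples
        assert set(records["sample_id"]) == set(m.sample_ids)

    def test_separable_limit_is_perfect(self, separable_sim):
        m = separable_sim.matrix
        probes = separable_sim.informative_probes()
        # Verify separability independently: every sample's nearest
        # other sample (cosine) belongs to its own class.
        V = m.subset_values(probes)
        Vn = V / np.linalg.norm(V, axis=1, keepdims=True)
        D = 1 - Vn @ Vn.T
        np.fill_diagonal(D, np.inf)
        nearest = np.argmin(D, axis=1)
        assert all(m.labels[i] == m.labels[j] for i, j in enumerate(nearest))
        _, acc = jackknife(m, probes, "nn1")
        assert acc == 1.0

    def test_held_out_label_cannot_leak(self, default_sim):
        # Flipping the held-out sample's label must not change its own
        # predicted label under any engine.
        m = default_sim.matrix
        probes = default_sim.informative_probes()
        base = jackknife_predictions(m, probes)
        i = 5
        mutated_labels = m.labels.copy()
        mutated_labels[i] = "MT" if m.labels[i] != "MT" else "NT"
        mutated = LabeledExpressionMatrix(
            values=m.values, probe_ids=m.probe_ids, sample_ids=m.sample_ids,
            labels=mutated_labels, class_order=m.class_order)
        alt = jackknife_predictions(mutated, probes)
        for engine in ("vote5", "nn1", "centroid"):
            assert alt.loc[i, engine] == base.loc[i, engine]

    def test_multiclass_accuracy_equals_micro_summed_confusion(self, default_sim):
        m = default_sim.matrix
        records, acc = jackknife(m, default_sim.informative_probes(), "centroid")
        total = ConfusionCounts(0, 0, 0, 0)
        for cls in m.class_order:
            c = confusion_counts(records["true"], records["predicted"], cls)
            total = ConfusionCounts(total.TP + c.TP, total.TN + c.TN,
                                    total.FP + c.FP, total.FN + c.FN)
        k = len(m.class_order)
        n = m.n_samples
        correct = records["correct"].sum()
        # micro: TP+TN = correct*k + (n-correct)*(k-2); total = n*k
        assert accuracy(total) == pytest.approx(
            (correct * k + (n - correct) * (k - 2)) / (n * k))


class TestPairwiseAccuracy:
    def _records(self):
        import pandas as pd
        return pd.DataFrame({
            "true":      ["NT", "NT", "PT", "MT", "MT", "MT"],
            "predicted": ["NT", "PT", "PT", "MT", "NT", "MT"],
        })

    def test_hand_tally(self):
        r = self._records()
        # Restricted to NT/MT: 5 samples, predictions NT,PT,MT,NT,MT
        # correct: NT, MT, MT -> 4/5? sample2 true NT pred PT wrong;
        # samples: (NT,NT)+, (NT,PT)-, (MT,MT)+, (MT,NT)-, (MT,MT)+ = 3/5
        assert pairwise_accuracy(r, "NT", "MT") == pytest.approx(3 / 5)
        assert pairwise_accuracy(r, "PT", "MT") == pytest.approx(3 / 4)

    def test_third_class_predictions_do_not_matter(self):
        r = self._records()
        base = pairwise_accuracy(r, "NT", "MT")
        r2 = r.copy()
        r2.loc[r2["true"] == "PT", "predicted"] = "NT"  # flip PT rows
        assert pairwise_accuracy(r2, "NT", "MT") == base

    def test_empty_restriction_rejected(self):
        with pytest.raises(EmptyEvaluationError):
            pairwise_accuracy(self._records(), "XX", "YY")
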