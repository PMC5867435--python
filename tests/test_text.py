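"""Text classification, sentiment scoring, agreement and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from carevoice import (
    ValidationError,
    classification_metrics,
    classify,
    cohen_kappa,
    generate_labelled_corpus,
    oversample,
    score_sentiment,
    star_accuracy,
    train_text_model,
)
from carevoice.text import LabelledText


def corpus_of(counts: dict) -> list[LabelledText]:
    out = []
    for label, n in counts.items():
        out.extend(LabelledText(f"text {label} {i}", label, None) for i in range(n))
    return out


class TestOversample:
    def test_minority_raised_to_majority(self):
        corpus = corpus_of({"A": 10, "B": 2})
        out = oversample(corpus, seed=0)
        counts = {lab: sum(1 for it in out if it.label == lab) for lab in "AB"}
        assert counts == {"A": 10, "B": 10}
        # additions are drawn from B's own two items
        b_texts = {it.text for it in out if it.label == "B"}
        assert b_texts == {"text B 0", "text B 1"}

    def test_balanced_corpus_unchanged(self):
        corpus = corpus_of({"A": 5, "B": 5})
        out = oversample(corpus, seed=0)
        assert sorted((it.label, it.text) for it in out) == sorted(
            (it.label, it.text) for it in corpus
        )

    def test_coded_sample_proportions(self):
        # the double-coded microblog sample: majority class 5,351 of 5,869
        counts = {
            "patient_experience_effectiveness": 348,
            "environment_facilities": 67,
            "timeliness_access": 90,
            "safety": 13,
            "not_care_quality": 5351,
        }
        out = oversample(corpus_of(counts), seed=1)
        for label in counts:
            assert sum(1 for it in out if it.label == label) == 5351

    def test_majority_multiset_preserved(self):
        corpus = corpus_of({"A": 7, "B": 3})
        out = oversample(corpus, seed=2)
        majority = sorted(it.text for it in out if it.label == "A")
        assert majority == sorted(f"text A {i}" for i in range(7))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            oversample([], seed=0)


class TestTraining:
    def test_separable_corpus_high_holdout_f1(self):
        corpus = generate_labelled_corpus(2000, separation=1.0, seed=11)
        model, report = train_text_model(corpus, "relevance", seed=11)
        assert report["holdout_macro_f1"] >= 0.95

    def test_no_signal_corpus_cannot_beat_majority(self):
        # identical class-conditional distributions: no classifier beats the
        # majority class in expectation (oversampling trades majority accuracy
        # for minority recall, so accuracy typically lands below it)
        corpus = generate_labelled_corpus(1500, separation=0.0, seed=13)
        labels = [c.label for c in corpus]
        majority_rate = max(labels.count(l) for l in set(labels)) / len(labels)
        model, report = train_text_model(corpus, "relevance", seed=13)
        assert report["holdout_accuracy"] <= majority_rate + 0.03

    def test_same_seed_reproducible(self):
        corpus = generate_labelled_corpus(800, separation=0.9, seed=5)
        _, r1 = train_text_model(corpus, "relevance", seed=5)
        _, r2 = train_text_model(corpus, "relevance", seed=5)
        assert r1["selected_params"] == r2["selected_params"]
        assert r1["holdout_macro_f1"] == r2["holdout_macro_f1"]

    def test_holdout_never_in_training(self):
        corpus = generate_labelled_corpus(800, separation=0.9, seed=6)
        _, report = train_text_model(corpus, "relevance", seed=6)
        assert set(report["train_indices"]).isdisjoint(report["holdout_indices"])
        assert len(report["train_indices"]) + len(report["holdout_indices"]) == len(corpus)

    def test_training_accuracy_at_least_holdout_on_separable(self):
        corpus = generate_labelled_corpus(1200, separation=1.0, seed=7)
        model, report = train_text_model(corpus, "relevance", seed=7)
        texts = [c.text for c in corpus]
        labels = [c.label for c in corpus]
        train_idx = report["train_indices"]
        pred = classify(model, [texts[i] for i in train_idx])
        train_acc = np.mean([p == labels[i] for p, i in zip(pred, train_idx)])
        assert train_acc >= report["holdout_accuracy"] - 1e-9

    def test_sentiment_learnable_when_separable(self):
        corpus = generate_labelled_corpus(2000, separation=1.0, seed=8)
        model, report = train_text_model(corpus, "sentiment", seed=8)
        assert report["holdout_exact_accuracy"] >= 0.9
        assert report["holdout_within_one_accuracy"] >= report["holdout_exact_accuracy"]

    def test_empty_grid_rejected(self):
        corpus = generate_labelled_corpus(200, seed=1)
        with pytest.raises(ValidationError):
            train_text_model(corpus, "relevance", grid=())

    def test_unknown_task_rejected(self):
        with pytest.raises(ValidationError):
            train_text_model(generate_labelled_corpus(100, seed=1), "topic")


@pytest.fixture(scope="module")
def models():
    corpus = generate_labelled_corpus(1200, separation=1.0, seed=21)
    rel, _ = train_text_model(corpus, "relevance", seed=21)
    sent, _ = train_text_model(corpus, "sentiment", seed=21)
    return rel, sent


class TestClassify:

    def test_wrong_task_is_usage_error(self, models):
        rel, sent = models
        with pytest.raises(ValidationError):
            classify(sent, ["x"])
        with pytest.raises(ValidationError):
            score_sentiment(rel, ["x"])

    def test_empty_text_gets_majority_label(self, models):
        rel, _ = models
        assert classify(rel, [""]) == [rel.majority_label]

    def test_batch_order_preserved(self, models):
        rel, _ = models
        corpus = generate_labelled_corpus(50, separation=1.0, seed=22)
        out = classify(rel, [c.text for c in corpus])
        assert len(out) == 50
        # separable vocabularies: each prediction matches its own item's label
        n_correct = sum(p == c.label for p, c in zip(out, corpus))
        assert n_correct >= 45

    def test_sentiment_outputs_are_stars(self, models):
        _, sent = models
        corpus = [c for c in generate_labelled_corpus(80, separation=1.0, seed=23) if c.stars]
        stars = score_sentiment(sent, [c.text for c in corpus])
        assert all(isinstance(s, int) and 1 <= s <= 5 for s in stars)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(list("aabbc"), list("aabbc")) == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # confusion counts [[20, 5], [10, 15]]: p_o = 0.70, p_e = 0.50, kappa = 0.40
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohen_kappa(a, b) == pytest.approx(0.40)

    def test_matches_sklearn(self, rng):
        a = rng.integers(0, 4, size=500).tolist()
        b = rng.integers(0, 4, size=500).tolist()
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_symmetric(self, rng):
        a = rng.integers(0, 3, size=200).tolist()
        b = rng.integers(0, 3, size=200).tolist()
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa(b, a))

    def test_chance_level_near_zero(self, rng):
        # independent labels with matched marginals: kappa -> 0 for large n
        a = rng.integers(0, 3, size=20000).tolist()
        b = rng.permutation(a).tolist()
        assert abs(cohen_kappa(a, b)) < 0.03

    def test_degenerate_marginals_signalled(self):
        with pytest.raises(ValidationError, match="undefined"):
            cohen_kappa(["a", "a"], ["a", "a"])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            cohen_kappa(["a"], ["a", "b"])


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        rep = classification_metrics(list("aabb"), list("aabb"))
        assert rep.macro_f1 == 1.0 and rep.micro_f1 == 1.0 and rep.accuracy == 1.0

    def test_binary_hand_computation(self):
        # positive class: TP=8, FP=2, FN=2 -> precision = recall = F1 = 0.8
        truth = ["p"] * 10 + ["n"] * 10
        pred = ["p"] * 8 + ["n"] * 2 + ["p"] * 2 + ["n"] * 8
        rep = classification_metrics(truth, pred)
        assert rep.per_class["p"].precision == pytest.approx(0.8)
        assert rep.per_class["p"].recall == pytest.approx(0.8)
        assert rep.per_class["p"].f1 == pytest.approx(0.8)

    def test_absent_class_flagged_undefined(self):
        # class "c" predicted but never true: recall defined, precision 0/.. fine;
        # class "d" true but never predicted: precision undefined
        rep = classification_metrics(["a", "a", "d"], ["a", "c", "a"])
        assert "d" in rep.undefined_classes or rep.per_class["d"].precision is None
        assert "c" in rep.undefined_classes or rep.per_class["c"].recall is None

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            classification_metrics(["a"], ["a", "b"])


class TestStarAccuracy:
    def test_identity(self):
        assert star_accuracy([1, 3, 5], [1, 3, 5]) == (1.0, 1.0)

    def test_hand_example(self):
        exact, within1 = star_accuracy([5, 1, 3], [4, 3, 3])
        assert exact == pytest.approx(1 / 3)
        assert within1 == pytest.approx(2 / 3)

    def test_shift_by_one(self):
        truth = [1, 2, 3, 4]
        pred = [2, 3, 4, 5]
        exact, within1 = star_accuracy(truth, pred)
        assert exact == 0.0 and within1 == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            star_accuracy([1, 2], [0, 2])
        with pytest.raises(ValidationError):
            star_accuracy([6], [5])

    @given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 5)), min_size=1, max_size=50))
    def test_within_one_rate_dominates_exact(self, pairs):
        truth = [t for t, _ in pairs]
        pred = [p for _, p in pairs]
        exact, within1 = star_accuracy(truth, pred)
        assert within1 >= exact
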