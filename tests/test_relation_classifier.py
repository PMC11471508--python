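"""D-Model training, evaluation metrics, Integrated Gradients, agreement."""

import io

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from meshkg import synth
from meshkg.matrix_builder import REDUCED_VOCAB, flatten, split_dataset
from meshkg.relation_classifier import (
    ASSIGNED,
    HEAD_DISAGREEMENT,
    NO_QUALIFIER_DATA,
    DModel,
    ModelConfig,
    agreement_filter,
    agreement_matrix,
    classify_candidates,
    compute_metrics,
    evaluate,
    integrated_gradients,
    pairwise_error_share,
    select_qualifiers,
    train_dmodel,
)


def labels_from_counts(tp, fp, fn, pos="pos", neg="neg"):
    """Construct label sequences realizing given one-vs-rest counts."""
    y_true = [pos] * tp + [pos] * fn + [neg] * fp + [neg] * 50
    y_pred = [pos] * tp + [neg] * fn + [pos] * fp + [neg] * 50
    return y_true, y_pred


class TestComputeMetrics:
    def test_symmetric_class_precision_and_recall_hand_counts(self):
        """Precision 90/118 and recall 90/109 from TP=90, FP=28, FN=19."""
        y_true, y_pred = labels_from_counts(tp=90, fp=28, fn=19)
        report = compute_metrics(y_true, y_pred)
        assert report.precision["pos"] == pytest.approx(90 / 118)
        assert report.recall["pos"] == pytest.approx(90 / 109)
        assert report.tp["pos"] == 90 and report.fp["pos"] == 28 and report.fn["pos"] == 19

    def test_matches_sklearn_on_random_multiclass_labels(self):
        rng = np.random.default_rng(0)
        y_true = list(rng.choice(["a", "b", "c"], size=300))
        y_pred = list(rng.choice(["a", "b", "c"], size=300))
        report = compute_metrics(y_true, y_pred, labels=("a", "b", "c"))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=["a", "b", "c"], zero_division=0
        )
        for i, label in enumerate(("a", "b", "c")):
            assert report.precision[label] == pytest.approx(p[i])
            assert report.recall[label] == pytest.approx(r[i])
            assert report.f1[label] == pytest.approx(f[i])

    def test_perfect_predictions(self):
        report = compute_metrics(["a", "b"] * 5, ["a", "b"] * 5)
        assert report.accuracy == 1.0
        assert all(v == 1.0 for v in report.f1.values())

    def test_confusion_identities(self):
        rng = np.random.default_rng(1)
        y_true = list(rng.choice(["a", "b", "c"], size=200))
        y_pred = list(rng.choice(["a", "b", "c"], size=200))
        report = compute_metrics(y_true, y_pred)
        assert report.confusion.sum() == 200
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / 200, abs=1e-12
        )
        for label in report.labels:
            assert report.tp[label] + report.fn[label] == y_true.count(label)

    def test_empty_prediction_class_reports_zero_with_flag(self):
        report = compute_metrics(["a", "a", "b"], ["a", "a", "a"])
        assert report.precision["b"] == 0.0
        assert "b" in report.zero_division_classes

    def test_pairwise_error_share(self):
        y_true = ["a"] * 5 + ["c"] * 4 + ["b"] * 1
        y_pred = ["c"] * 5 + ["a"] * 4 + ["a"] * 1
        report = compute_metrics(y_true, y_pred)
        assert pairwise_error_share(report, "a", "c") == pytest.approx(9 / 10)


class TestTraining:
    def test_separable_two_class_problem_reaches_high_dev_accuracy(self):
        hierarchy = {"T0": "Taxonomic", "T1": "BiomedicalSymmetric"}
        profiles = synth.disjoint_profiles(hierarchy, REDUCED_VOCAB, seed=11)
        data = synth.generate_labeled_matrices(250, profiles, hierarchy, seed=11)
        train, dev = data[:200], data[200:]
        model = train_dmodel(train, dev, ModelConfig(task="superclass", seed=0, epochs=40))
        report = evaluate(model, dev)
        assert report.accuracy >= 0.95

    def test_same_seed_gives_identical_parameters(self):
        hierarchy = {"T0": "Taxonomic", "T1": "BiomedicalSymmetric"}
        profiles = synth.disjoint_profiles(hierarchy, REDUCED_VOCAB, seed=12)
        data = synth.generate_labeled_matrices(120, profiles, hierarchy, seed=12)
        cfg = ModelConfig(task="superclass", seed=3, epochs=5)
        m1 = train_dmodel(data[:100], data[100:], cfg)
        m2 = train_dmodel(data[:100], data[100:], cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_single_class_training_data_is_rejected(self):
        hierarchy = {"T0": "Taxonomic"}
        profiles = synth.disjoint_profiles(hierarchy, REDUCED_VOCAB, seed=13)
        data = synth.generate_labeled_matrices(30, profiles, hierarchy, seed=13)
        with pytest.raises(ValueError, match="single class"):
            train_dmodel(data[:20], data[20:], ModelConfig(task="superclass"))

    def test_checkpoint_round_trip_preserves_predictions(self, superclass_model, matrix_dataset):
        splits, _ = matrix_dataset
        buf = io.StringIO()
        superclass_model.save(buf)
        buf.seek(0)
        clone = DModel.load(buf)
        X = np.stack([flatten(lm.matrix) for lm in splits.test[:20]])
        assert list(clone.predict(X)) == list(superclass_model.predict(X))


class _LinearScorer:
    """w . x scorer used as a closed-form Integrated-Gradients oracle."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def class_score(self, x, target):
        return float(self.w @ x)

    def class_score_grad(self, x, target):
        return self.w


class TestIntegratedGradients:
    def test_input_equal_to_baseline_gives_zero_attributions(self, superclass_model):
        x = np.zeros(900)
        attr = integrated_gradients(superclass_model, x, baseline=x, steps=10, target=0)
        assert np.allclose(attr, 0.0)

    def test_linear_scorer_is_exact_at_any_step_count(self):
        w = np.arange(6.0) - 2.0
        x = np.linspace(-1, 1, 6)
        for steps in (1, 3, 50):
            attr = integrated_gradients(_LinearScorer(w), x, steps=steps, target=0)
            assert np.allclose(attr, w * x)

    def test_completeness_error_below_one_percent_at_200_steps(
        self, superclass_model, matrix_dataset
    ):
        splits, _ = matrix_dataset
        x = superclass_model.preprocess(flatten(splits.test[0].matrix))
        target = int(np.argmax(superclass_model.logits(x)))
        delta = superclass_model.class_score(x, target) - superclass_model.class_score(
            np.zeros_like(x), target
        )
        attr = integrated_gradients(superclass_model, x, steps=200, target=target)
        assert abs(attr.sum() - delta) < 0.01 * abs(delta)

    def test_error_shrinks_as_steps_double(self, superclass_model, matrix_dataset):
        splits, _ = matrix_dataset
        x = superclass_model.preprocess(flatten(splits.test[1].matrix))
        target = int(np.argmax(superclass_model.logits(x)))
        delta = superclass_model.class_score(x, target) - superclass_model.class_score(
            np.zeros_like(x), target
        )
        errs = [
            abs(integrated_gradients(superclass_model, x, steps=s, target=target).sum() - delta)
            for s in (25, 100, 400)
        ]
        assert errs[2] < errs[0]


class TestSelectQualifiers:
    def test_union_size_bounded_by_classes_times_k(self, superclass_model, matrix_dataset, hierarchy8):
        splits, _ = matrix_dataset
        selected = select_qualifiers(superclass_model, list(splits.dev), hierarchy8, k=10, steps=20)
        assert 10 <= len(selected) <= 30
        assert selected <= set(REDUCED_VOCAB.names)

    def test_k_equal_one_single_class_is_the_argmax_qualifier(self, superclass_model, matrix_dataset):
        splits, _ = matrix_dataset
        sample = [lm for lm in splits.dev if lm.superclass == "Taxonomic"][:5]
        hierarchy = {"T0": "Taxonomic"}
        selected = select_qualifiers(superclass_model, sample, hierarchy, k=1, steps=20)
        # brute-force: recompute scores and take the argmax directly
        from meshkg.relation_classifier import qualifier_attribution_scores

        scores = np.zeros(REDUCED_VOCAB.size)
        for lm in sample:
            x = superclass_model.preprocess(flatten(lm.matrix))
            attr = integrated_gradients(superclass_model, x, steps=20)
            scores += qualifier_attribution_scores(attr, REDUCED_VOCAB)
        assert selected == {REDUCED_VOCAB.names[int(np.argmax(scores))]}


class TestAgreement:
    HIERARCHY = {"subclass of": "Taxonomic", "drug interaction": "BiomedicalSymmetric"}

    def test_filter_accepts_agreeing_heads(self):
        assert (
            agreement_filter("subclass of", "Taxonomic", self.HIERARCHY)
            == "subclass of"
        )

    def test_filter_rejects_disagreeing_heads(self):
        assert agreement_filter("subclass of", "BiomedicalNonSymmetric", self.HIERARCHY) is None

    def test_filter_requires_a_known_type(self):
        with pytest.raises(KeyError):
            agreement_filter("unknown type", "Taxonomic", self.HIERARCHY)

    def test_filter_never_accepts_a_mismatched_parent(self):
        superclasses = set(self.HIERARCHY.values()) | {"BiomedicalNonSymmetric"}
        for rtype, parent in self.HIERARCHY.items():
            for sc in superclasses:
                accepted = agreement_filter(rtype, sc, self.HIERARCHY)
                assert (accepted == rtype) == (sc == parent)

    def test_printed_agreement_counts_reproduce_published_rates(self):
        """3146/1004/353/101 over 4604 give 68.3 %, 2.2 %, 90.9 %, 77.8 %."""
        flags_type = [True] * 3146 + [False] * 1004 + [True] * 353 + [False] * 101
        flags_super = [True] * 3146 + [True] * 1004 + [False] * 353 + [False] * 101
        am = agreement_matrix(flags_type, flags_super)
        assert am.total == 4604
        assert am.both_correct_rate == pytest.approx(100 * 3146 / 4604)
        assert am.both_wrong_rate == pytest.approx(100 * 101 / 4604)
        assert am.type_error_detection_rate == pytest.approx(100 * 1004 / 1105)
        assert am.super_error_detection_rate == pytest.approx(100 * 353 / 454)
        assert am.total_type_wrong == 1004 + 101 == 1105
        assert am.total_super_wrong == 353 + 101 == 454

    def test_all_correct_flags(self):
        am = agreement_matrix([True] * 7, [True] * 7)
        assert (am.both_correct, am.type_wrong_only, am.super_wrong_only, am.both_wrong) == (7, 0, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement_matrix([True], [True, False])


@pytest.fixture(scope="module")
def pipeline():
    """A small corpus of profile-generated publications plus heads
    trained on matching matrices (reduced vocabulary throughout)."""
    hierarchy = {
        "P279": "Taxonomic",
        "P769": "BiomedicalSymmetric",
        "P2176": "BiomedicalNonSymmetric",
    }
    config = synth.default_config(seed=21)
    from dataclasses import replace

    config = replace(config, n_publications=8000)
    records, truth = synth.generate_corpus(config)
    data = synth.generate_labeled_matrices(
        900, config.type_profiles, hierarchy, seed=21
    )
    splits = split_dataset(data, seed=21)
    m_super = train_dmodel(splits.train, splits.dev, ModelConfig(task="superclass", seed=0, epochs=40))
    m_type = train_dmodel(splits.train, splits.dev, ModelConfig(task="type", seed=0, epochs=40))
    return hierarchy, config, records, truth, m_super, m_type


class TestClassifyCandidates:

    def test_planted_pairs_get_assigned_their_relation_type(self, pipeline):
        hierarchy, config, records, truth, m_super, m_type = pipeline
        candidates = [(r.x, r.y) for r in truth.planted if r.lift >= 8]
        out = classify_candidates(
            candidates, records, m_super, m_type, hierarchy,
            vocab=config.vocab, reduced_vocab=config.vocab,
        )
        expected = {(r.x, r.y): r.relation_type for r in truth.planted}
        assigned = [c for c in out if c.reason == ASSIGNED]
        assert len(assigned) >= len(candidates) * 2 // 3
        for c in assigned:
            assert c.relation_type == expected[c.pair]

    def test_pair_without_qualifier_publications_is_unclassified(self, pipeline):
        hierarchy, config, records, _, m_super, m_type = pipeline
        out = classify_candidates(
            [("KW9998", "KW9999")], records, m_super, m_type, hierarchy,
            vocab=config.vocab, reduced_vocab=config.vocab,
        )
        assert out[0].reason == NO_QUALIFIER_DATA
        assert out[0].relation_type is None
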