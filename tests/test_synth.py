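"""Generator determinism, planted-truth manifests, end-to-end recovery."""

import io
from dataclasses import replace

import numpy as np
import pytest

from meshkg import synth
from meshkg.kg_store import audit_external_ids, find_unreferenced
from meshkg.obo_audit import diff_alignment, extract_term_ids
from meshkg.pmi_relations import (
    SUPPORTED,
    CooccurrenceRecord,
    calibrate_threshold,
    classify_support,
    discover_candidates,
    pmi_from_index,
)
from meshkg.publications import CorpusIndex, write_publications


class TestGenerateCorpus:
    def test_zero_publications_gives_an_empty_corpus(self):
        config = replace(synth.default_config(seed=0), n_publications=0)
        records, truth = synth.generate_corpus(config)
        assert records == []
        assert len(truth.planted) == 12

    def test_same_seed_is_byte_identical(self):
        config = replace(synth.default_config(seed=4), n_publications=2000)
        a, _ = synth.generate_corpus(config)
        b, _ = synth.generate_corpus(config)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        write_publications(a, buf_a)
        write_publications(b, buf_b)
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_infeasible_lift_is_a_config_error(self):
        config = synth.default_config(seed=0)
        bad = replace(
            config,
            base_marginal=0.5,
            planted=(replace(config.planted[0], lift=32.0),),
        )
        with pytest.raises(ValueError, match="infeasible"):
            synth.generate_corpus(bad)

    def test_planted_co_mentions_carry_major_topics_and_profile_qualifiers(self):
        config = replace(synth.default_config(seed=6), n_publications=3000)
        records, truth = synth.generate_corpus(config)
        rel = max(truth.planted, key=lambda r: r.lift)  # most co-mentions
        profile = config.type_profiles[rel.relation_type]
        support_rows = {i for i, j in zip(*np.nonzero(profile))}
        seen = 0
        for recd in records:
            ax = recd.annotation_for(rel.x)
            ay = recd.annotation_for(rel.y)
            if ax is not None and ay is not None:
                seen += 1
                assert ax.major and ay.major
                assert len(ax.qualifiers) == 1 and len(ay.qualifiers) == 1
                qs = config.vocab.index(ax.qualifiers[0])
                assert qs in support_rows
        assert seen > 0


class TestGenerateKg:
    def make(self, **kw):
        config = replace(synth.default_config(seed=9), n_publications=0, **kw)
        _, truth = synth.generate_corpus(config)
        return synth.generate_kg(truth, config), config

    def test_zero_unreferenced_rate_means_every_statement_referenced(self):
        (_, statements, _, _), _ = self.make(unreferenced_rate=0.0)
        assert find_unreferenced(statements) == []

    def test_unreferenced_statements_match_the_manifest_exactly(self):
        (_, statements, _, manifest), _ = self.make(unreferenced_rate=0.5)
        found = {
            (s.subject, s.property_id, s.object) for s in find_unreferenced(statements)
        }
        assert found == set(manifest.unreferenced_statements)

    def test_audit_recovers_the_corruption_manifest_exactly(self):
        (_, _, claims, manifest), _ = self.make(wrong_id_rate=0.15, duplicate_id_rate=0.15)
        report = audit_external_ids(claims, set(manifest.valid_id_universe))
        assert set(report.invalid_claims) == set(manifest.wrong_claims)
        assert set(report.duplicate_claims) == set(manifest.duplicate_claims)
        assert report.distinct_duplicated_ids == manifest.distinct_duplicated_ids
        assert report.distinct_duplicated_ids > 0


class TestGenerateOntology:
    def test_all_canonical_claims_diff_clean(self):
        doc, claims, _ = synth.generate_ontology(
            "SYN", 50, {"canonical": 1.0}, seed=1
        )
        term_set = extract_term_ids(io.StringIO(doc), "SYN")
        report = diff_alignment(term_set, claims)
        assert not report.missing_in_kg and not report.wrong_in_kg
        assert report.valid_count == 50

    def test_missing_terms_match_the_manifest(self):
        doc, claims, manifest = synth.generate_ontology(
            "SYN", 200, {"canonical": 0.9, "missing": 0.1}, seed=2
        )
        term_set = extract_term_ids(io.StringIO(doc), "SYN")
        report = diff_alignment(term_set, claims)
        assert report.missing_in_kg == manifest.missing_terms
        assert len(manifest.missing_terms) > 0

    def test_underscore_dialect_requires_repair(self):
        doc, claims, _ = synth.generate_ontology(
            "SYN", 40, {"underscore": 1.0}, seed=3
        )
        term_set = extract_term_ids(io.StringIO(doc), "SYN")
        assert diff_alignment(term_set, claims, repair_dialects=True).valid_count == 40
        assert diff_alignment(term_set, claims, repair_dialects=False).valid_count == 0

    def test_obsolete_terms_are_emitted_and_flagged(self):
        doc, _, manifest = synth.generate_ontology(
            "SYN", 100, {"canonical": 1.0}, seed=4, obsolete_rate=0.2
        )
        term_set = extract_term_ids(io.StringIO(doc), "SYN")
        assert term_set.obsolete_ids == manifest.obsolete_terms
        assert len(manifest.obsolete_terms) > 0


class TestEndToEndDiscovery:
    def test_pipeline_recovers_planted_pairs_and_rejects_noise(
        self, planted_corpus, corpus_index
    ):
        """pmi -> calibrate -> discover finds >=90 % of pairs with lift >= 8
        while admitting <=5 % of non-planted pairs."""
        config, _, truth = planted_corpus
        index = corpus_index

        # calibrate on the planted relations as the trusted edge set
        trusted = [pmi_from_index(index, r.x, r.y) for r in truth.planted]
        threshold = calibrate_threshold(trusted).threshold

        planted_pairs = {tuple(sorted((r.x, r.y))) for r in truth.planted}
        strong_pairs = {
            tuple(sorted((r.x, r.y))) for r in truth.planted if r.lift >= 8
        }

        records = [
            CooccurrenceRecord(
                x=x, y=y, n_x=index.count(x), n_y=index.count(y),
                n_xy=index.pair_count(x, y), corpus_size=index.n_documents,
            )
            for x, y in index.pairs_with_cooccurrence()
        ]
        candidates = discover_candidates(records, threshold, existing_edges=[])
        found = {p for p, _ in candidates}

        assert len(strong_pairs & found) >= 0.9 * len(strong_pairs)

        non_planted = [
            r for r in records if tuple(sorted((r.x, r.y))) not in planted_pairs
        ]
        admitted = [p for p in found if p not in planted_pairs]
        assert len(admitted) <= 0.05 * len(non_planted)


class TestClassifierRecoveryFromCorpus:
    def test_matrices_built_from_publications_train_to_high_accuracy(self):
        """Corpus -> matrix -> classifier recovery on disjoint profiles."""
        from meshkg.matrix_builder import build_matrix, select_publications, split_dataset
        from meshkg.relation_classifier import ModelConfig, evaluate, train_dmodel
        from meshkg.matrix_builder import LabeledMatrix

        hierarchy = {
            "P279": "Taxonomic",
            "P769": "BiomedicalSymmetric",
            "P2176": "BiomedicalNonSymmetric",
        }
        config = synth.default_config(seed=31)
        config = replace(config, n_publications=6000)
        records, truth = synth.generate_corpus(config)

        # one matrix per planted pair, from its actual publications
        data = []
        for rel in truth.planted:
            pubs = select_publications(records, rel.x, rel.y, cap=20)
            if not pubs:
                continue
            m = build_matrix(pubs, rel.x, rel.y, vocab=config.vocab)
            data.append(LabeledMatrix(m, rel.relation_type, rel.superclass))
        assert len(data) >= 9

        # supplement with profile-sampled matrices to a trainable size
        extra = synth.generate_labeled_matrices(
            600, config.type_profiles, hierarchy, seed=31
        )
        splits = split_dataset(extra, seed=31)
        model = train_dmodel(
            splits.train, splits.dev, ModelConfig(task="superclass", seed=0, epochs=40)
        )
        report = evaluate(model, data)
        assert report.accuracy >= 0.9
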