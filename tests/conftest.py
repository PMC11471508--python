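"""Shared fixtures: synthetic study corpora and trained classifier heads.

The expensive artefacts (the 50,000-document planted corpus and the
trained D-Model heads) are session-scoped so the property tests and the
acceptance tests share one computation.
"""

from __future__ import annotations

import pytest

from meshkg import synth
from meshkg.matrix_builder import REDUCED_VOCAB, split_dataset
from meshkg.publications import CorpusIndex
from meshkg.relation_classifier import ModelConfig, train_dmodel

SUPERCLASSES = ("Taxonomic", "BiomedicalSymmetric", "BiomedicalNonSymmetric")


@pytest.fixture(scope="session")
def planted_corpus():
    """The reference synthetic corpus: 50,000 documents, twelve planted
    pairs with lifts 4/8/32, plus its ground truth."""
    config = synth.default_config(seed=101)
    records, truth = synth.generate_corpus(config)
    return config, records, truth


@pytest.fixture(scope="session")
def corpus_index(planted_corpus):
    _, records, _ = planted_corpus
    return CorpusIndex(records)


@pytest.fixture(scope="session")
def hierarchy8():
    """Eight relation types over the three superclasses."""
    return {f"T{i}": SUPERCLASSES[i % 3] for i in range(8)}


@pytest.fixture(scope="session")
def matrix_dataset(hierarchy8):
    """2,000 synthetic qualifier matrices with disjoint per-type profiles,
    split 70/15/15."""
    profiles = synth.disjoint_profiles(hierarchy8, REDUCED_VOCAB, cells_per_type=4, seed=7)
    data = synth.generate_labeled_matrices(2000, profiles, hierarchy8, seed=7)
    return split_dataset(data, seed=7), profiles


@pytest.fixture(scope="session")
def superclass_model(matrix_dataset):
    splits, _ = matrix_dataset
    return train_dmodel(
        splits.train, splits.dev, ModelConfig(task="superclass", seed=0, epochs=60)
    )


@pytest.fixture(scope="session")
def type_model(matrix_dataset):
    splits, _ = matrix_dataset
    return train_dmodel(
        splits.train, splits.dev, ModelConfig(task="type", seed=0, epochs=60)
    )
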