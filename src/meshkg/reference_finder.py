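"""Literature-reference assignment for unsupported KG statements.

For a statement whose subject and object both resolve to MeSH
descriptors, candidate supporting publications are those co-indexed with
*both* descriptors, restricted — mirroring evidence-based-medicine
practice — to review-type publications from the last five years. The
eligible candidates are ranked by Okapi BM25 over a bag-of-words document
representation (descriptor names, qualifier names and title tokens) with
the two descriptor names as the query, and the top five are proposed as
references.

Statements are then bucketed by how many references could be assigned
(0 / 1 / 2 / 3+), and unclassified relations are broken down by the first
letter of their MeSH tree codes (A Anatomy, C Diseases, D Chemicals and
Drugs, ...).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .publications import PublicationRecord

__all__ = [
    "SearchConfig",
    "RankedReference",
    "ReferenceBuckets",
    "TreeCategoryBreakdown",
    "BagOfWordsIndex",
    "MESH_TREE_CATEGORIES",
    "bm25_score",
    "find_references",
    "bucket_statements",
    "tree_category",
    "category_breakdown",
]


@dataclass(frozen=True)
class SearchConfig:
    """BM25 and eligibility parameters.

    ``reference_year`` anchors the recency window (a publication is recent
    iff year >= reference_year - recency_window_years); it is an explicit
    value, never the wall clock, so runs are reproducible.
    """

    k1: float = 1.2
    b: float = 0.75
    top_k: int = 5
    recency_window_years: int = 5
    reference_year: int = 2023
    require_review: bool = True

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError("k1 must be > 0")
        if not 0 <= self.b <= 1:
            raise ValueError("b must be in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class RankedReference:
    pub_id: str
    score: float
    rank: int  # 1-based


_TOKEN_RE = re.compile(r"[a-z0-9&]+")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def document_terms(record: PublicationRecord) -> list[str]:
    """The term bag of one publication: descriptor names, qualifier names
    and title tokens (descriptor/qualifier names are kept whole, lowercased)."""
    terms: list[str] = []
    for ann in record.annotations:
        terms.append(ann.descriptor.lower())
        terms.extend(q.lower() for q in ann.qualifiers)
    terms.extend(tokenize(record.title))
    return terms


class BagOfWordsIndex:
    """Corpus statistics for BM25: document frequencies, lengths, and the
    average document length."""

    def __init__(self, records: Iterable[PublicationRecord]):
        self.records: list[PublicationRecord] = list(records)
        if not self.records:
            raise ValueError("cannot index an empty corpus")
        self.term_bags: list[Counter[str]] = []
        self.doc_freq: Counter[str] = Counter()
        self.doc_len: list[int] = []
        for rec in self.records:
            bag = Counter(document_terms(rec))
            self.term_bags.append(bag)
            self.doc_freq.update(bag.keys())
            self.doc_len.append(sum(bag.values()))
        self.n_documents = len(self.records)
        self.avg_doc_len = sum(self.doc_len) / self.n_documents

    def idf(self, term: str) -> float:
        df = self.doc_freq.get(term, 0)
        return math.log((self.n_documents - df + 0.5) / (df + 0.5) + 1.0)


def bm25_score(
    query_terms: Sequence[str],
    doc_index: int,
    index: BagOfWordsIndex,
    config: SearchConfig = SearchConfig(),
) -> float:
    """Okapi BM25 of one document against a term query.

    score = sum_t idf(t) * tf * (k1 + 1) / (tf + k1*(1 - b + b*len/avglen))
    with idf(t) = ln((N - df + 0.5)/(df + 0.5) + 1); absent terms add 0.
    """
    bag = index.term_bags[doc_index]
    length_norm = config.k1 * (
        1.0 - config.b + config.b * index.doc_len[doc_index] / index.avg_doc_len
    )
    score = 0.0
    for term in query_terms:
        tf = bag.get(term, 0)
        if tf == 0:
            continue
        score += index.idf(term) * tf * (config.k1 + 1.0) / (tf + length_norm)
    return score


def _is_eligible(
    rec: PublicationRecord, subject: str, object_: str, config: SearchConfig
) -> bool:
    if config.require_review and not any("review" in t.lower() for t in rec.pub_types):
        return False
    if rec.year < config.reference_year - config.recency_window_years:
        return False
    descs = rec.descriptors()
    return subject in descs and object_ in descs


def find_references(
    subject_descriptor: str,
    object_descriptor: str,
    index: BagOfWordsIndex,
    config: SearchConfig = SearchConfig(),
) -> list[RankedReference]:
    """Top-k supporting publications for one statement.

    Eligibility (co-annotation with both descriptors, review type, recency
    window) is applied first; eligible documents are then ranked by BM25
    of the two-descriptor query, ties broken by ascending publication ID.
    """
    if not subject_descriptor or not object_descriptor:
        raise ValueError("subject and object descriptors must resolve to MeSH names")
    query = [subject_descriptor.lower(), object_descriptor.lower()]
    scored: list[tuple[float, str, int]] = []
    for i, rec in enumerate(index.records):
        if not _is_eligible(rec, subject_descriptor, object_descriptor, config):
            continue
        scored.append((bm25_score(query, i, index, config), rec.pub_id, i))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [
        RankedReference(pub_id=pid, score=s, rank=r + 1)
        for r, (s, pid, _) in enumerate(scored[: config.top_k])
    ]


@dataclass(frozen=True)
class ReferenceBuckets:
    """Statement counts by number of assigned references: 0 / 1 / 2 / 3+."""

    counts: Mapping[str, int]
    rates: Mapping[str, float]  # percentages

    @property
    def total(self) -> int:
        return sum(self.counts.values())


BUCKET_LABELS = ("0", "1", "2", "3+")


def bucket_statements(reference_counts: Sequence[int]) -> ReferenceBuckets:
    """Bucket statements by reference count; rates are percentages of the
    statement total."""
    if any(c < 0 for c in reference_counts):
        raise ValueError("reference counts must be >= 0")
    counts = {label: 0 for label in BUCKET_LABELS}
    for c in reference_counts:
        counts[BUCKET_LABELS[min(c, 3)]] += 1
    total = len(reference_counts)
    rates = {
        label: (100.0 * n / total if total else 0.0) for label, n in counts.items()
    }
    return ReferenceBuckets(counts=counts, rates=rates)


#: First letter of a MeSH tree code -> category label.
MESH_TREE_CATEGORIES: dict[str, str] = {
    "A": "Anatomy",
    "B": "Organisms",
    "C": "Diseases",
    "D": "Chemical and Drugs",
    "E": "Analytical, Diagnostic and Therapeutic Techniques and Equipment",
    "F": "Psychiatry and Psychology",
    "G": "Biological Sciences",
    "H": "Disciplines and Occupations",
    "I": "Anthropology, Education, Sociology, and Social Phenomena",
    "J": "Technology, Industry, and Agriculture",
    "K": "Humanities",
    "L": "Information Science",
    "M": "Named Groups",
    "N": "Health Care",
    "V": "Publication Characteristics",
    "Z": "Geographicals",
}


def tree_category(tree_code: str) -> tuple[str, str]:
    """Category letter and label of a MeSH tree code ("C04.557" -> C,
    Diseases). Letters without a curated label pass through letter-only."""
    if not tree_code:
        raise ValueError("tree code must be non-empty")
    letter = tree_code[0].upper()
    return letter, MESH_TREE_CATEGORIES.get(letter, letter)


@dataclass(frozen=True)
class TreeCategoryBreakdown:
    """Counts of relations per (subject-category, object-category) letter
    pair; rates are percentages of the relation total (not of pair
    assignments — one relation with several codes can hit several pairs)."""

    pair_counts: Mapping[tuple[str, str], int]
    rates: Mapping[tuple[str, str], float]
    n_relations: int
    n_skipped: int


def category_breakdown(
    relations_with_tree_codes: Sequence[tuple[Sequence[str], Sequence[str]]],
) -> TreeCategoryBreakdown:
    """Tally relations by the tree categories of their endpoints.

    Each element is (subject tree codes, object tree codes). A relation
    contributes one count to every *distinct* (subject-letter,
    object-letter) pair its codes span. Relations with no codes on either
    side are skipped and tallied.
    """
    pair_counts: Counter[tuple[str, str]] = Counter()
    n_relations = 0
    n_skipped = 0
    for subject_codes, object_codes in relations_with_tree_codes:
        if not subject_codes or not object_codes:
            n_skipped += 1
            continue
        n_relations += 1
        pairs = {
            (tree_category(sc)[0], tree_category(oc)[0])
            for sc in subject_codes
            for oc in object_codes
        }
        pair_counts.update(pairs)
    rates = {
        pair: 100.0 * n / n_relations if n_relations else 0.0
        for pair, n in pair_counts.items()
    }
    return TreeCategoryBreakdown(
        pair_counts=dict(pair_counts),
        rates=rates,
        n_relations=n_relations,
        n_skipped=n_skipped,
    )
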