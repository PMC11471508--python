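"""Subject x object MeSH-qualifier co-occurrence matrices.

For an entity pair (x, y) and a set of publications co-indexing both as
major topics, the qualifier matrix counts, over publications, how often
each (subject-qualifier, object-qualifier) combination is assigned: for a
publication where x carries qualifiers Qx and y carries Qy, every cell in
Qx x Qy is incremented once. The qualifier-assignment profile of a pair is
what discriminates relation types downstream.

Two vocabularies ship with the module: the full 76-name MeSH topical
subheading set, and the 30-name reduced set retained after Integrated
Gradients feature selection (the qualifiers ranking in the top ten for at
least one relation superclass). Matrices over the reduced set flatten to
length-900 feature vectors for the classifier.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .publications import PublicationRecord

__all__ = [
    "FULL_QUALIFIERS",
    "REDUCED_QUALIFIERS",
    "SUPERCLASSES",
    "QualifierVocabulary",
    "QualifierMatrix",
    "LabeledMatrix",
    "DatasetSplits",
    "VocabularyError",
    "select_publications",
    "build_matrix",
    "reduce_matrix",
    "flatten",
    "unflatten",
    "split_dataset",
]

logger = logging.getLogger(__name__)

#: The MeSH topical subheadings (qualifiers), 76 names.
FULL_QUALIFIERS: tuple[str, ...] = (
    "abnormalities", "administration & dosage", "adverse effects", "agonists",
    "analogs & derivatives", "analysis", "anatomy & histology",
    "antagonists & inhibitors", "biosynthesis", "blood", "blood supply",
    "cerebrospinal fluid", "chemical synthesis", "chemically induced",
    "chemistry", "classification", "complications", "congenital", "cytology",
    "deficiency", "diagnosis", "diagnostic imaging", "diet therapy",
    "drug effects", "drug therapy", "economics", "education", "embryology",
    "enzymology", "epidemiology", "ethics", "ethnology", "etiology",
    "genetics", "growth & development", "history", "immunology", "injuries",
    "innervation", "instrumentation", "isolation & purification",
    "legislation & jurisprudence", "metabolism", "methods", "microbiology",
    "mortality", "nursing", "organization & administration", "parasitology",
    "pathogenicity", "pathology", "pharmacokinetics", "pharmacology",
    "physiology", "physiopathology", "poisoning", "prevention & control",
    "psychology", "radiation effects", "radiotherapy", "rehabilitation",
    "secondary", "secretion", "standards", "statistics & numerical data",
    "surgery", "therapeutic use", "therapy", "toxicity", "transmission",
    "transplantation", "trends", "ultrastructure", "urine", "veterinary",
    "virology",
)

#: The 30 qualifiers that contribute to biomedical relation classification
#: (top-ten Integrated-Gradients features for at least one superclass).
REDUCED_QUALIFIERS: tuple[str, ...] = (
    "analysis", "pathology", "diagnosis", "etiology", "complications",
    "metabolism", "biosynthesis", "therapy", "drug therapy", "methods",
    "chemistry", "diagnostic imaging", "genetics", "physiopathology",
    "epidemiology", "blood", "pharmacology", "analogs & derivatives",
    "adverse effects", "therapeutic use", "surgery", "pharmacokinetics",
    "agonists", "ethnology", "administration & dosage", "drug effects",
    "enzymology", "physiology", "toxicity", "immunology",
)

#: The three relation superclasses of the filtered dataset.
SUPERCLASSES: tuple[str, ...] = (
    "Taxonomic",
    "BiomedicalSymmetric",
    "BiomedicalNonSymmetric",
)


class VocabularyError(KeyError):
    """A qualifier fell outside the active vocabulary."""


@dataclass(frozen=True)
class QualifierVocabulary:
    """An ordered qualifier name sequence; index = matrix row/column."""

    names: tuple[str, ...]
    vocab_id: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("qualifier names must be unique")

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise VocabularyError(f"qualifier not in vocabulary: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names


FULL_VOCAB = QualifierVocabulary(FULL_QUALIFIERS, vocab_id="mesh-76")
REDUCED_VOCAB = QualifierVocabulary(REDUCED_QUALIFIERS, vocab_id="reduced-30")


@dataclass(frozen=True)
class QualifierMatrix:
    """A q x q (subject-qualifier, object-qualifier) count matrix."""

    subject: str
    object: str
    counts: np.ndarray
    vocab: QualifierVocabulary
    n_publications: int

    def __post_init__(self) -> None:
        q = self.vocab.size
        if self.counts.shape != (q, q):
            raise ValueError(f"counts must be {q}x{q}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class LabeledMatrix:
    """A reduced qualifier matrix annotated with its relation type and the
    type's parent superclass."""

    matrix: QualifierMatrix
    relation_type: str
    superclass: str


@dataclass(frozen=True)
class DatasetSplits:
    train: tuple[LabeledMatrix, ...]
    dev: tuple[LabeledMatrix, ...]
    test: tuple[LabeledMatrix, ...]
    fractions: tuple[float, float, float]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.dev), len(self.test))


def select_publications(
    corpus: Iterable[PublicationRecord], x: str, y: str, cap: int = 20
) -> list[PublicationRecord]:
    """Pick up to ``cap`` publications usable for the pair's matrix.

    Eligible publications index *both* x and y as major topics with at
    least one qualifier each. The most recent publications are preferred
    (ties broken by ascending record ID) — recency mirrors the reference
    retriever's preference for current literature and makes the selection
    deterministic.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    eligible = []
    for rec in corpus:
        ax = rec.annotation_for(x)
        ay = rec.annotation_for(y)
        if ax is None or ay is None:
            continue
        if not (ax.major and ay.major):
            continue
        if not (ax.qualifiers and ay.qualifiers):
            continue
        eligible.append(rec)
    eligible.sort(key=lambda r: (-r.year, r.pub_id))
    return eligible[:cap]


def build_matrix(
    publications: Sequence[PublicationRecord],
    x: str,
    y: str,
    vocab: QualifierVocabulary = FULL_VOCAB,
) -> QualifierMatrix:
    """Accumulate the (subject-qualifier, object-qualifier) counts.

    For each publication, each qualifier pair in the cross product of x's
    and y's qualifier lists increments its cell by one. A qualifier outside
    ``vocab`` raises :class:`VocabularyError` naming it.
    """
    counts = np.zeros((vocab.size, vocab.size), dtype=np.int64)
    for rec in publications:
        ax = rec.annotation_for(x)
        ay = rec.annotation_for(y)
        if ax is None or ay is None or not (ax.qualifiers and ay.qualifiers):
            raise ValueError(
                f"publication {rec.pub_id} does not qualify for pair ({x}, {y})"
            )
        for qx in ax.qualifiers:
            i = vocab.index(qx)
            for qy in ay.qualifiers:
                counts[i, vocab.index(qy)] += 1
    return QualifierMatrix(
        subject=x, object=y, counts=counts, vocab=vocab,
        n_publications=len(publications),
    )


def reduce_matrix(
    matrix: QualifierMatrix, reduced_vocab: QualifierVocabulary = REDUCED_VOCAB
) -> QualifierMatrix:
    """Project a matrix onto a qualifier sub-vocabulary (rows and columns),
    output order following ``reduced_vocab``."""
    idx = np.array([matrix.vocab.index(name) for name in reduced_vocab.names])
    counts = matrix.counts[np.ix_(idx, idx)]
    return QualifierMatrix(
        subject=matrix.subject,
        object=matrix.object,
        counts=counts,
        vocab=reduced_vocab,
        n_publications=matrix.n_publications,
    )


def flatten(matrix: QualifierMatrix) -> np.ndarray:
    """Row-major flattening: index = q*row + column (900 for q=30)."""
    return matrix.counts.reshape(-1).astype(np.float64)


def unflatten(vector: np.ndarray, q: int) -> np.ndarray:
    if vector.size != q * q:
        raise ValueError(f"vector of length {vector.size} is not {q}x{q}")
    return vector.reshape(q, q)


def split_dataset(
    labeled_matrices: Sequence[LabeledMatrix],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DatasetSplits:
    """Shuffled train/dev/test split, stratified by relation type.

    Sizes are |train| = floor(f_train * N), |dev| = floor((N - |train|)/2),
    |test| = the remainder — so at the default fractions dev and test are
    equal up to one matrix. Stratification allocates each relation type
    proportionally (largest-remainder rounding); types with a single member
    fall back to pooled assignment with a logged warning.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(labeled_matrices)
    if n < 3:
        raise ValueError("need at least 3 matrices to split")

    n_train = int(np.floor(fractions[0] * n))
    n_dev = (n - n_train) // 2
    n_test = n - n_train - n_dev

    rng = np.random.default_rng(seed)

    by_type: dict[str, list[int]] = {}
    for i, lm in enumerate(labeled_matrices):
        by_type.setdefault(lm.relation_type, []).append(i)

    pooled: list[int] = []
    strata: list[list[int]] = []
    for rtype in sorted(by_type):
        members = by_type[rtype]
        if len(members) < 2:
            logger.warning(
                "relation type %r has a single matrix; unstratified assignment",
                rtype,
            )
            pooled.extend(members)
        else:
            strata.append(members)

    train_idx: list[int] = []
    dev_idx: list[int] = []
    test_idx: list[int] = []

    # Largest-remainder allocation of each stratum across the three splits.
    for members in strata:
        members = list(members)
        rng.shuffle(members)
        m = len(members)
        quotas = np.array([fractions[0] * m, fractions[1] * m, fractions[2] * m])
        base = np.floor(quotas).astype(int)
        rem = quotas - base
        for _ in range(m - base.sum()):
            j = int(np.argmax(rem))
            base[j] += 1
            rem[j] = -1
        a, b = base[0], base[0] + base[1]
        train_idx.extend(members[:a])
        dev_idx.extend(members[a:b])
        test_idx.extend(members[b:])

    pooled = list(pooled)
    rng.shuffle(pooled)
    train_idx.extend(pooled)

    # Rebalance to the exact floor sizes by moving from over-full splits.
    overflow: list[int] = []
    for bucket, target in ((train_idx, n_train), (dev_idx, n_dev), (test_idx, n_test)):
        while len(bucket) > target:
            overflow.append(bucket.pop())
    for bucket, target in ((train_idx, n_train), (dev_idx, n_dev), (test_idx, n_test)):
        while len(bucket) < target:
            bucket.append(overflow.pop())
    assert not overflow

    pick = lambda idxs: tuple(labeled_matrices[i] for i in sorted(idxs))
    return DatasetSplits(
        train=pick(train_idx),
        dev=pick(dev_idx),
        test=pick(test_idx),
        fractions=tuple(fractions),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Matrix archive I/O: one JSON record per labeled matrix.

def write_matrices(matrices: Iterable[LabeledMatrix], fh: IO[str]) -> int:
    n = 0
    for lm in matrices:
        fh.write(
            json.dumps(
                {
                    "subject": lm.matrix.subject,
                    "object": lm.matrix.object,
                    "relation_type": lm.relation_type,
                    "superclass": lm.superclass,
                    "vocab_id": lm.matrix.vocab.vocab_id,
                    "n_publications": lm.matrix.n_publications,
                    "counts": lm.matrix.counts.tolist(),
                },
                sort_keys=True,
            )
            + "\n"
        )
        n += 1
    return n


_KNOWN_VOCABS = {"mesh-76": FULL_VOCAB, "reduced-30": REDUCED_VOCAB}


def read_matrices(
    fh: IO[str], vocab: QualifierVocabulary | None = None
) -> list[LabeledMatrix]:
    out = []
    for line in fh:
        line = line.strip()
        if not line:
            continue
        d = json.loads(line)
        v = vocab or _KNOWN_VOCABS.get(d.get("vocab_id", ""), None)
        counts = np.asarray(d["counts"], dtype=np.int64)
        if v is None:
            v = QualifierVocabulary(
                tuple(f"q{i}" for i in range(counts.shape[0])),
                vocab_id=d.get("vocab_id", "unknown"),
            )
        out.append(
            LabeledMatrix(
                matrix=QualifierMatrix(
                    subject=d["subject"],
                    object=d["object"],
                    counts=counts,
                    vocab=v,
                    n_publications=int(d.get("n_publications", 0)),
                ),
                relation_type=d["relation_type"],
                superclass=d["superclass"],
            )
        )
    return out
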