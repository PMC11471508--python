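"""MEDLINE-like publication records and corpus-level counting.

A :class:`PublicationRecord` mirrors the parts of a MEDLINE citation this
toolkit consumes: the accession ID, publication year, publication types
(e.g. ``"Review"``, ``"Clinical Trial"``), and the MeSH indexing — one
:class:`MeshAnnotation` per descriptor, carrying the attached qualifiers
(subheadings), the major-topic flag and the descriptor's tree codes.

Corpora are streamed as JSONL, one record per line.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "MeshAnnotation",
    "PublicationRecord",
    "CorpusIndex",
    "read_publications",
    "write_publications",
]


@dataclass(frozen=True)
class MeshAnnotation:
    """One MeSH descriptor attached to a publication."""

    descriptor: str
    qualifiers: tuple[str, ...] = ()
    major: bool = False
    tree_codes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "descriptor": self.descriptor,
            "qualifiers": list(self.qualifiers),
            "major": self.major,
            "tree_codes": list(self.tree_codes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MeshAnnotation":
        return cls(
            descriptor=d["descriptor"],
            qualifiers=tuple(d.get("qualifiers", ())),
            major=bool(d.get("major", False)),
            tree_codes=tuple(d.get("tree_codes", ())),
        )


@dataclass(frozen=True)
class PublicationRecord:
    """One MEDLINE-like citation restricted to the fields the pipeline uses."""

    pub_id: str
    year: int
    pub_types: tuple[str, ...] = ()
    annotations: tuple[MeshAnnotation, ...] = ()
    title: str = ""

    def descriptors(self) -> set[str]:
        return {a.descriptor for a in self.annotations}

    def annotation_for(self, descriptor: str) -> MeshAnnotation | None:
        for a in self.annotations:
            if a.descriptor == descriptor:
                return a
        return None

    def to_dict(self) -> dict:
        return {
            "pub_id": self.pub_id,
            "year": self.year,
            "pub_types": list(self.pub_types),
            "annotations": [a.to_dict() for a in self.annotations],
            "title": self.title,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PublicationRecord":
        return cls(
            pub_id=d["pub_id"],
            year=int(d["year"]),
            pub_types=tuple(d.get("pub_types", ())),
            annotations=tuple(
                MeshAnnotation.from_dict(a) for a in d.get("annotations", ())
            ),
            title=d.get("title", ""),
        )


def write_publications(records: Iterable[PublicationRecord], fh: IO[str]) -> int:
    n = 0
    for rec in records:
        fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")
        n += 1
    return n


def read_publications(fh: IO[str]) -> Iterator[PublicationRecord]:
    for line in fh:
        line = line.strip()
        if line:
            yield PublicationRecord.from_dict(json.loads(line))


class CorpusIndex:
    """Exact document-count index over a publication corpus.

    Counts how many documents mention each descriptor and each unordered
    descriptor pair; these are the N(x), N(y), N(x,y) and R quantities that
    feed pointwise mutual information. Counting is per-document (a
    descriptor mentioned once or thrice in one record counts one document).
    """

    def __init__(self, records: Iterable[PublicationRecord]):
        self._doc_counts: Counter[str] = Counter()
        self._pair_counts: Counter[tuple[str, str]] = Counter()
        self.n_documents = 0
        for rec in records:
            self.n_documents += 1
            descs = sorted(rec.descriptors())
            self._doc_counts.update(descs)
            self._pair_counts.update(combinations(descs, 2))

    def count(self, descriptor: str) -> int:
        return self._doc_counts.get(descriptor, 0)

    def pair_count(self, x: str, y: str) -> int:
        key = (x, y) if x <= y else (y, x)
        return self._pair_counts.get(key, 0)

    def descriptors(self) -> list[str]:
        return sorted(self._doc_counts)

    def pairs_with_cooccurrence(self) -> list[tuple[str, str]]:
        """All unordered descriptor pairs seen together in >=1 document."""
        return sorted(self._pair_counts)
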