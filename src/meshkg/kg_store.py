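"""Data model and I/O for knowledge-graph exports.

Statements are subject–property–object triples with an attached (possibly
empty) reference list, as exported from a Wikidata-style collaborative
knowledge graph. Two ingest formats are supported:

* W3C SPARQL SELECT result JSON (the shape returned by query services),
  ingest-only;
* JSONL statement dumps (one statement per line), read and written, which
  is the storage format for desk-scale processing without a triple store.

The module also hosts the two statement-level audits the enrichment
pipeline needs: finding unreferenced ("unsupported") statements, and
auditing external-identifier claims for invalid and duplicated raw IDs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "EntityRecord",
    "StatementRecord",
    "ExternalIdClaim",
    "ExternalIdAuditReport",
    "ParseError",
    "SchemaError",
    "load_statements",
    "read_statements_jsonl",
    "write_statements_jsonl",
    "find_unreferenced",
    "audit_external_ids",
]


class ParseError(ValueError):
    """A document row could not be interpreted as a statement."""


class SchemaError(ValueError):
    """The document's variable layout is not one this reader understands."""


@dataclass(frozen=True)
class EntityRecord:
    """A KG entity: external-ID claims plus per-language lexicalisations.

    ``labels``/``descriptions``/``aliases`` map a lowercase BCP-47-like
    language tag to the set of strings recorded for that language.
    """

    entity_id: str
    external_ids: Mapping[str, str] = field(default_factory=dict)
    labels: Mapping[str, frozenset[str]] = field(default_factory=dict)
    descriptions: Mapping[str, frozenset[str]] = field(default_factory=dict)
    aliases: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")


@dataclass(frozen=True)
class StatementRecord:
    """One triple. ``references`` is always a sequence; "no reference" is
    the empty sequence, never an absent field."""

    subject: str
    property_id: str
    object: str
    object_is_literal: bool = False
    object_datatype: str | None = None
    references: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.subject or not self.property_id:
            raise ValueError("subject and property_id must be non-empty")

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "property_id": self.property_id,
            "object": self.object,
            "object_is_literal": self.object_is_literal,
            "object_datatype": self.object_datatype,
            "references": list(self.references),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StatementRecord":
        return cls(
            subject=d["subject"],
            property_id=d["property_id"],
            object=d["object"],
            object_is_literal=bool(d.get("object_is_literal", False)),
            object_datatype=d.get("object_datatype"),
            references=tuple(d.get("references", ())),
        )


@dataclass(frozen=True)
class ExternalIdClaim:
    """One external-identifier claim: entity -> (catalog, raw identifier)."""

    entity_id: str
    catalog: str
    raw_id: str


# Variable names accepted for each triple role in SPARQL SELECT results.
# Query exports name the roles ?subject / ?prop / ?object.
_ROLE_VARS = {
    "subject": ("subject", "s", "item"),
    "property_id": ("prop", "property", "p"),
    "object": ("object", "o", "value"),
}


def _entity_id_from_binding(binding: Mapping) -> str:
    """Strip a Wikidata-style entity URI down to its local Q/P-number."""
    value = binding["value"]
    if binding.get("type") == "uri" and "/" in value:
        return value.rstrip("/").rsplit("/", 1)[-1]
    return value


def load_statements(document: Mapping) -> list[StatementRecord]:
    """Read statements from a W3C SPARQL SELECT result JSON document.

    One :class:`StatementRecord` per binding row, order preserved. A row
    missing any required variable raises :class:`ParseError` naming the
    offending row; a document without the SELECT-result structure raises
    :class:`SchemaError`.
    """
    try:
        declared = list(document["head"]["vars"])
        bindings = document["results"]["bindings"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"not a SPARQL SELECT result document: {exc}") from exc

    roles: dict[str, str] = {}
    for role, candidates in _ROLE_VARS.items():
        for var in candidates:
            if var in declared:
                roles[role] = var
                break
        else:
            raise SchemaError(
                f"no declared variable for the {role} role among {declared}"
            )

    statements: list[StatementRecord] = []
    for i, row in enumerate(bindings):
        fields: dict[str, str] = {}
        for role, var in roles.items():
            if var not in row:
                raise ParseError(f"binding row {i} lacks required variable ?{var}")
            fields[role] = _entity_id_from_binding(row[var])
        obj_binding = row[roles["object"]]
        is_literal = obj_binding.get("type") == "literal"
        statements.append(
            StatementRecord(
                subject=fields["subject"],
                property_id=fields["property_id"],
                object=fields["object"],
                object_is_literal=is_literal,
                object_datatype=obj_binding.get("datatype"),
                references=(),
            )
        )
    return statements


def write_statements_jsonl(statements: Iterable[StatementRecord], fh: IO[str]) -> int:
    n = 0
    for st in statements:
        fh.write(json.dumps(st.to_dict(), sort_keys=True) + "\n")
        n += 1
    return n


def read_statements_jsonl(fh: IO[str]) -> Iterator[StatementRecord]:
    for i, line in enumerate(fh):
        line = line.strip()
        if not line:
            continue
        try:
            yield StatementRecord.from_dict(json.loads(line))
        except (json.JSONDecodeError, KeyError) as exc:
            raise ParseError(f"malformed statement on line {i + 1}: {exc}") from exc


def find_unreferenced(statements: Sequence[StatementRecord]) -> list[StatementRecord]:
    """The statements whose reference sequence is empty, input order kept."""
    return [st for st in statements if not st.references]


@dataclass(frozen=True)
class ExternalIdAuditReport:
    """Outcome of auditing one catalog's claims against its ID universe."""

    invalid_claims: tuple[ExternalIdClaim, ...]
    duplicate_claims: tuple[ExternalIdClaim, ...]
    distinct_duplicated_ids: int

    @property
    def n_invalid(self) -> int:
        return len(self.invalid_claims)

    @property
    def n_duplicate(self) -> int:
        return len(self.duplicate_claims)


def audit_external_ids(
    claims: Sequence[ExternalIdClaim], valid_id_set: set[str]
) -> ExternalIdAuditReport:
    """Audit claims of one catalog against the authoritative ID universe.

    invalid = claims whose raw_id is outside ``valid_id_set``; duplicate =
    claims sharing a raw_id with a claim on a *different* entity (counted
    pairwise-symmetrically: every claim involved is reported).
    """
    invalid = tuple(c for c in claims if c.raw_id not in valid_id_set)

    entities_per_id: dict[str, set[str]] = {}
    for c in claims:
        entities_per_id.setdefault(c.raw_id, set()).add(c.entity_id)
    duplicated_ids = {rid for rid, ents in entities_per_id.items() if len(ents) > 1}
    duplicates = tuple(c for c in claims if c.raw_id in duplicated_ids)

    return ExternalIdAuditReport(
        invalid_claims=invalid,
        duplicate_claims=duplicates,
        distinct_duplicated_ids=len(duplicated_ids),
    )
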