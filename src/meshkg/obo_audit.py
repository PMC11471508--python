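"""Ontology–knowledge-graph identifier alignment auditing.

Given an OBO ontology's term-ID universe and a KG's external-ID claims for
the same catalog, this module finds terms missing from the KG, claims that
match no term ("wrong IDs"), and claims written in a recognisable but
non-canonical identifier dialect — the two dialects observed in the wild
being the underscore form (``CLO_0000031`` for ``CLO:0000031``) and the
bare form (local ID with the prefix omitted entirely). It also produces
per-language label/description/alias censuses and a cross-ontology
relation census for KG statements.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import obonet
import pandas as pd

from .kg_store import EntityRecord, ExternalIdClaim, StatementRecord

__all__ = [
    "OntologyTermSet",
    "DialectDiagnosis",
    "AlignmentReport",
    "LanguageCensus",
    "RelationCensus",
    "OboParseError",
    "extract_term_ids",
    "normalize_identifier",
    "diff_alignment",
    "qualifies_for_enrichment",
    "language_census",
    "relation_census",
]

logger = logging.getLogger(__name__)

#: Default minimum number of valid KG identifiers an ontology must have to
#: qualify for KG-based semantic enrichment.
DEFAULT_MIN_VALID_IDS = 100


class OboParseError(ValueError):
    """The OBO document could not be parsed into term stanzas."""


@dataclass(frozen=True)
class OntologyTermSet:
    """The term-ID universe of one ontology under one CURIE prefix."""

    prefix: str
    term_ids: frozenset[str]
    obsolete_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = [t for t in self.term_ids if not t.startswith(self.prefix + ":")]
        if bad:
            raise ValueError(f"term ids not under prefix {self.prefix!r}: {bad[:3]}")
        if not self.obsolete_ids <= self.term_ids:
            raise ValueError("obsolete_ids must be a subset of term_ids")


@dataclass(frozen=True)
class DialectDiagnosis:
    """How a raw KG identifier relates to the canonical CURIE form."""

    raw_id: str
    canonical: str | None
    dialect: str  # canonical | underscore | bare | unrecognized


@dataclass(frozen=True)
class AlignmentReport:
    """Outcome of diffing an ontology term set against KG claims."""

    prefix: str
    missing_in_kg: frozenset[str]
    wrong_in_kg: frozenset[str]
    obsolete_matched: frozenset[str]
    valid_count: int
    n_claims: int
    dialect_tallies: Mapping[str, int]


def extract_term_ids(ontology_document: str | IO[str], prefix: str) -> OntologyTermSet:
    """Extract the [Term] stanza IDs matching ``prefix`` from an OBO file.

    Obsolete terms are included in ``term_ids`` and additionally flagged in
    ``obsolete_ids`` — an obsolete identifier still claimed by the KG is a
    distinct audit finding, not an unknown ID.
    """
    try:
        graph = obonet.read_obo(ontology_document, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError/KeyError
        raise OboParseError(f"cannot parse OBO document: {exc}") from exc

    term_ids = set()
    obsolete = set()
    for node, data in graph.nodes(data=True):
        if not node.startswith(prefix + ":"):
            continue
        term_ids.add(node)
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
    if not term_ids:
        logger.warning("no [Term] stanzas under prefix %r", prefix)
    return OntologyTermSet(
        prefix=prefix, term_ids=frozenset(term_ids), obsolete_ids=frozenset(obsolete)
    )


def normalize_identifier(raw_id: str, prefix: str) -> DialectDiagnosis:
    """Diagnose and repair the identifier dialect of one raw KG ID.

    ``PREFIX:LOCAL`` is canonical; ``PREFIX_LOCAL`` is the underscore
    dialect; a bare local ID (prefix omitted) is the bare dialect. Local
    IDs are kept verbatim — no zero-padding normalisation. Anything else
    is unrecognized (a value, not an error).
    """
    if not prefix:
        raise ValueError("prefix must be non-empty")
    if raw_id.startswith(prefix + ":"):
        local = raw_id[len(prefix) + 1 :]
        if local:
            return DialectDiagnosis(raw_id, raw_id, "canonical")
    if raw_id.startswith(prefix + "_"):
        local = raw_id[len(prefix) + 1 :]
        if local:
            return DialectDiagnosis(raw_id, f"{prefix}:{local}", "underscore")
    if raw_id and re.fullmatch(r"[A-Za-z0-9.\-]+", raw_id) and ":" not in raw_id:
        return DialectDiagnosis(raw_id, f"{prefix}:{raw_id}", "bare")
    return DialectDiagnosis(raw_id, None, "unrecognized")


def diff_alignment(
    term_set: OntologyTermSet,
    claims: Sequence[ExternalIdClaim],
    repair_dialects: bool = False,
) -> AlignmentReport:
    """Diff the ontology's term universe against the KG's claims.

    With ``repair_dialects`` off, a claim is valid iff its raw_id is a term
    ID verbatim; with repair on, validity is tested after
    :func:`normalize_identifier`. Claims matching an obsolete term count as
    valid but are tallied separately in ``obsolete_matched``.
    """
    matched_terms: set[str] = set()
    wrong: set[str] = set()
    obsolete_matched: set[str] = set()
    tallies: Counter[str] = Counter()
    valid_count = 0

    for claim in claims:
        diag = normalize_identifier(claim.raw_id, term_set.prefix)
        candidate = diag.canonical if repair_dialects else claim.raw_id
        if candidate is not None and candidate in term_set.term_ids:
            valid_count += 1
            matched_terms.add(candidate)
            tallies[diag.dialect] += 1
            if candidate in term_set.obsolete_ids:
                obsolete_matched.add(candidate)
        else:
            wrong.add(claim.raw_id)
            tallies["unmatched"] += 1

    return AlignmentReport(
        prefix=term_set.prefix,
        missing_in_kg=frozenset(term_set.term_ids - matched_terms),
        wrong_in_kg=frozenset(wrong),
        obsolete_matched=frozenset(obsolete_matched),
        valid_count=valid_count,
        n_claims=len(claims),
        dialect_tallies=dict(tallies),
    )


def qualifies_for_enrichment(
    report: AlignmentReport, min_valid: int = DEFAULT_MIN_VALID_IDS
) -> bool:
    """Whether the ontology has enough valid KG identifiers (boundary
    inclusive: exactly ``min_valid`` qualifies)."""
    if min_valid < 0:
        raise ValueError("min_valid must be >= 0")
    return report.valid_count >= min_valid


@dataclass(frozen=True)
class LanguageCensus:
    """Per-language counts of labels, descriptions and aliases, with the
    languages whose count strictly exceeds each field's threshold."""

    label_counts: Mapping[str, int]
    description_counts: Mapping[str, int]
    alias_counts: Mapping[str, int]
    significant_label_languages: frozenset[str]
    significant_description_languages: frozenset[str]
    significant_alias_languages: frozenset[str]

    @property
    def total_labels(self) -> int:
        return sum(self.label_counts.values())

    @property
    def total_descriptions(self) -> int:
        return sum(self.description_counts.values())

    @property
    def total_aliases(self) -> int:
        return sum(self.alias_counts.values())


def _count_field(
    records: Iterable[EntityRecord], attr: str
) -> Counter[str]:
    counts: Counter[str] = Counter()
    for rec in records:
        for lang, values in getattr(rec, attr).items():
            counts[lang] += len(values)
    return counts


def language_census(
    entity_records: Sequence[EntityRecord],
    label_threshold: int = 50,
    description_threshold: int = 50,
    alias_threshold: int = 100,
) -> LanguageCensus:
    """Census of label/description/alias coverage per language.

    A language is significant for a field iff its count *strictly* exceeds
    that field's threshold.
    """
    for t in (label_threshold, description_threshold, alias_threshold):
        if t < 0:
            raise ValueError("thresholds must be >= 0")
    labels = _count_field(entity_records, "labels")
    descriptions = _count_field(entity_records, "descriptions")
    aliases = _count_field(entity_records, "aliases")
    return LanguageCensus(
        label_counts=dict(labels),
        description_counts=dict(descriptions),
        alias_counts=dict(aliases),
        significant_label_languages=frozenset(
            l for l, c in labels.items() if c > label_threshold
        ),
        significant_description_languages=frozenset(
            l for l, c in descriptions.items() if c > description_threshold
        ),
        significant_alias_languages=frozenset(
            l for l, c in aliases.items() if c > alias_threshold
        ),
    )


@dataclass(frozen=True)
class RelationCensus:
    """Pairwise (subject-ontology, object-ontology) statement counts plus
    top-k property tallies split into same- vs cross-ontology."""

    pair_counts: Mapping[tuple[str, str], int]
    top_properties_same: tuple[tuple[str, int], ...]
    top_properties_cross: tuple[tuple[str, int], ...]
    n_resolvable: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_ontology": s, "object_ontology": o, "relations": c}
            for (s, o), c in sorted(self.pair_counts.items())
        ]
        return pd.DataFrame(rows, columns=["subject_ontology", "object_ontology", "relations"])


def relation_census(
    statements: Sequence[StatementRecord],
    entity_to_ontology: Mapping[str, str],
    top_k: int = 4,
) -> RelationCensus:
    """Tally KG statements by the ontologies their endpoints resolve to.

    ``entity_to_ontology`` maps a KG entity ID to the (single) ontology it
    is aligned with; statements whose subject or object does not resolve
    are ignored. Top-k properties are ranked by count; ties break toward
    the lexicographically smaller property ID.
    """
    pair_counts: Counter[tuple[str, str]] = Counter()
    props_same: Counter[str] = Counter()
    props_cross: Counter[str] = Counter()
    resolvable = 0
    for st in statements:
        s_ont = entity_to_ontology.get(st.subject)
        o_ont = entity_to_ontology.get(st.object)
        if s_ont is None or o_ont is None:
            continue
        resolvable += 1
        pair_counts[(s_ont, o_ont)] += 1
        (props_same if s_ont == o_ont else props_cross)[st.property_id] += 1

    def top(counter: Counter[str]) -> tuple[tuple[str, int], ...]:
        return tuple(sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k])

    return RelationCensus(
        pair_counts=dict(pair_counts),
        top_properties_same=top(props_same),
        top_properties_cross=top(props_cross),
        n_resolvable=resolvable,
    )


def alignment_report_frame(reports: Sequence[AlignmentReport], term_sets: Mapping[str, OntologyTermSet]) -> pd.DataFrame:
    """Tabular coverage report: one row per ontology, with item counts,
    KG claim counts, and missing/wrong tallies."""
    rows = []
    for rep in reports:
        ts = term_sets[rep.prefix]
        rows.append(
            {
                "ontology": rep.prefix,
                "ontology_items": len(ts.term_ids),
                "kg_items": rep.n_claims,
                "missing_in_kg": len(rep.missing_in_kg),
                "wrong_in_kg": len(rep.wrong_in_kg),
                "valid": rep.valid_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["ontology", "ontology_items", "kg_items", "missing_in_kg", "wrong_in_kg", "valid"],
    )
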