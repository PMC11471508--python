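"""Synthetic corpora, knowledge graphs and ontologies with planted truth.

Every pipeline stage is testable offline against generators whose ground
truth is known by construction:

* **Corpus generator** — publications sample keyword mentions from
  per-keyword marginal probabilities; a *planted* keyword pair (x, y)
  with lift lambda co-occurs with probability lambda*p_x*p_y while its
  marginals stay p_x and p_y (a lifted-independence model), so the
  expected pointwise mutual information of a planted pair is exactly
  log2(lambda). On planted co-mentions, a (subject-qualifier,
  object-qualifier) cell is drawn from the pair's relation-type profile
  and attached as major-topic indexing — the signal the qualifier-matrix
  classifier learns.
* **KG generator** — one statement per planted relation, with configured
  fractions left unreferenced and external-ID claims corrupted (wrong or
  duplicated raw IDs); a manifest records every corruption so audits are
  checked by equality, not statistics.
* **Ontology generator** — an OBO document plus KG claims written in
  configured identifier dialects, again with a manifest.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kg_store import EntityRecord, ExternalIdClaim, StatementRecord
from .matrix_builder import (
    REDUCED_VOCAB,
    LabeledMatrix,
    QualifierMatrix,
    QualifierVocabulary,
)
from .publications import MeshAnnotation, PublicationRecord

__all__ = [
    "PlantedRelation",
    "SimulationConfig",
    "GroundTruth",
    "KgCorruptionManifest",
    "OntologyManifest",
    "generate_corpus",
    "generate_kg",
    "generate_ontology",
    "generate_labeled_matrices",
    "disjoint_profiles",
    "default_config",
]

#: Tree-category letters assigned round-robin to synthetic keywords.
_TREE_LETTERS = ("A", "C", "D", "E", "G", "N")


@dataclass(frozen=True)
class PlantedRelation:
    """A ground-truth relation between two keywords."""

    x: str
    y: str
    lift: float
    relation_type: str
    superclass: str

    @property
    def expected_pmi(self) -> float:
        return math.log2(self.lift)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic corpus and KG.

    Defaults encode the regime the pipeline is characterised in: a
    50,000-document corpus over keywords with 1 % marginal mention
    probability, association lifts of 4–32 on planted pairs, a review
    share of 10 % (reviews are a minority of the literature), and
    publication years spanning the decade up to the 2023 reference year.
    """

    n_keywords: int = 60
    n_publications: int = 50_000
    base_marginal: float = 0.01
    planted: tuple[PlantedRelation, ...] = ()
    #: per relation type: distribution over (subject-qualifier,
    #: object-qualifier) cells, shape (q, q), summing to 1.
    type_profiles: Mapping[str, np.ndarray] = field(default_factory=dict)
    vocab: QualifierVocabulary = REDUCED_VOCAB
    year_range: tuple[int, int] = (2014, 2023)
    review_probability: float = 0.10
    #: chance that a non-planted mention carries a random qualifier / is major
    stray_qualifier_rate: float = 0.3
    stray_major_rate: float = 0.5
    wrong_id_rate: float = 0.0
    duplicate_id_rate: float = 0.0
    unreferenced_rate: float = 0.0
    seed: int = 0

    def keyword_names(self) -> list[str]:
        return [f"KW{i:04d}" for i in range(self.n_keywords)]

    def validate(self) -> None:
        if not 0 <= self.base_marginal <= 1:
            raise ValueError("base_marginal must be a probability")
        for rel in self.planted:
            p11 = rel.lift * self.base_marginal * self.base_marginal
            if p11 > min(self.base_marginal, 1.0):
                raise ValueError(
                    f"infeasible lift for pair ({rel.x}, {rel.y}): "
                    f"lambda*p_x*p_y = {p11} exceeds a marginal"
                )
        for rtype, profile in self.type_profiles.items():
            p = np.asarray(profile)
            if p.shape != (self.vocab.size, self.vocab.size):
                raise ValueError(f"profile for {rtype!r} has shape {p.shape}")
            if abs(float(p.sum()) - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError(f"profile for {rtype!r} is not a distribution")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for equality checks downstream."""

    planted: tuple[PlantedRelation, ...]
    keyword_tree_codes: Mapping[str, tuple[str, ...]]
    expected_pmi: Mapping[tuple[str, str], float]


def _keyword_tree_codes(names: Sequence[str]) -> dict[str, tuple[str, ...]]:
    return {
        name: (f"{_TREE_LETTERS[i % len(_TREE_LETTERS)]}{(i % 20) + 1:02d}.{i:03d}",)
        for i, name in enumerate(names)
    }


def generate_corpus(
    config: SimulationConfig,
) -> tuple[list[PublicationRecord], GroundTruth]:
    """Sample a corpus under the lifted-independence co-mention model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.keyword_names()
    n, m = config.n_publications, config.n_keywords
    p = config.base_marginal

    planted_members: set[str] = set()
    for rel in config.planted:
        if rel.x in planted_members or rel.y in planted_members:
            raise ValueError("a keyword may belong to at most one planted pair")
        planted_members.update((rel.x, rel.y))
        if rel.x not in names or rel.y not in names:
            raise ValueError("planted pair references an unknown keyword")

    name_idx = {name: i for i, name in enumerate(names)}
    present = np.zeros((n, m), dtype=bool)

    # Independent keywords.
    free = [i for i, name in enumerate(names) if name not in planted_members]
    if free:
        present[:, free] = rng.random((n, len(free))) < p

    # Planted pairs: joint (x, y) categories preserving the marginals.
    co_mention: dict[tuple[str, str], np.ndarray] = {}
    for rel in config.planted:
        p11 = rel.lift * p * p
        p10 = p - p11
        p01 = p - p11
        u = rng.random(n)
        both = u < p11
        only_x = (u >= p11) & (u < p11 + p10)
        only_y = (u >= p11 + p10) & (u < p11 + p10 + p01)
        ix, iy = name_idx[rel.x], name_idx[rel.y]
        present[:, ix] = both | only_x
        present[:, iy] = both | only_y
        co_mention[(rel.x, rel.y)] = both

    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)
    is_review = rng.random(n) < config.review_probability
    tree_codes = _keyword_tree_codes(names)

    # Pre-draw profile cells for planted co-mentions.
    cell_draws: dict[tuple[str, str], np.ndarray] = {}
    for rel in config.planted:
        profile = np.asarray(config.type_profiles[rel.relation_type], dtype=float)
        flat = profile.reshape(-1)
        k = int(co_mention[(rel.x, rel.y)].sum())
        cell_draws[(rel.x, rel.y)] = rng.choice(flat.size, size=k, p=flat)

    stray_qual = rng.random((n, m)) < config.stray_qualifier_rate
    stray_major = rng.random((n, m)) < config.stray_major_rate
    stray_qual_choice = rng.integers(0, config.vocab.size, size=(n, m))

    q_names = config.vocab.names
    records: list[PublicationRecord] = []
    cursor: dict[tuple[str, str], int] = {pair: 0 for pair in co_mention}
    doc_rows = [np.flatnonzero(present[d]) for d in range(n)]

    for d in range(n):
        annotations: dict[str, MeshAnnotation] = {}
        for i in doc_rows[d]:
            name = names[i]
            quals: tuple[str, ...] = ()
            major = bool(stray_major[d, i])
            if stray_qual[d, i]:
                quals = (q_names[stray_qual_choice[d, i]],)
            annotations[name] = MeshAnnotation(
                descriptor=name,
                qualifiers=quals,
                major=major,
                tree_codes=tree_codes[name],
            )
        for rel in config.planted:
            pair = (rel.x, rel.y)
            if co_mention[pair][d]:
                cell = int(cell_draws[pair][cursor[pair]])
                cursor[pair] += 1
                qs, qo = divmod(cell, config.vocab.size)
                annotations[rel.x] = MeshAnnotation(
                    descriptor=rel.x, qualifiers=(q_names[qs],),
                    major=True, tree_codes=tree_codes[rel.x],
                )
                annotations[rel.y] = MeshAnnotation(
                    descriptor=rel.y, qualifiers=(q_names[qo],),
                    major=True, tree_codes=tree_codes[rel.y],
                )
        records.append(
            PublicationRecord(
                pub_id=f"PMID{d:08d}",
                year=int(years[d]),
                pub_types=("Review",) if is_review[d] else ("Journal Article",),
                annotations=tuple(
                    annotations[k] for k in sorted(annotations)
                ),
            )
        )

    truth = GroundTruth(
        planted=config.planted,
        keyword_tree_codes=tree_codes,
        expected_pmi={
            (rel.x, rel.y): rel.expected_pmi for rel in config.planted
        },
    )
    return records, truth


@dataclass(frozen=True)
class KgCorruptionManifest:
    wrong_claims: tuple[ExternalIdClaim, ...]
    duplicate_claims: tuple[ExternalIdClaim, ...]
    distinct_duplicated_ids: int
    unreferenced_statements: tuple[tuple[str, str, str], ...]  # (s, p, o)
    valid_id_universe: frozenset[str]


def generate_kg(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[list[EntityRecord], list[StatementRecord], list[ExternalIdClaim], KgCorruptionManifest]:
    """Emit a KG export for the planted relations, with corruptions.

    Each keyword becomes an entity with one MeSH-style external-ID claim;
    each planted relation becomes one statement. Configured fractions of
    claims get a wrong raw ID or a duplicate of another entity's raw ID,
    and a configured fraction of statements is left unreferenced.
    """
    rng = np.random.default_rng(config.seed + 1)
    names = sorted(truth.keyword_tree_codes)
    mesh_ids = {name: f"D{i:06d}" for i, name in enumerate(names)}
    valid_universe = frozenset(mesh_ids.values())

    entities = []
    claims = []
    wrong: list[ExternalIdClaim] = []
    duplicates: list[ExternalIdClaim] = []

    n = len(names)
    wrong_mask = rng.random(n) < config.wrong_id_rate
    dup_mask = (rng.random(n) < config.duplicate_id_rate) & ~wrong_mask

    dup_targets: dict[str, str] = {}
    clean = [i for i in range(n) if not wrong_mask[i] and not dup_mask[i]]
    for i in range(n):
        name = names[i]
        entity_id = f"Q{i + 1000}"
        raw = mesh_ids[name]
        if wrong_mask[i]:
            raw = f"X{i:06d}"  # outside the valid universe
        elif dup_mask[i] and clean:
            target = names[int(rng.choice(clean))]
            raw = mesh_ids[target]
            dup_targets[name] = target
        claim = ExternalIdClaim(entity_id=entity_id, catalog="MeSH", raw_id=raw)
        claims.append(claim)
        if wrong_mask[i]:
            wrong.append(claim)
        entities.append(
            EntityRecord(
                entity_id=entity_id,
                external_ids={"MeSH": raw},
                labels={"en": frozenset({name})},
            )
        )

    # Pairwise-symmetric duplicate bookkeeping: the copier and the copied.
    raw_by_entity = {c.entity_id: c.raw_id for c in claims}
    raw_counts: dict[str, int] = {}
    for c in claims:
        raw_counts[c.raw_id] = raw_counts.get(c.raw_id, 0) + 1
    dup_ids = {
        rid for rid, cnt in raw_counts.items() if cnt > 1
    }
    duplicates = [c for c in claims if c.raw_id in dup_ids]

    entity_of = {name: f"Q{i + 1000}" for i, name in enumerate(names)}
    statements = []
    unref: list[tuple[str, str, str]] = []
    unref_mask = rng.random(len(truth.planted)) < config.unreferenced_rate
    for j, rel in enumerate(truth.planted):
        refs: tuple[str, ...]
        if unref_mask[j]:
            refs = ()
            unref.append((entity_of[rel.x], rel.relation_type, entity_of[rel.y]))
        else:
            refs = (f"PMID{j:08d}",)
        statements.append(
            StatementRecord(
                subject=entity_of[rel.x],
                property_id=rel.relation_type,
                object=entity_of[rel.y],
                references=refs,
            )
        )

    manifest = KgCorruptionManifest(
        wrong_claims=tuple(wrong),
        duplicate_claims=tuple(duplicates),
        distinct_duplicated_ids=len(dup_ids),
        unreferenced_statements=tuple(unref),
        valid_id_universe=valid_universe,
    )
    return entities, statements, claims, manifest


@dataclass(frozen=True)
class OntologyManifest:
    dialect_of_term: Mapping[str, str]  # canonical CURIE -> dialect name
    missing_terms: frozenset[str]
    obsolete_terms: frozenset[str]


def generate_ontology(
    prefix: str,
    n_terms: int,
    dialect_rates: Mapping[str, float],
    seed: int = 0,
    obsolete_rate: float = 0.0,
) -> tuple[str, list[ExternalIdClaim], OntologyManifest]:
    """Build an OBO document and KG claims in configured dialects.

    ``dialect_rates`` distributes terms over {canonical, underscore, bare,
    missing}; "missing" terms get no KG claim at all.
    """
    order = ("canonical", "underscore", "bare", "missing")
    rates = [dialect_rates.get(k, 0.0) for k in order]
    if abs(sum(rates) - 1.0) > 1e-9:
        raise ValueError("dialect rates must sum to 1")
    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(order), size=n_terms, p=rates)
    obsolete_mask = rng.random(n_terms) < obsolete_rate

    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    claims: list[ExternalIdClaim] = []
    dialect_of: dict[str, str] = {}
    missing: set[str] = set()
    obsolete: set[str] = set()
    for i in range(n_terms):
        local = f"{i:07d}"
        curie = f"{prefix}:{local}"
        lines += [f"[Term]", f"id: {curie}", f"name: synthetic term {i}"]
        if obsolete_mask[i]:
            lines.append("is_obsolete: true")
            obsolete.add(curie)
        lines.append("")
        dialect = order[assignment[i]]
        dialect_of[curie] = dialect
        if dialect == "missing":
            missing.add(curie)
            continue
        raw = {
            "canonical": curie,
            "underscore": f"{prefix}_{local}",
            "bare": local,
        }[dialect]
        claims.append(
            ExternalIdClaim(entity_id=f"Q{i + 5000}", catalog=prefix, raw_id=raw)
        )

    manifest = OntologyManifest(
        dialect_of_term=dialect_of,
        missing_terms=frozenset(missing),
        obsolete_terms=frozenset(obsolete),
    )
    return "\n".join(lines), claims, manifest


# ---------------------------------------------------------------------------
# Direct matrix sampling (for classifier recovery studies)


def disjoint_profiles(
    relation_types: Mapping[str, str],
    vocab: QualifierVocabulary = REDUCED_VOCAB,
    cells_per_type: int = 4,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-type qualifier-pair profiles with pairwise-disjoint supports.

    ``relation_types`` maps type name -> superclass. Each type receives
    ``cells_per_type`` exclusive (subject, object) cells with uniform
    mass; disjoint supports make the classes separable by construction.
    """
    q = vocab.size
    total_cells = q * q
    types = sorted(relation_types)
    if len(types) * cells_per_type > total_cells:
        raise ValueError("not enough cells for disjoint supports")
    rng = np.random.default_rng(seed)
    cells = rng.permutation(total_cells)[: len(types) * cells_per_type]
    profiles = {}
    for j, rtype in enumerate(types):
        own = cells[j * cells_per_type : (j + 1) * cells_per_type]
        p = np.zeros(total_cells)
        p[own] = 1.0 / cells_per_type
        profiles[rtype] = p.reshape(q, q)
    return profiles


def generate_labeled_matrices(
    n: int,
    type_profiles: Mapping[str, np.ndarray],
    hierarchy: Mapping[str, str],
    vocab: QualifierVocabulary = REDUCED_VOCAB,
    seed: int = 0,
    publications_range: tuple[int, int] = (1, 20),
) -> list[LabeledMatrix]:
    """Sample labeled qualifier matrices directly from type profiles.

    Each matrix draws its publication count uniformly from
    ``publications_range`` and its cell counts from a multinomial over the
    type's profile — the distribution a corpus-built matrix would have
    when every publication contributes one qualifier on each side.
    """
    rng = np.random.default_rng(seed)
    types = sorted(type_profiles)
    out = []
    lo, hi = publications_range
    for i in range(n):
        rtype = types[int(rng.integers(len(types)))]
        n_pubs = int(rng.integers(lo, hi + 1))
        flat = np.asarray(type_profiles[rtype], dtype=float).reshape(-1)
        counts = rng.multinomial(n_pubs, flat).reshape(vocab.size, vocab.size)
        out.append(
            LabeledMatrix(
                matrix=QualifierMatrix(
                    subject=f"S{i}",
                    object=f"O{i}",
                    counts=counts.astype(np.int64),
                    vocab=vocab,
                    n_publications=n_pubs,
                ),
                relation_type=rtype,
                superclass=hierarchy[rtype],
            )
        )
    return out


def default_config(seed: int = 0) -> SimulationConfig:
    """The reference study conditions: 60 keywords, 50,000 documents,
    twelve planted pairs (four per lift in {4, 8, 32}) across three
    relation types, one per superclass, with disjoint qualifier profiles."""
    hierarchy = {
        "P279": "Taxonomic",
        "P769": "BiomedicalSymmetric",
        "P2176": "BiomedicalNonSymmetric",
    }
    profiles = disjoint_profiles(hierarchy, REDUCED_VOCAB, cells_per_type=4, seed=seed)
    lifts = [4.0, 8.0, 32.0]
    types = sorted(hierarchy)
    planted = []
    for j in range(12):
        rtype = types[j % 3]
        planted.append(
            PlantedRelation(
                x=f"KW{2 * j:04d}",
                y=f"KW{2 * j + 1:04d}",
                lift=lifts[j % 3],
                relation_type=rtype,
                superclass=hierarchy[rtype],
            )
        )
    return SimulationConfig(
        planted=tuple(planted),
        type_profiles=profiles,
        seed=seed,
    )
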