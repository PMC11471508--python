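# Methods

This note documents the models and procedures implemented in `meshkg`,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic experiments do and do not
demonstrate.

## Identifier alignment auditing

An ontology's term universe is the set of `[Term]` stanza IDs (CURIEs,
`PREFIX:LOCALID`) parsed from its OBO document; obsolete terms are kept
and flagged rather than dropped, because a KG claim pointing at an
obsolete identifier is a distinct curation finding, not an unknown ID.
KG claims are compared against this universe in two modes:

* **strict** — a claim is valid iff its raw identifier is a term ID
  verbatim;
* **repair** — the claim is first normalised across the two dialects
  observed in real exports: the underscore form (`CLO_0000031`,
  produced when URIs leak into identifier fields) and the bare form
  (local ID with the prefix omitted). Local IDs are never renumbered or
  re-padded — OBO local IDs are fixed-width strings, so `007` and `7`
  are different identifiers.

Both modes are exposed because published coverage tallies are ambiguous
about whether dialect-repaired matches were counted as valid; repair
can only increase the valid count, never decrease it. Entities with
several claims in one catalog resolve to the first valid one; the rest
feed the duplicate audit, where a raw ID shared by two *different*
entities marks every claim involved (pairwise-symmetric counting).

An ontology qualifies for KG-based enrichment when it has at least 100
valid identifiers in the KG (inclusive boundary). Language censuses
count labels/descriptions/aliases per language with strict
greater-than significance thresholds (defaults 50/50/100); relation
censuses tally statements per (subject-ontology, object-ontology) cell,
with top-k property rankings tie-broken lexicographically on property
ID for determinism.

## PMI relation mining

PMI is computed in bits, base-2 exactly, with no smoothing or
continuity correction; a pair never co-mentioned receives the sentinel
−10 rather than −∞. Sentinels are excluded from threshold calibration
and histograms: on a sparse corpus they would otherwise dominate the
mode and drag the threshold to −10.

The threshold τ is the mode of the floor-rounded PMI values of a
trusted relation set (the KG's existing relations between MeSH-aligned
items), ties broken toward the smaller integer so that a tie never
tightens the filter. Support is boundary-inclusive (PMI ≥ τ). Candidate
discovery treats keyword pairs as unordered — document co-occurrence
has no orientation — and returns candidates in lexicographic order.

Counts come from an exact in-repository corpus index (per-document
descriptor sets, pairwise intersection counts). A connector for live
search-count services would slot in behind the same
`CooccurrenceRecord` surface but is deliberately not part of the tested
package.

## Qualifier matrices

For an entity pair (x, y), up to 20 publications are selected that
index both x and y as **major topics with at least one qualifier
each** — the qualifier co-assignment pattern is the classification
signal, so qualifier-less mentions carry no information. Selection
order (most recent year first, ties by ascending record ID) is a
package choice: no selection order is canonical, recency matches the
reference retriever's preference for current literature, and a
deterministic rule makes matrix construction reproducible.

The matrix entry (q_s, q_o) counts, over selected publications, the
co-assignment of subject-qualifier q_s with object-qualifier q_o; one
publication contributes its full qualifier cross-product. Matrices
store raw integer counts; normalisation (counts → proportions) is part
of the classifier's preprocessing rather than the data, keeping the
archives lossless.

Two vocabularies ship with the package: the full 76-name MeSH topical
subheading set and the 30-name reduced set retained by the
Integrated-Gradients selection (union over superclasses of the top-ten
qualifiers). The reduced set is shipped as a constant so users get
reproducible 900-feature vectors without retraining;
`select_qualifiers` can regenerate an alternative set from any trained
model.

Splits are 70/15/15 with |train| = ⌊0.70·N⌋, |dev| = ⌊(N−|train|)/2⌋
and the remainder in test; on the 30,693-matrix dataset this yields
21,485 / 4,604 / 4,604. Splitting is stratified by relation type
(largest-remainder allocation per stratum) under a fixed seed — with 56
types and a symmetric superclass of only 801 matrices (2.6 %),
unstratified splits are high-variance. Single-member types fall back to
pooled assignment with a logged warning.

## The D-Model

Architecture: input 900 (flattened 30×30 matrix), one hidden layer of
450 with ReLU, softmax output over C classes (3 for the superclass
head; the type head's C is always derived from the dataset labels at
run time, never hardcoded). Only the layer sizes are canonical; the
training recipe is the minimal standard choice for a small MLP:
cross-entropy loss, Adam (lr 10⁻³, β 0.9/0.999), batch size 64, early
stopping on dev accuracy with patience 10, best-epoch parameters
restored, fixed seed throughout. Inputs are sum-normalised per matrix
(toggleable): publication counts per relation vary from 1 to 20, and
raw counts would confound frequency with profile shape.

The model is written directly in numpy rather than on a framework
because the explanation step needs exact input gradients, and at
≤ 0.5 M parameters a hand-rolled forward/backward pass on one CPU is
entirely adequate.

**Evaluation.** Per-class TP/TN/FP/FN come from one-vs-rest readings of
the confusion matrix; headline accuracy is overall correct/total; both
macro and support-weighted F1 are reported because averaging
conventions differ between publications. Precision or recall with an
empty denominator is reported as 0 and the class flagged, never raised.

**Integrated Gradients.** Attributions use the right-endpoint Riemann
approximation of the path integral from a baseline to the input,

  attr_i = (x_i − b_i) · (1/m) Σ_{k=1..m} ∂F/∂x_i |_{b + (k/m)(x−b)},

with baseline the all-zero matrix, target the predicted class's
*logit*, and m = 50 steps by default. The logit (rather than the
softmax probability) keeps the completeness check linear in the
network's score; for a purely linear scorer the formula is exact at any
m, and for the trained model the completeness error falls below 1 % of
F(x) − F(baseline) by m = 200. Qualifier-level scores sum the absolute
attributions over a qualifier's row and column cells — no canonical
cell-to-qualifier aggregation exists, and row+column mass is the
symmetric choice that treats subject and object roles equally.

**Agreement filter.** A type prediction is accepted iff the type's
parent superclass equals the superclass head's prediction. Over a test
set, the cross-tabulation of the two heads' correctness (both correct /
type-wrong only / superclass-wrong only / both wrong) yields the
filter's error-detection rates: of the type-head errors, the fraction
with a correct superclass head is the share the filter catches without
supervision, and symmetrically for the superclass head.

**End-to-end candidate typing** runs select → build → reduce → flatten
→ two predictions → filter per candidate; every failure mode is a
recorded reason (`no_qualifier_data` when no eligible publication
exists, `head_disagreement` when the filter rejects), never an
exception.

## Reference retrieval

Candidate references for a statement must be co-indexed with both
descriptors, be typed as reviews (evidence-based-medicine practice
privileges synthesised evidence; the filter is toggleable), and fall in
a recency window of 5 years before an explicit `reference_year` — never
the wall clock, so runs are reproducible. Filtering happens *before*
ranking: the retriever emulates a filtered search, and ranking a
pre-filtered pool is the only order under which the returned set is
provably all-eligible. Eligible documents are ranked by Okapi BM25
(k1 = 1.2, b = 0.75, idf = ln((N−df+0.5)/(df+0.5)+1)) over a term bag
of descriptor names (kept whole), qualifier names and title tokens,
with the two descriptor names as the query; ties break by ascending
publication ID. The production search engine this emulates adds a
learning-to-rank stage on top of BM25; that stage has no published
feature set or training signal and is out of scope here.

Statements are bucketed by assigned-reference count into {0, 1, 2, 3+}.
Tree-category breakdowns take the first letter of each MeSH tree code
(A Anatomy, C Diseases, D Chemicals and Drugs, …); a relation whose
endpoints carry several codes contributes one count to every distinct
letter pair it spans — the alternative (a primary-code pick) would be
arbitrary — so pair counts can exceed the relation total while rates
stay relative to relations.

## Synthetic data: what it shows and what it does not

The corpus generator uses a lifted-independence co-mention model: a
planted pair (x, y) with lift λ co-occurs with probability λ·p_x·p_y
while keeping both marginals at p, so the population PMI is exactly
log₂ λ and recovery can be asserted against a closed form (within 0.3
bits at 50,000 documents for λ ∈ {4, 8, 32}). Planted co-mentions draw
one (subject, object) qualifier cell from the relation type's profile
and attach both as major topics; non-planted mentions receive stray
qualifiers and major flags at configurable rates, providing label-free
background. Configurations that violate feasibility (λ·p_x·p_y above a
marginal) are rejected.

Defaults: 60 keywords, 50,000 documents, 1 % marginals, twelve planted
pairs (four per lift in {4, 8, 32}) across three relation types — one
per superclass — with disjoint qualifier profiles; years uniform over
2014–2023; a 10 % review share (reviews are a minority of the indexed
literature). KG and ontology generators emit corruption manifests
(wrong IDs, duplicated IDs, unreferenced statements, identifier
dialects, missing terms) so the audits are checked by exact equality.

What passing these tests shows: the arithmetic, filters and learning
machinery do what they claim under a generative model matching their
assumptions. What they do not show: performance on real MEDLINE
indexing, whose term frequencies are Zipfian, whose qualifier profiles
overlap heavily across relation types, and whose relation labels are
noisy. The disjoint-profile recovery bounds (≥ 0.9 superclass, ≥ 0.8
type accuracy at 2,000 matrices) are a correctness property of the
implementation, not a forecast of accuracy on curated datasets; the
published full-scale accuracies were obtained on an external matrix
archive with stochastic training and are not reproduced here.

## Numerical choices and degenerate inputs

* Floor rounding is mathematical floor (⌊−0.2⌋ = −1), applied only to
  finite values.
* The PMI sentinel is exactly −10.0 and is excluded from calibration;
  calibration with nothing but sentinels is an error, not a threshold.
* Threshold ties break toward the smaller integer; census and ranking
  ties break lexicographically; reference-score ties break by
  publication ID.
* Splits conserve N exactly for every fraction triple summing to 1.
* An empty SPARQL result is an empty statement list; a row missing a
  required variable is a parse error naming the row.
* Matrices are validated non-negative and square against their
  vocabulary; flatten/unflatten are exact inverses.

## Problem sizes

The test suite and acceptance script run on one CPU: the reference
corpus is 50,000 documents over 60 keywords; classifier recovery uses
2,000 matrices (8 types); BM25 brute-force cross-checks use up to
1,000 documents; the split-arithmetic check instantiates the full
30,693-matrix composition with shared zero matrices.

## Known limitations

* No OWL reasoning or xref mapping — identifier equality only.
* No live endpoint or Entrez client; query templates ship as text for
  users who run them elsewhere.
* BM25 without the production re-ranker; retrieval quality on real
  PubMed will differ.
* The evaluation metrics assume single-label classification.
* PMI significance/variance is not estimated; a pair seen once in a
  small corpus can clear the threshold.
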