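# Methods

## The representation

The toolkit models connectomics data in a deliberately small description-logic
fragment. A **TBox** holds named classes, object-property declarations
(inverse, symmetric, transitive, sub-property links, domain/range), subclass
and equivalence axioms whose right-hand sides are trees of named classes,
conjunctions, disjunctions and existential restrictions, and a single role
chain `is_tracto_connected ∘ tracto_connects ⊑ mr_connection`. An **ABox**
holds individuals with type and role assertions. There are no datatype
properties, no negation, no cardinalities and no nominals; every knowledge
base in the fragment is satisfiable, so consistency checking reduces to
referential-integrity checks.

Terms live in three namespaces: `fma` (anatomy classes and part-properties),
`hco` (connectomics vocabulary and subject-scoped individuals), `data`
(free). Conjunction/disjunction children are kept in a canonical sorted
order, so structural equality is order-insensitive and serialization is
byte-stable.

## View extraction and DL translation

The source anatomy ontology is frame-style: a term is simultaneously a class
and an individual, and part-whole knowledge is asserted as plain triples
between these punned entities. A *view* is extracted by, in order: (1) seed
with the most specific mapped terms (gyri, segments, tracts); (2) close
transitively over the part-of properties in the entity→whole direction only —
parts of a seed are deliberately not pulled in, matching the
most-specific-to-most-general extraction direction; (3) admit lateral
`attributed_continuous_with` partners (`one_step` policy: the partner enters
once and the part-of closure is re-run from it; `closed`: only
already-included partners keep their lateral links); (4) close over
subsumption (superclass closure is re-run after lateral expansion — an open
choice, exposed as a flag); (5) remove metaclasses and excluded hubs such as
`Human_body` — *after* closure, so an excluded hub cannot truncate the
traversal; (6) restrict triples to subsumption, the kept part-properties and
the lateral property.

Translation then removes the punning: every view entity becomes a named
class, every subsumption triple a named-to-named subclass axiom, and every
kept triple `(A, p, B)` the axiom `A ⊑ ∃p.B`. Inverse assertions are not
duplicated at translation time — one stored direction yields one existential
axiom, and inverse reasoning is the saturation engine's job. Triples over
discarded properties are dropped and counted in a report, not fatal.

## Matrix post-processing

Region-wise connectivity is aggregated from voxel-wise matrices by the
arithmetic mean over voxel pairs. Binarization applies `ln(1+x)`, divides
each row by its row maximum (all-zero rows stay zero), and keeps cells with
normalized value `>= 0.7`. Choices made where the procedure was genuinely
underdetermined:

* **log1p, natural base** — handles zero counts without a pseudo-count; the
  base matters (ratios of logs are base-invariant only for fixed base), so it
  is fixed and documented rather than configurable-by-accident.
* **row-maximum normalization** — makes the 0.7 threshold read as "at least
  70 % of the strongest log-connectivity in the row" and guarantees every
  non-empty row keeps at least one connection (its maximum maps to exactly
  1.0). Sum- or min-max-normalization would not give the threshold that
  interpretation.
* **inclusive comparison** (`>=`) — ties with the threshold survive, and the
  row maximum survives under exact arithmetic.

The transform is intentionally *not* scale-invariant: rescaling a row changes
ln-ratios and may change which cells survive; only the row maximum is
guaranteed stable. A dedicated test asserts exactly this behavior.

## Annotation

Per subject, each cortical parcel becomes a `Gray_matter_part` individual
named `{subject}_gray_matter_of_{region}_{parcel_id}`, related by
`regional_part_of` to a shared per-subject "gray matter of region" individual,
which is `constitutional_part_of` the per-subject region individual (typed
with its gyrus class); configurable partonomy hints hang further ancestors
(lobe, hemisphere, cortical segments) off that region individual. Subcortical
regions are typed directly with their own class. Nearest-neighbor pairs get
one `continuous_with` assertion each (symmetry is derived, not asserted).

Each surviving binary-matrix cell produces one fresh `MR_Route` individual
with `tracto_connects` to both endpoints plus a direct `mr_connection`
between them; the route counter increments across matrices in input order and
row-major within a matrix, so instance names are reproducible. One route is
created per cell per matrix (the same region pair seen from two seed masks
yields two routes — each seed mask witnesses its own pathway); a collapse to
one route per pair can be obtained by merging matrices upstream. Routes from
a bundle-labeled matrix are `regional_part_of` the lazily created per-subject
bundle individual. Self-cells are rejected: a connection links two different
structures by construction.

## Saturation engine

Materialization is a least fixpoint of an explicit rule set rather than a
tableau procedure. TBox level: reflexivity, transitivity of `⊑`, both
directions of equivalences (decomposition of the definition body; definition
*introduction* when a class entails every conjunct / some disjunct),
existential weakening along the sub-property hierarchy and along subsumption
of fillers, and chaining of existentials over transitive properties. ABox
level: type inheritance, role sub-properties, inverses, symmetry,
transitivity, the role chain, and realization of defined classes via the
`holds` evaluator (role edge to a satisfying individual, or an inherited
class-level existential whose filler entails the target — the
anonymous-filler case, applicable when the target reduces to named classes).

The chain rule excludes reflexive conclusions (`i ≠ j`): a pure property
chain would entail that every connected node is `mr_connection`-related to
itself through its own route, which contradicts the intended "two different
nodes" semantics, so the divergence from a literal chain is deliberate.

Implementation: role facts are processed semi-naively with a worklist and
per-property indexes; TBox rules and realization iterate to their (small)
fixpoints. The result is order-independent; the derivation *trace* (optional)
is not. The engine claims soundness for the declared axioms, not completeness
relative to a full DL reasoner: disjunction is handled definitionally only,
and no case branching is performed. Equivalence with an exhaustive naive
rule-application oracle is tested on hundreds of random small knowledge
bases; a saturated knowledge base re-saturates to itself (idempotence), and
derived facts only grow under added assertions (monotonicity — the fragment
is negation-free).

## Queries

The query grammar is Manchester-like: `some` binds tighter than `and`, which
binds tighter than `or`; `some` is right-associative; parentheses group.
Unprefixed names resolve against the TBox at evaluation time, `hco` before
`fma`, with an error when a name exists in both. The four shipped competency
queries interrogate the medial-premotor (BA6) parcel set: (1) motor
connectivity through the corticospinal tract or to precentral parcels;
(2) pre-SMA-like connectivity to right medial parietal cortex — expressed as
the conjunction *cortex-of-parietal-lobe ⊓ medial-segment* — or to
orbitobasal frontal cortex; (3) query 1 widened by connections to
neighbors of the precentral gyrus, whose answers therefore always contain
query 1's; (4) bundles with routes to both temporal and superior-frontal
parcels. Query 2's printed parenthesization is unbalanced in its source; the
reading implemented groups both disjuncts under the outer conjunction with
the superior-frontal restriction, matching the prose of the question.

## Synthetic data

The miniature anatomy fixture is deterministic: ~85 entities covering every
term the queries and the cohort touch, partonomy chains from gyri up to the
neuraxis and body, both directions of each part edge (as a frame source
stores both slots), one metaclass-flagged entity on the subsumption chain and
a `Human_body` hub for exclusion tests. The 20 tract classes follow the JHU
tractography-atlas composition — nine name stems, bilateral except the two
commissural forceps — because the full published enumeration cannot be
reconstructed from the nine stems alone; the list is a documented stand-in.

The cohort generator emulates the study design: 5 subjects, 1000 cortical
parcels (11 of them — ids 20, 12, 32, 9, 17, 13, 42, 18, 24, 25, 38 — the
medial-premotor target mask, all in the right superior frontal gyrus), 15
subcortical/brainstem regions, ring adjacency within each gyrus, and 22
seed-mask matrices of shape 11 × 1004 (= 1000 − 11 + 15). Planted cells
receive the pre-binarization value 1000 (the row maximum); noise cells are
Bernoulli(`noise_rate`, default 0.002) with values drawn uniformly from
[1, 120], strictly below `exp(0.7·ln(1001)) − 1 ≈ 125`, so noise can never
survive thresholding in a row that contains a planted value. Recovery is
therefore provable, not probabilistic: with `noise_rate = 0` the query
answers equal the planted truth exactly, and with small noise they can only
grow (noise adds connections, never removes planted ones). Randomness is
seeded per subject and per matrix through integer seed sequences, so a fixed
seed reproduces bundles bitwise on any platform.

What the generator does **not** emulate: parcel geometry and surface areas
(adjacency is a ring, not a mesh neighborhood), distance-dependent
tractography artifacts, inter-subject anatomical variability (all subjects
share the parcel layout and differ only in noise), and realistic connection
density. Passing tests therefore demonstrate the correctness of the
representation, rules and queries — not the biological fidelity of any
particular tractography pipeline upstream.

## Overlap statistics

The published five-subject table of regions connected to the right medial
premotor cortex is shipped verbatim (checksummed). Cells are split on commas
and trimmed; *no other normalization* is applied — the table prints a few
terms once without their final noun ("Right postcentral", "Left posterior
cingulate"), and these remain distinct terms, which is the policy that
reproduces all three printed percentages (23.7 / 38.9 / 69.5 for ≥5/≥4/≥3
subjects) within 0.1 percentage point. Fractions are computed at full
precision; display rounding is half-up to one decimal (the raw value for the
≥4 level is 38.98, whose half-up rounding 39.0 differs from the printed 38.9
by one ulp of the printed precision — the source's rounding convention is
unstated). `derive_term_sets` lifts pipeline output to the same shape: every
individual connected to a part of the target region contributes the name of
its enclosing region class, located through the annotation pipeline's
asserted `regional_part_of`/`constitutional_part_of` steps.

## Problem sizes in the shipped checks

Unit and property tests run on scaled-down cohorts (1–2 subjects, 120–150
parcels) whose planted structure is identical to the full design; the
acceptance script and the end-to-end acceptance tests run the full
5-subject, 1000-parcel, 22-matrix design. Reasoner-oracle equivalence uses
hundreds of random knowledge bases with ≤ 12 individuals and ≤ 8 classes,
the regime where the exhaustive oracle is itself trivially auditable.

## Known limitations

* The reasoner is sound but not complete for OWL DL; no cross-check against
  a tableau reasoner is bundled.
* Turtle support is a subset (the restriction/intersection/union patterns the
  schema uses); arbitrary OWL 2 documents are out of scope.
* The frame reader maps both `subClassOf` and rdf:type-to-entity patterns to
  subsumption; reified attributed-relation nodes are not interpreted — the
  fixture presents lateral adjacency as a direct triple.
* `part_of` and `part` are independent transitive umbrellas, deliberately
  *not* declared inverse of each other (their declared characteristics do not
  state it); instance-level inversion still happens through the part-property
  inverses.
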