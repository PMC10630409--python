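# Methods

This note describes the model implemented by trialmatch, the rules that
were genuinely open design choices, the numerical and procedural defaults,
and what the synthetic corpus does and does not establish about behaviour
on real trial registries.

## The eligibility model

A clinical trial's eligibility section is treated as a bag of *standard
entries* — normalized biomedical concepts in six categories (cancer, gene,
alteration, drug, biomarker, therapy) — each carrying a *criteria class*:

* **inclusion** — the entity is a recruitment requirement;
* **exclusion** — the entity disqualifies;
* **NC** (*not criteria*) — mentioned inside the eligibility section but
  functioning as neither, the canonical case being the excepted item of an
  exclusion clause ("prior malignancy **except** non-melanoma skin
  cancer": the skin cancer is neither required nor disqualifying);
* **NA** (*not available*) — mentioned outside the eligibility section,
  where context cannot determine criteria status.

The atomic record is the triplet *(entry, class, trial)*. Matching a
patient then reduces to set intersections between the patient's entry
sets and the triplet index, which keeps every decision auditable: each
category assignment cites the triplets that produced it.

## Dictionary recognition

Entity recognition is purely lexical: case-insensitive,
whitespace-normalized exact matching of synonym surface forms, taking
leftmost-longest non-overlapping matches on word boundaries. There is no
fuzzy matching and no statistical NER; a mention either resolves through
the terminology's synonym closure or it does not. This trades recall on
free-text variation for complete auditability and determinism — the right
trade for a pre-screening tool whose output feeds manual review, and the
reason byte-identical inputs always give byte-identical triplet tables.
Ambiguous synonyms (one surface owned by several entries) resolve to all
owners; downstream consumers see every candidate.

## Minimization

Composite phrases are decomposed into atomic entities:

* A compound covered by shorter dictionary terms of at least two
  categories ("HER2-positive breast cancer" → alteration + cancer) is
  split into those atoms. The split requires the sub-terms to jointly
  cover every alphanumeric character of the compound, and is suppressed
  when an alteration term merely names its own gene ("MET amplification",
  "EGFR L858R") — such a term already *is* the normalized gene:class pair
  and splitting it would discard specificity.
* A run of gene mentions separated only by connectors (commas, "and",
  "or", "and/or", "/") and governed by a following alteration-class word
  distributes that class over every gene: "NSCLC with KEAP1, NFE2L2 and/or
  STK11 mutation" derives `KEAP1:mutation`, `NFE2L2:mutation`,
  `STK11:mutation`. Distribution conserves genes — one derived pair per
  conjoined gene — and derived pairs are kept only when they resolve in
  the alteration terminology (the shipped terminology carries a
  `GENE:mutation` entry for every gene, so template corpora always
  resolve).

Compound alteration entries follow the `GENE:class` convention
(`KEAP1:mutation`, `EGFR:exon21mut`); the gene half must itself resolve in
the gene terminology.

## Criteria classification

Classification is section-driven with sentence-scoped cue rules:

| section | default | cue rule |
| --- | --- | --- |
| outside eligibility | NA | — |
| unsegmented eligibility text | NC | — |
| inclusion block | inclusion | negation cue before the mention → NC |
| exclusion block | exclusion | exception cue before the mention → NC |

Sentences are delimited by period, semicolon and newline; a cue governs
only mentions after it in its own sentence. The exception-cue list
("except", "other than", "with the exception of", "excluding", ...) and
the negation list ("no prior", "must not", "without", ...) are shipped
defaults, extensible via a YAML file (`trialmatch.criteria_miner.load_cues`);
they are a best-effort lexical stand-in for judgement a human annotator
would apply, and borderline phrasings outside the lists will be classified
by the section default.

Two conservative choices here: negated inclusion mentions demote to NC
rather than promote to exclusion (a "no prior chemotherapy" requirement is
not evidence the trial *excludes* chemotherapy-treated patients under the
loose-inclusion philosophy — treating it as exclusion would manufacture
vetoes from inferred text), and triplets with conflicting classes for the
same entry are all kept; conflict resolution belongs to the matcher.

## Variant expansion

Each variant maps to an ordered specific-to-general ladder of standard
alteration terms; only rungs present in the terminology are emitted, and
enlarging the terminology can only add rungs:

* SNV/indel: `GENE:<change>` → `GENE:<functional class>` →
  `GENE:exon<N>mut` → `GENE:Mutations`/`GENE:mutation`;
* CNV: `GENE:<direction>` → `GENE:CNV`;
* fusion: `GENE-<partner>:fusion` → `GENE:fusion` → `GENE:Fusions`;
* expression: `GENE:overexpression`/`GENE:underexpression` → `GENE:Expression`.

Exon numbers and functional-class labels come from a table-driven gene
model (protein length, numbered exon intervals in protein residues, a
`protein_change → class` map). The package deliberately does not
re-implement a genome annotator: pre-annotated protein changes (HGVS-p
short forms — L858R, V600E, fs/del/ins suffixes) are accepted directly
from an `ANN=GENE|CHANGE` INFO field in a minimal VCF, from pasted gene
lists, or from profile YAML, because the mapping ladder — not the
annotation — is what matching consumes. The VCF reader is intentionally a
small strict line parser so malformed body lines can be reported with
their line number. A single gene-model source is authoritative; merging
disagreeing annotators is out of scope.

Biomarkers map to entries as: numeric TMB ≥ 10 mut/Mb ⇒ `TMB-H`
(threshold configurable everywhere it is used; 10 is the conventional
cutoff from the pembrolizumab TMB-high approval), `MSI-H` ⇒ `MSI-H`,
`dMMR` ⇒ `dMMR`.

During matching the expansion is treated as an unordered entry set; the
specific-first order is preserved for display and reporting only.

## Matching rules

The patient contributes two matching dimensions: **variation** (all
expansion rungs plus implied biomarker entries) and **cancer** (the
profile cancer plus its ontology ancestors — upward only by default, so a
trial enrolling "solid tumor" accepts an NSCLC patient; this maximizes
recall consistently with loose inclusion, and downward matching stays off
because a "lung cancer" patient record does not license enrolment into an
NSCLC-specific trial).

* **Candidacy** — basket: any variation entry holds an inclusion-or-NA
  triplet; umbrella: likewise for the cancer dimension; combination:
  either. NA counts toward candidacy (the trial does mention the concept)
  but never toward a positive call (non-criteria context is not an
  inclusion criterion). NC triplets are invisible to matching.
* **Negative** — any profile item (cancer chain, any rung, biomarker,
  supplied prior therapy or drug) hits an exclusion triplet. Exclusion
  evidence dominates in all modes.
* **Positive** — otherwise, the confirming dimension holds inclusion
  evidence: cancer for basket, variation for umbrella; in combination
  mode one dimension must be confirmed as inclusion while the other
  matched at least at candidacy level. This formulation makes every
  basket-positive and umbrella-positive trial combination-positive while
  still never promoting NA-only evidence.
* **Unclassified** — everything else. Absence of evidence never yields
  negative.

The positive/negative/unclassified decision table is a reconstruction
from the principles above (loose inclusion, tight exclusion; preferred
conditions per mode) rather than a transcription of a published flowchart,
and is exercised exhaustively in the tests over every combination of
triplet classes on both dimensions.

Prior-therapy history participates two ways: optionally as a profile field
(contributing exclusion-veto items only), and as refinement input — the
screening step where a therapy the patient failed drops trials requiring
it as inclusion. It never contributes candidacy.

Metadata filters keep a trial iff status/phase are in the selected sets,
the country intersection is non-empty, trial gender is `all` or equals the
patient's, and the patient age lies in the trial's (possibly unbounded)
age window. Filters and refinement are anti-monotone — they only remove
trials — and refinements compose: chaining equals applying the
conjunction. Results are content-addressed (SHA-256 of the canonical
report JSON) and each refinement records its parent's id, replacing the
job-queue/permanent-URL bookkeeping of a hosted service.

## Synthetic corpus

The generator emulates the *structure* of registry eligibility text, not
its messiness: sentences are drawn from templates (plain
inclusion/exclusion statements, exception clauses, composite
alteration+cancer phrases, gene-conjunction sentences, negated inclusion
requirements, and non-eligibility summary passages), filled from realistic
pools — 13 cancers under a solid-tumor hierarchy, 16 genes, clinically
familiar alterations (EGFR L858R/T790M, KRAS G12C, BRAF V600E, ERBB2 and
MET events, ALK/RET/ROS1 fusions), 10 drugs, 7 biomarkers, 6 therapies —
with metadata drawn uniformly from the registry enums, a minimum age of
18 for most trials, and 1–3 trial countries. Defaults: 50 trials, 1–4
inclusion and 0–3 exclusion sentences per trial, exception clauses in 25%
of trials, conjunction sentences in 35%, composite phrases in 30%,
negated inclusions in 15%, a non-eligibility passage in 50%. One seeded
RNG stream drives everything; the seed is recorded in the corpus manifest,
and identical seeds give byte-identical output files.

Templates are within the miner's grammar by design, so mined triplets
equal the planted ground truth exactly — that is a *closure* check of the
pipeline's internal consistency, not evidence about recall on free text.
Real eligibility prose contains nested bullets, cross-sentence scope,
lab-value predicates and typos that the generator deliberately omits;
passing tests therefore demonstrate that the rules are implemented as
specified, not that the rules capture all registry language. Patient
generation can target an outcome (positive/negative/unclassified per
mode) by re-applying the matching rules directly to the planted triplet
sets — never by calling the matcher — so targeted expectations stay
independent of the code under test.

## Numerical and procedural choices

* Tokenization for matching treats any non-alphanumeric character as a
  boundary; synonym-internal spaces match arbitrary whitespace runs.
* Normalization keys are case-folded with collapsed whitespace; ties
  among ambiguous entries break by ascending entry id everywhere, so all
  orderings are total and deterministic.
* Ages parse to years (months/weeks/days/hours divided out); missing or
  `N/A` bounds are unbounded; trial records with min > max are rejected.
* Eligibility segmentation keeps header text inside its passage so that
  the passages exactly partition the input; duplicate headers each start
  a new passage.
* Parent links in a terminology must be acyclic and same-category; cycles
  are reported with their member entries at load time. Ancestor closures
  are memoized.
* Problem sizes in the test suite and the acceptance script — 50–100
  trial corpora, 15–30 profiles per sweep — are chosen so the exhaustive
  brute-force oracles (linear scans, nested loops, boolean-matrix
  reachability) stay trivially cheap while still exercising every rule
  path; the properties they check are size-independent.

## Known limitations

* Dictionary recognition misses surface forms absent from the synonym
  closure; there is no stemming or edit-distance tolerance.
* Cue scope is a single sentence; exceptions reaching across sentence
  boundaries ("... are excluded. Exceptions: ...") are classified by the
  section default.
* Nested bullet structure inside criteria blocks is flattened to
  sentences.
* The HGVS grammar is limited to protein-level short forms; genomic
  coordinates resolve only through a supplied annotation field or
  coding-change table.
* Only country-level trial locations are modelled.
* Entity categories are fixed at six; phenotype criteria (performance
  status, lab values) are not represented.
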