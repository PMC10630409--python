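# trialmatch

**trialmatch** is an offline engine for precision-oncology clinical-trial
matching. It mines trial eligibility text into a structured database of
*entity–criteria–trial triplets*, expands a patient's genomic variants into
hierarchies of standard alteration terms, and matches patient profiles
against trials under basket, umbrella and combination strategies.

It is aimed at clinical bioinformaticians and informatics researchers who
need an auditable, scriptable pre-screening step between a molecular
profiling report and a list of candidate trials — without a web service,
a database server or any network access.

## What it computes

**Triplet mining.** Trial text is scanned with dictionary-based entity
recognition over six terminologies (cancers, genes, alterations, drugs,
biomarkers, therapies), using leftmost-longest matching on word
boundaries. The *minimization principle* decomposes composite phrases into
atomic entities — `HER2-positive breast cancer` becomes one alteration
plus one cancer — and distributes a gene conjunction over its governing
alteration word:

```
NSCLC with KEAP1, NFE2L2 and/or STK11 mutation
  → 1 cancer + 3 genes + 1 alteration
  → KEAP1:mutation, NFE2L2:mutation, STK11:mutation
```

Each occurrence is then classified as **inclusion**, **exclusion**, **NC**
(*not criteria* — e.g. the excepted item in "prior malignancy *except*
non-melanoma skin cancer") or **NA** (*not available* — outside the
eligibility section). Every distinct (standard entry, class, trial) pair
is one triplet of the eligibility database.

**Variant expansion.** A variant is expanded into an ordered,
specific-to-general ladder of standard alteration terms:

```
EGFR p.L858R → EGFR:L858R → EGFR:Activating mutations → EGFR:exon21mut → EGFR:Mutations
```

so a trial standardized on any rung still matches. Exon numbers and
functional-class labels come from a small tabular gene model; CNV, fusion
and expression variants use analogous ladders, and TMB/MSI/MMR values map
to biomarker entries (TMB ≥ 10 mut/Mb ⇒ `TMB-H` by default).

**Matching.** *Basket* matching selects trials whose inclusion-or-NA
triplets hit the patient's variation entries; *umbrella* does the same
with the cancer dimension (the profile cancer or any ontology ancestor —
a "solid tumor" trial accepts an NSCLC patient); *combination* takes the
union. Candidates are categorized under **loose inclusion, tight
exclusion**: any exclusion hit on any profile item vetoes (negative);
otherwise inclusion evidence on the confirming dimension makes the trial
positive; absence of evidence never excludes (unclassified). Metadata
filters (status, phase, country, gender, age) and iterative refinement
only ever remove trials.

A seeded synthetic-corpus generator produces terminologies, gene models,
trials with planted ground-truth triplets, and patient profiles with known
match outcomes, so the whole pipeline is testable end to end offline.

## Worked example

```python
from trialmatch import (Biomarkers, EligibilityDB, MatchJob, PatientProfile,
                        Variant, expand_profile, run_match)
from trialmatch.synthetic_corpus import CorpusSpec, generate_corpus

bundle = generate_corpus(CorpusSpec(seed=7, n_trials=50))
db = EligibilityDB.build(bundle.trials, bundle.terminology)
print("triplets:", len(db.triplets))

profile = PatientProfile(
    cancer_entry_id="C_NSCLC",
    variants=(Variant("snv_indel", "EGFR", "L858R"),),
    biomarkers=Biomarkers(tmb=14.0),
    age_years=61.0, gender="female",
)
xp = expand_profile(profile, bundle.terminology, bundle.gene_models)
print("expanded:", [bundle.terminology.entries[e].canonical_name
                    for e in sorted(xp.variation_entries)])

result = run_match(MatchJob(profile=profile, mode="combination"), db,
                   gene_models=bundle.gene_models)
print(result.overview(db)["by_category"])
```

prints

```
triplets: 437
expanded: ['EGFR:Activating mutations', 'EGFR:exon21mut', 'EGFR:L858R', 'EGFR:mutation', 'TMB-H']
{'negative': 3, 'positive': 7, 'unclassified': 19}
```

The 50-trial corpus yielded 437 triplets; the patient's single L858R
substitution expanded to four alteration rungs plus the `TMB-H` biomarker;
29 trials entered the provisional list, of which 7 are positive (cancer
and variation both confirmed as inclusion criteria), 3 negative (an
exclusion criterion hit some profile item) and 19 unclassified (matched on
one dimension, no evidence on the other).

The same pipeline is available from the shell:

```bash
trialmatch gen-corpus --seed 7 --n-trials 50 --out corpus/
trialmatch mine --trials corpus/trials.jsonl --terminology corpus/terminology.tsv --out db/
trialmatch search "NSCLC" --mode entity --db db/ --terminology corpus/terminology.tsv
trialmatch match --profile patient.yaml --db db/ --terminology corpus/terminology.tsv \
    --gene-models corpus/gene_models.tsv --mode basket
```

## Layout

| Module | Role |
| --- | --- |
| `trialmatch.terminology` | standard entries, synonym normalization, ontology ancestors |
| `trialmatch.trial_ingest` | trial-record JSON dialect, eligibility segmentation |
| `trialmatch.criteria_miner` | dictionary NER, minimization, criteria classification, triplets |
| `trialmatch.eligibility_db` | indexed store, quick/advanced search, corpus statistics |
| `trialmatch.variant_profile` | VCF/gene-list/profile parsing, expansion ladders |
| `trialmatch.matcher` | basket/umbrella/combination matching, filters, refinement |
| `trialmatch.synthetic_corpus` | seeded corpora and patients with planted ground truth |

See `docs/methods.md` for the model, its assumptions and the design
decisions behind the rules.
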