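"""Patient–trial matching: basket, umbrella and combination strategies.

Candidate selection follows the trial-design logic: *basket* matching
treats the patient's variations (expanded alterations plus biomarkers) as
the preferred condition and selects trials holding an inclusion-or-NA
triplet for any of them; *umbrella* matching does the same with the cancer
dimension (the profile cancer or any of its ontology ancestors, so a trial
enrolling "solid tumor" accepts an NSCLC patient); *combination* takes the
union — a trial matched by either entity enters the provisional list.

Candidates are then categorized under loose inclusion / tight exclusion:

* **negative** — any profile item (cancer incl. ancestors, any expansion
  rung, biomarker, or supplied prior therapy/drug) hits an exclusion
  triplet; exclusion evidence vetoes regardless of inclusion evidence;
* **positive** — otherwise, the secondary dimension also holds inclusion
  evidence (basket: cancer; umbrella: variation; combination: both);
* **unclassified** — otherwise; absence of evidence never excludes.

NA triplets count toward candidacy but never promote a trial to positive
(non-criteria context is not an inclusion criterion), and NC triplets are
ignored entirely.  Metadata filters and iterative refinement only ever
remove trials.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .eligibility_db import EligibilityDB, TrialFilters
from .errors import MatchJobError, RefineError
from .terminology import Terminology
from .variant_profile import (
    ExpandedProfile,
    GeneModelSet,
    PatientProfile,
    TMB_HIGH_THRESHOLD,
    expand_profile,
)

MODES = ("basket", "umbrella", "combination")
CATEGORIES = ("positive", "negative", "unclassified")

#: criteria classes that make a trial a candidate for a matching dimension
CANDIDACY_CLASSES = ("inclusion", "NA")


@dataclass(frozen=True)
class MatchJob:
    profile: PatientProfile
    mode: str = "combination"
    filters: TrialFilters = TrialFilters()

    def __post_init__(self):
        if self.mode not in MODES:
            raise MatchJobError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class Evidence:
    """One triplet that contributed to a trial's category."""

    entry_id: str
    criteria_class: str
    matched_item: str  # the profile item (dimension:identifier) that matched


@dataclass(frozen=True)
class MatchedTrial:
    trial_id: str
    category: str
    evidence: tuple[Evidence, ...]


@dataclass(frozen=True)
class MatchResult:
    mode: str
    trials: tuple[MatchedTrial, ...]  # ordered by trial_id
    filters: TrialFilters = TrialFilters()
    parent_id: str | None = None

    @property
    def trial_ids(self) -> list[str]:
        return [t.trial_id for t in self.trials]

    def category_of(self, trial_id: str) -> str | None:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t.category
        return None

    @property
    def result_id(self) -> str:
        """Content-addressed identifier of this result."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "parent_id": self.parent_id,
            "filters": {
                "statuses": sorted(self.filters.statuses) if self.filters.statuses is not None else None,
                "phases": sorted(self.filters.phases) if self.filters.phases is not None else None,
                "countries": sorted(self.filters.countries) if self.filters.countries is not None else None,
                "gender": self.filters.gender,
                "age_years": self.filters.age_years,
            },
            "trials": [
                {
                    "trial_id": t.trial_id,
                    "category": t.category,
                    "evidence": [
                        {
                            "entry_id": e.entry_id,
                            "criteria_class": e.criteria_class,
                            "matched_item": e.matched_item,
                        }
                        for e in t.evidence
                    ],
                }
                for t in self.trials
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MatchResult":
        f = data.get("filters", {})
        filters = TrialFilters(
            statuses=frozenset(f["statuses"]) if f.get("statuses") is not None else None,
            phases=frozenset(f["phases"]) if f.get("phases") is not None else None,
            countries=frozenset(f["countries"]) if f.get("countries") is not None else None,
            gender=f.get("gender"),
            age_years=f.get("age_years"),
        )
        trials = tuple(
            MatchedTrial(
                trial_id=t["trial_id"],
                category=t["category"],
                evidence=tuple(
                    Evidence(e["entry_id"], e["criteria_class"], e["matched_item"])
                    for e in t["evidence"]
                ),
            )
            for t in data["trials"]
        )
        return cls(
            mode=data["mode"], trials=trials, filters=filters, parent_id=data.get("parent_id")
        )

    def overview(self, db: EligibilityDB) -> dict:
        """Summary statistics of the matched list (the match-result overview)."""
        by_category: dict[str, int] = {c: 0 for c in CATEGORIES}
        by_phase: dict[str, int] = {}
        by_status: dict[str, int] = {}
        by_country: dict[str, int] = {}
        by_entity: dict[str, int] = {}
        for t in self.trials:
            by_category[t.category] += 1
            rec = db.trials.get(t.trial_id)
            if rec is not None:
                by_phase[rec.metadata.phase] = by_phase.get(rec.metadata.phase, 0) + 1
                by_status[rec.metadata.status] = by_status.get(rec.metadata.status, 0) + 1
                for c in rec.metadata.countries:
                    by_country[c] = by_country.get(c, 0) + 1
            for e in t.evidence:
                by_entity[e.entry_id] = by_entity.get(e.entry_id, 0) + 1
        return {
            "n_trials": len(self.trials),
            "by_category": dict(sorted(by_category.items())),
            "by_phase": dict(sorted(by_phase.items())),
            "by_status": dict(sorted(by_status.items())),
            "by_country": dict(sorted(by_country.items())),
            "by_entity": dict(sorted(by_entity.items())),
        }


# -- core steps -------------------------------------------------------------


def _item_labels(expanded: ExpandedProfile) -> dict[str, str]:
    """Map each matchable entry id to the profile item it came from."""
    labels: dict[str, str] = {}
    for e in sorted(expanded.cancer_entries):
        labels[e] = f"cancer:{expanded.profile.cancer_entry_id}"
    for x in expanded.expansions:
        v = x.variant
        desc = v.gene_symbol
        if v.protein_change:
            desc += f" {v.protein_change}"
        elif v.direction:
            desc += f" {v.direction}"
        for e in x.entries:
            labels.setdefault(e, f"variant:{desc}")
    for e in sorted(expanded.alteration_entries):
        labels.setdefault(e, "variant")
    for e in sorted(expanded.biomarker_entry_ids):
        labels.setdefault(e, "biomarker")
    for e in sorted(expanded.prior_entry_ids):
        labels.setdefault(e, "prior_therapy")
    return labels


def candidate_trials(
    expanded: ExpandedProfile, db: EligibilityDB, mode: str
) -> set[str]:
    """Trials entering the provisional list for a profile under a mode."""
    if mode not in MODES:
        raise MatchJobError(f"unknown mode {mode!r}")
    if not expanded.all_entries:
        raise MatchJobError("profile has no matchable entries")

    def dimension_candidates(entries: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for e in entries:
            for cls in CANDIDACY_CLASSES:
                out |= db.trials_for_entry(e, cls)
        return out

    if mode == "basket":
        if not expanded.variation_entries:
            raise MatchJobError("basket matching needs at least one variation entry")
        return dimension_candidates(expanded.variation_entries)
    if mode == "umbrella":
        return dimension_candidates(expanded.cancer_entries)
    return dimension_candidates(expanded.variation_entries) | dimension_candidates(
        expanded.cancer_entries
    )


def categorize(
    trial_id: str, expanded: ExpandedProfile, db: EligibilityDB, mode: str
) -> MatchedTrial:
    """Assign positive/negative/unclassified to one candidate trial."""
    labels = _item_labels(expanded)
    exclusion_hits = [
        Evidence(e, "exclusion", labels[e])
        for e in sorted(expanded.all_entries)
        if trial_id in db.trials_for_entry(e, "exclusion")
    ]
    if exclusion_hits:
        return MatchedTrial(trial_id, "negative", tuple(exclusion_hits))

    def inclusion_hits(entries: Iterable[str]) -> list[Evidence]:
        return [
            Evidence(e, "inclusion", labels[e])
            for e in sorted(entries)
            if trial_id in db.trials_for_entry(e, "inclusion")
        ]

    def candidacy_hits(entries: Iterable[str]) -> list[Evidence]:
        out = []
        for e in sorted(entries):
            for cls in CANDIDACY_CLASSES:
                if trial_id in db.trials_for_entry(e, cls):
                    out.append(Evidence(e, cls, labels[e]))
        return out

    cancer_incl = inclusion_hits(expanded.cancer_entries)
    var_incl = inclusion_hits(expanded.variation_entries)
    cancer_cand = candidacy_hits(expanded.cancer_entries)
    var_cand = candidacy_hits(expanded.variation_entries)
    if mode == "basket":
        # candidate via the variation dimension; cancer must confirm as inclusion
        positive = bool(cancer_incl)
    elif mode == "umbrella":
        positive = bool(var_incl)
    else:
        # one dimension confirmed as inclusion, the other matched at least
        # at candidacy (inclusion-or-NA) level; NA alone never makes positive
        positive = (bool(cancer_incl) and bool(var_cand)) or (
            bool(var_incl) and bool(cancer_cand)
        )
    if positive:
        evidence = {e for e in cancer_incl + var_incl + cancer_cand + var_cand}
        return MatchedTrial(
            trial_id,
            "positive",
            tuple(sorted(evidence, key=lambda e: (e.entry_id, e.criteria_class))),
        )
    evidence = candidacy_hits(expanded.all_entries)
    return MatchedTrial(trial_id, "unclassified", tuple(evidence))


def apply_filters(result: MatchResult, filters: TrialFilters, db: EligibilityDB) -> MatchResult:
    """Keep only trials whose metadata passes the filters (anti-monotone)."""
    kept = tuple(
        t
        for t in result.trials
        if t.trial_id in db.trials and filters.accepts(db.trials[t.trial_id])
    )
    return replace(result, trials=kept, filters=filters)


def run_match(
    job: MatchJob,
    db: EligibilityDB,
    terminology: Terminology | None = None,
    gene_models: GeneModelSet | None = None,
    tmb_threshold: float = TMB_HIGH_THRESHOLD,
) -> MatchResult:
    """Expand → select candidates → categorize → filter, deterministically."""
    term = terminology if terminology is not None else db.terminology
    if term is None:
        raise MatchJobError("matching requires a terminology")
    expanded = expand_profile(job.profile, term, gene_models, tmb_threshold)
    candidates = candidate_trials(expanded, db, job.mode)
    matched = tuple(
        categorize(tid, expanded, db, job.mode) for tid in sorted(candidates)
    )
    result = MatchResult(mode=job.mode, trials=matched)
    return apply_filters(result, job.filters, db)


def refine(
    result: MatchResult,
    db: EligibilityDB,
    required: Sequence[tuple[str, str | None]] = (),
    excluded: Sequence[str] = (),
    filters: TrialFilters | None = None,
) -> MatchResult:
    """Secondary screening of an existing result; repeatable and composable.

    ``required`` entries keep only trials holding a matching triplet (of the
    given class when specified); ``excluded`` entries (e.g. a therapy the
    patient failed) drop trials that require them as inclusion; optional
    metadata ``filters`` are applied on top.  The new result records its
    parent's content id.
    """

    def check_known(entry_id: str) -> None:
        if entry_id not in db.by_entry and (
            db.terminology is None or entry_id not in db.terminology
        ):
            raise RefineError(f"unknown entry_id {entry_id!r}")

    kept = list(result.trials)
    for entry_id, cls in required:
        check_known(entry_id)
        holders = db.trials_for_entry(entry_id, cls)
        kept = [t for t in kept if t.trial_id in holders]
    for entry_id in excluded:
        check_known(entry_id)
        holders = db.trials_for_entry(entry_id, "inclusion")
        kept = [t for t in kept if t.trial_id not in holders]
    out = replace(result, trials=tuple(kept), parent_id=result.result_id)
    if filters is not None:
        out = apply_filters(out, filters, db)
    return out
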