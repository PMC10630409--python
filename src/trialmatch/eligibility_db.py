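"""The eligibility database: trials, triplets and mention indexes.

Persistence is deliberately flat-file (JSON-lines for trials, TSV for
triplets and mentions) with in-memory indexes rebuilt on load; the package
is a library, not a database server.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .criteria_miner import CRITERIA_CLASSES, CueLexicon, DEFAULT_CUES, MinedTrial, Triplet, mine_trial
from .errors import QueryError
from .terminology import Terminology
from .trial_ingest import TrialRecord, read_trials, write_trials


@dataclass(frozen=True)
class TrialFilters:
    """Metadata filters; ``None`` means 'no constraint' for that field.

    ``gender`` and ``age_years`` are patient attributes: a trial passes when
    its gender is ``all`` or equals the patient's, and when the patient age
    falls inside the trial's (possibly unbounded) age window.
    """

    statuses: frozenset[str] | None = None
    phases: frozenset[str] | None = None
    countries: frozenset[str] | None = None
    gender: str | None = None
    age_years: float | None = None

    def accepts(self, trial: TrialRecord) -> bool:
        md = trial.metadata
        if self.statuses is not None and md.status not in self.statuses:
            return False
        if self.phases is not None and md.phase not in self.phases:
            return False
        if self.countries is not None and not (self.countries & md.countries):
            return False
        if self.gender is not None and md.gender not in ("all", self.gender):
            return False
        if self.age_years is not None:
            if md.min_age_years is not None and self.age_years < md.min_age_years:
                return False
            if md.max_age_years is not None and self.age_years > md.max_age_years:
                return False
        return True


class EligibilityDB:
    """Indexed store of trials, their triplets and recognized mention surfaces."""

    def __init__(
        self,
        trials: Iterable[TrialRecord],
        mined: Iterable[MinedTrial] | None = None,
        terminology: Terminology | None = None,
        triplets: Iterable[Triplet] | None = None,
        mention_surfaces: dict[str, list[str]] | None = None,
    ):
        self.trials: dict[str, TrialRecord] = {t.trial_id: t for t in trials}
        self.terminology = terminology
        self.triplets: list[Triplet] = []
        self.mention_surfaces: dict[str, list[str]] = {}
        if mined is not None:
            for m in mined:
                self.triplets.extend(m.triplets)
                surfaces = sorted({em.surface.casefold() for em, _ in m.mentions})
                if surfaces:
                    self.mention_surfaces[m.trial_id] = surfaces
        if triplets is not None:
            self.triplets.extend(triplets)
        if mention_surfaces is not None:
            self.mention_surfaces.update(mention_surfaces)
        self.rebuild_indexes()

    @classmethod
    def build(
        cls,
        trials: Iterable[TrialRecord],
        terminology: Terminology,
        cues: CueLexicon = DEFAULT_CUES,
    ) -> "EligibilityDB":
        """Mine every trial and assemble the database in one pass."""
        trials = list(trials)
        mined = [mine_trial(t, terminology, cues) for t in trials]
        return cls(trials, mined=mined, terminology=terminology)

    def rebuild_indexes(self) -> None:
        """(Re)derive all secondary indexes from the base tables; idempotent."""
        self.triplets = sorted(
            set(
                Triplet(t.entry_id, t.criteria_class, t.trial_id, t.evidence)
                for t in self.triplets
            ),
            key=lambda t: (t.entry_id, t.criteria_class, t.trial_id),
        )
        self.by_entry: dict[str, dict[str, set[str]]] = {}
        self.by_trial: dict[str, list[Triplet]] = {}
        for t in self.triplets:
            self.by_entry.setdefault(t.entry_id, {}).setdefault(
                t.criteria_class, set()
            ).add(t.trial_id)
            self.by_trial.setdefault(t.trial_id, []).append(t)

    # -- queries ------------------------------------------------------------

    def trials_for_entry(self, entry_id: str, criteria_class: str | None = None) -> set[str]:
        classes = self.by_entry.get(entry_id, {})
        if criteria_class is not None:
            return set(classes.get(criteria_class, set()))
        out: set[str] = set()
        for tids in classes.values():
            out |= tids
        return out

    def quick_search(self, keyword: str, mode: str = "mention") -> list[str]:
        """Keyword search over the corpus.

        ``mention`` mode: substring match of the case-folded keyword against
        recognized mention surfaces.  ``entity`` mode: resolve the keyword to
        standard entries across all categories and return every trial with a
        triplet for any resolved entry (synonym-invariant by construction).
        Results are trial ids, ascending.
        """
        key = keyword.casefold()
        if mode == "mention":
            return sorted(
                tid
                for tid, surfaces in self.mention_surfaces.items()
                if any(key in s for s in surfaces)
            )
        if mode == "entity":
            if self.terminology is None:
                raise QueryError("entity-mode search requires a terminology")
            out: set[str] = set()
            for eid in self.terminology.normalize_mention(keyword):
                out |= self.trials_for_entry(eid)
            return sorted(out)
        raise QueryError(f"unknown search mode {mode!r}")

    def advanced_search(
        self,
        entity_conditions: Sequence[tuple[str, str | None]] = (),
        filters: TrialFilters = TrialFilters(),
    ) -> list[str]:
        """Conjunctive entity + metadata retrieval.

        Each entity condition is ``(entry_id, criteria_class or None)``; a
        class-qualified condition matches only triplets of that class (e.g.
        a cancer *as inclusion* vs *as exclusion*).  An empty condition list
        constrains nothing, so the result is all trials passing the filters.
        """
        candidates = set(self.trials)
        for entry_id, cls in entity_conditions:
            if entry_id not in self.by_entry and (
                self.terminology is None or entry_id not in self.terminology
            ):
                raise QueryError(f"unknown entry_id {entry_id!r}")
            if cls is not None and cls not in CRITERIA_CLASSES:
                raise QueryError(f"unknown criteria class {cls!r}")
            candidates &= self.trials_for_entry(entry_id, cls)
        return sorted(t for t in candidates if filters.accepts(self.trials[t]))

    # -- statistics ----------------------------------------------------------

    def corpus_statistics(self, min_trials: int = 3) -> "CorpusStatistics":
        """Per-entry/per-class distinct-trial counts and category shares.

        The category share table answers questions of the form "what fraction
        of the entries appearing in at least ``min_trials`` trials under
        exclusion criteria are drugs?".
        """
        rows = []
        for entry_id, classes in sorted(self.by_entry.items()):
            category = (
                self.terminology.entries[entry_id].category
                if self.terminology is not None and entry_id in self.terminology
                else ""
            )
            for cls, tids in sorted(classes.items()):
                rows.append(
                    {
                        "entry_id": entry_id,
                        "category": category,
                        "criteria_class": cls,
                        "n_trials": len(tids),
                    }
                )
        counts = pd.DataFrame(rows, columns=["entry_id", "category", "criteria_class", "n_trials"])
        share_rows = []
        for cls in CRITERIA_CLASSES:
            sub = counts[(counts.criteria_class == cls) & (counts.n_trials >= min_trials)]
            total = len(sub)
            for category, n in sub.groupby("category").size().items():
                share_rows.append(
                    {
                        "criteria_class": cls,
                        "category": category,
                        "n_entries": int(n),
                        "share": n / total,
                    }
                )
        shares = pd.DataFrame(
            share_rows, columns=["criteria_class", "category", "n_entries", "share"]
        )
        return CorpusStatistics(entry_counts=counts, category_shares=shares, min_trials=min_trials)

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_trials(
            (self.trials[t] for t in sorted(self.trials)), directory / "trials.jsonl"
        )
        pd.DataFrame(
            [
                {
                    "entry_id": t.entry_id,
                    "criteria_class": t.criteria_class,
                    "trial_id": t.trial_id,
                    "evidence_count": t.evidence,
                }
                for t in self.triplets
            ],
            columns=["entry_id", "criteria_class", "trial_id", "evidence_count"],
        ).to_csv(directory / "triplets.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"trial_id": tid, "surface": s}
                for tid in sorted(self.mention_surfaces)
                for s in self.mention_surfaces[tid]
            ],
            columns=["trial_id", "surface"],
        ).to_csv(directory / "mentions.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path, terminology: Terminology | None = None) -> "EligibilityDB":
        directory = Path(directory)
        trials = list(read_trials(directory / "trials.jsonl"))
        # keep_default_na guards the literal criteria class "NA"
        tdf = pd.read_csv(
            directory / "triplets.tsv", sep="\t", dtype=str, keep_default_na=False
        )
        triplets = [
            Triplet(r.entry_id, r.criteria_class, str(r.trial_id), int(r.evidence_count))
            for r in tdf.itertuples(index=False)
        ]
        surfaces: dict[str, list[str]] = {}
        mpath = directory / "mentions.tsv"
        if mpath.exists():
            mdf = pd.read_csv(mpath, sep="\t", dtype=str, keep_default_na=False)
            for r in mdf.itertuples(index=False):
                surfaces.setdefault(r.trial_id, []).append(r.surface)
        return cls(
            trials,
            terminology=terminology,
            triplets=triplets,
            mention_surfaces=surfaces,
        )


@dataclass
class CorpusStatistics:
    """Outputs of :meth:`EligibilityDB.corpus_statistics`."""

    entry_counts: pd.DataFrame
    category_shares: pd.DataFrame
    min_trials: int

    def share(self, criteria_class: str, category: str) -> float:
        sub = self.category_shares
        row = sub[(sub.criteria_class == criteria_class) & (sub.category == category)]
        return float(row["share"].iloc[0]) if len(row) else 0.0
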