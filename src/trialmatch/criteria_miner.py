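"""Mine entity–criteria–trial triplets from trial text.

The pipeline is dictionary recognition → minimization decomposition →
criteria classification:

* **Recognition** finds leftmost-longest, non-overlapping dictionary matches
  on word boundaries against every synonym surface form in the terminology.

* **Decomposition** applies the minimization principle: composite surface
  forms are split into their atomic cancer/gene/alteration parts
  ("HER2-positive breast cancer" → one alteration + one cancer), and a
  conjunction of gene mentions governed by a single alteration-class word
  is distributed into normalized compound entries ("NSCLC with KEAP1,
  NFE2L2 and/or STK11 mutation" → ``KEAP1:mutation``, ``NFE2L2:mutation``,
  ``STK11:mutation``).

* **Classification** assigns each occurrence one of four criteria classes:
  ``inclusion``, ``exclusion``, ``NC`` (mentioned inside the eligibility
  section but functioning as neither criterion — e.g. the exception clause
  "... except non-melanoma skin cancer") or ``NA`` (outside the eligibility
  section, where context cannot determine criteria status).  Cue words
  govern their own sentence only: an exception cue demotes exclusion
  mentions after it to NC, a negation cue demotes inclusion mentions after
  it to NC.

Each distinct (standard entry, criteria class) pair per trial becomes one
triplet; conflicting classes for the same entry are all kept — conflict
resolution belongs to the matcher, not the miner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ConsistencyError
from .terminology import Terminology, normalize_surface
from .trial_ingest import Passage, TrialRecord

CRITERIA_CLASSES = ("inclusion", "exclusion", "NC", "NA")

#: alteration-class surface words that can govern a gene conjunction,
#: mapped to the class token used in compound ``GENE:class`` entries
CLASS_WORDS = {
    "mutation": "mutation",
    "mutations": "mutation",
    "mutated": "mutation",
    "amplification": "amplification",
    "amplified": "amplification",
    "deletion": "deletion",
    "deleted": "deletion",
    "fusion": "fusion",
    "fusions": "fusion",
    "rearrangement": "fusion",
    "overexpression": "overexpression",
}

_CONNECTOR_TOKENS = {"", "and", "or", "and/or", "/", "&", "+"}


@dataclass(frozen=True)
class EntityMention:
    """One recognized occurrence of a dictionary term in a passage."""

    trial_id: str
    passage_id: str
    start: int  # 0-based half-open offsets into the passage text
    end: int
    surface: str
    category: str
    entry_ids: tuple[str, ...]


@dataclass(frozen=True)
class DerivedEntry:
    """A normalized ``GENE:class`` pair produced by conjunction distribution."""

    name: str
    gene_symbol: str
    class_token: str
    entry_ids: tuple[str, ...]  # resolved alteration entries (may be empty)
    gene_mention: EntityMention
    alteration_mention: EntityMention


@dataclass(frozen=True)
class Triplet:
    """The atomic eligibility-database record: entry × criteria class × trial."""

    entry_id: str
    criteria_class: str
    trial_id: str
    evidence: int = 1


@dataclass(frozen=True)
class CueLexicon:
    """Sentence-scoped cue phrases; shipped defaults are user-extensible.

    The phrase lists are a best-effort stand-in for the judgement human
    annotators apply; extend them via :func:`load_cues`.
    """

    exception_cues: tuple[str, ...] = (
        "except",
        "with the exception of",
        "excepting",
        "other than",
        "excluding",
        "not including",
        "apart from",
        "unless",
    )
    negation_cues: tuple[str, ...] = (
        "no prior",
        "no history of",
        "no previous",
        "must not",
        "without",
        "not eligible",
    )


DEFAULT_CUES = CueLexicon()


def load_cues(path: str | Path) -> CueLexicon:
    """Extend the default cue lexicon from a YAML file.

    Recognized keys: ``exception_cues``, ``negation_cues`` (lists of
    phrases, appended to the defaults).
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    return CueLexicon(
        exception_cues=DEFAULT_CUES.exception_cues
        + tuple(data.get("exception_cues", [])),
        negation_cues=DEFAULT_CUES.negation_cues + tuple(data.get("negation_cues", [])),
    )


# -- sentence segmentation --------------------------------------------------

_SENT_DELIM = re.compile(r"[.;\n]")


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open sentence spans; boundaries at period, semicolon, newline."""
    spans = []
    start = 0
    for m in _SENT_DELIM.finditer(text):
        spans.append((start, m.end()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def _containing_sentence(text: str, pos: int) -> tuple[int, int]:
    for a, b in sentence_spans(text):
        if a <= pos < b:
            return a, b
    return 0, len(text)


# -- recognition ------------------------------------------------------------


def _mentions_at(
    text: str, start: int, end: int, terminology: Terminology, trial_id: str, passage_id: str
) -> list[EntityMention]:
    """Mentions for one regex match span, one per category of the resolved surface."""
    surface = text[start:end]
    hits = terminology.surface_index.get(normalize_surface(surface), [])
    by_cat: dict[str, list[str]] = {}
    for eid in hits:
        by_cat.setdefault(terminology.entries[eid].category, []).append(eid)
    return [
        EntityMention(
            trial_id=trial_id,
            passage_id=passage_id,
            start=start,
            end=end,
            surface=surface,
            category=cat,
            entry_ids=tuple(sorted(eids)),
        )
        for cat, eids in sorted(by_cat.items())
    ]


def recognize_entities(
    passage: Passage, terminology: Terminology, trial_id: str = ""
) -> list[EntityMention]:
    """Leftmost-longest non-overlapping dictionary matches in a passage.

    A surface shared by entries of several categories yields one mention per
    category (each carrying the resolved entries of that category).  Output
    is ordered by span start, then category.
    """
    pattern = terminology.surface_pattern()
    out: list[EntityMention] = []
    for m in pattern.finditer(passage.text):
        out.extend(
            _mentions_at(
                passage.text, m.start(), m.end(), terminology, trial_id, passage.passage_id
            )
        )
    return out


# -- minimization decomposition ---------------------------------------------


def _gap_is_connector(gap: str) -> bool:
    tokens = re.split(r"[\s,]+", gap.strip().casefold())
    return all(t in _CONNECTOR_TOKENS for t in tokens)


def _split_composites(
    text: str, mentions: list[EntityMention], terminology: Terminology
) -> list[EntityMention]:
    """Replace a composite mention by the atomic sub-entities it contains.

    A mention is composite when scanning its own surface finds two or more
    strictly shorter dictionary terms of at least two distinct categories
    that jointly cover every alphanumeric character of the surface.  An
    alteration term that merely names its own gene ("MET amplification",
    "EGFR L858R") is *not* torn apart: it already is the normalized
    gene:class pair, so only compounds crossing beyond the gene+alteration
    pair (e.g. alteration+cancer) are split.
    """
    pattern = terminology.surface_pattern()
    out: list[EntityMention] = []
    for m in mentions:
        subs: list[EntityMention] = []
        covered = [False] * len(m.surface)
        for sm in pattern.finditer(m.surface):
            if sm.end() - sm.start() == len(m.surface):
                continue
            subs.extend(
                _mentions_at(
                    m.surface, sm.start(), sm.end(), terminology, m.trial_id, m.passage_id
                )
            )
            for i in range(sm.start(), sm.end()):
                covered[i] = True
        cats = {s.category for s in subs}
        full_cover = all(
            covered[i] for i, ch in enumerate(m.surface) if ch.isalnum()
        )
        self_pair = m.category == "alteration" and cats <= {"gene", "alteration"}
        if len(subs) >= 2 and len(cats) >= 2 and full_cover and not self_pair:
            out.extend(
                replace(s, start=m.start + s.start, end=m.start + s.end, surface=s.surface)
                for s in subs
            )
        else:
            out.append(m)
    out.sort(key=lambda x: (x.start, x.category))
    return out


def decompose_minimal(
    text: str, mentions: Sequence[EntityMention], terminology: Terminology
) -> tuple[list[EntityMention], list[DerivedEntry]]:
    """Apply the minimization principle within one sentence.

    Returns the (possibly composite-split) mentions plus the derived
    normalized ``GENE:class`` pair entries from conjunction distribution.
    Non-distributable patterns pass through unchanged.  Distribution never
    loses a gene: one derived entry per conjoined gene mention.
    """
    mentions = _split_composites(text, list(mentions), terminology)
    derived: list[DerivedEntry] = []
    for i, alt in enumerate(mentions):
        if alt.category != "alteration":
            continue
        class_token = CLASS_WORDS.get(normalize_surface(alt.surface))
        if class_token is None:
            continue
        # walk left over gene mentions separated only by connector text
        run: list[EntityMention] = []
        cursor = alt
        for prev in reversed(mentions[:i]):
            if prev.end > cursor.start:  # co-located mention of another category
                continue
            gap = text[prev.end : cursor.start]
            if prev.category == "gene" and _gap_is_connector(gap):
                run.append(prev)
                cursor = prev
            else:
                break
        for gene in reversed(run):
            gene_name = (
                terminology.entries[gene.entry_ids[0]].canonical_name
                if gene.entry_ids
                else gene.surface
            )
            name = f"{gene_name}:{class_token}"
            derived.append(
                DerivedEntry(
                    name=name,
                    gene_symbol=gene_name,
                    class_token=class_token,
                    entry_ids=tuple(terminology.normalize_mention(name, "alteration")),
                    gene_mention=gene,
                    alteration_mention=alt,
                )
            )
    return mentions, derived


# -- classification ---------------------------------------------------------


def _cue_before(
    sentence: str, sent_start: int, mention_start: int, cues: Iterable[str]
) -> bool:
    rel = mention_start - sent_start
    folded = sentence.casefold()
    for cue in cues:
        for m in re.finditer(r"(?<![a-z0-9])" + re.escape(cue) + r"(?![a-z0-9])", folded):
            if m.end() <= rel:
                return True
    return False


def classify_criteria(
    mention: EntityMention, passage: Passage, cues: CueLexicon = DEFAULT_CUES
) -> str:
    """Assign a criteria class to one mention given its passage context.

    Follows loose-inclusion/tight-exclusion at the evidence level: only an
    explicit exception cue moves an exclusion-block mention to NC, and a
    negation cue conservatively demotes inclusion-block mentions to NC
    rather than promoting them to exclusion.
    """
    if mention.passage_id != passage.passage_id:
        raise ConsistencyError(
            f"mention passage {mention.passage_id!r} != {passage.passage_id!r}"
        )
    section = passage.section
    if section == "other":
        return "NA"
    if section == "eligibility_unsegmented":
        return "NC"
    a, b = _containing_sentence(passage.text, mention.start)
    sentence = passage.text[a:b]
    if section == "eligibility_inclusion":
        if _cue_before(sentence, a, mention.start, cues.negation_cues):
            return "NC"
        return "inclusion"
    if section == "eligibility_exclusion":
        if _cue_before(sentence, a, mention.start, cues.exception_cues):
            return "NC"
        return "exclusion"
    raise ConsistencyError(f"unknown section {section!r}")


# -- the full per-trial pipeline --------------------------------------------


@dataclass
class MinedTrial:
    """Full mining output for one trial (mentions retain their classes)."""

    trial_id: str
    mentions: list[tuple[EntityMention, str]] = field(default_factory=list)
    derived: list[tuple[DerivedEntry, str]] = field(default_factory=list)
    triplets: list[Triplet] = field(default_factory=list)


def mine_trial(
    trial: TrialRecord, terminology: Terminology, cues: CueLexicon = DEFAULT_CUES
) -> MinedTrial:
    """Run recognize → decompose → classify over every passage of a trial."""
    result = MinedTrial(trial_id=trial.trial_id)
    counts: dict[tuple[str, str], int] = {}

    def add(entry_ids: Iterable[str], cls: str) -> None:
        for eid in entry_ids:
            counts[(eid, cls)] = counts.get((eid, cls), 0) + 1

    for passage in trial.passages:
        raw = recognize_entities(passage, terminology, trial.trial_id)
        for a, b in sentence_spans(passage.text) or [(0, len(passage.text))]:
            sent_mentions = [m for m in raw if a <= m.start < b]
            mentions, derived = decompose_minimal(passage.text, sent_mentions, terminology)
            for m in mentions:
                cls = classify_criteria(m, passage, cues)
                result.mentions.append((m, cls))
                add(m.entry_ids, cls)
            for d in derived:
                cls = classify_criteria(d.alteration_mention, passage, cues)
                result.derived.append((d, cls))
                add(d.entry_ids, cls)
    result.triplets = [
        Triplet(entry_id=eid, criteria_class=cls, trial_id=trial.trial_id, evidence=n)
        for (eid, cls), n in sorted(counts.items())
    ]
    return result


def build_triplets(
    trial: TrialRecord, terminology: Terminology, cues: CueLexicon = DEFAULT_CUES
) -> list[Triplet]:
    """Entity–criteria–trial triplets for one trial (deduplicated, sorted)."""
    return mine_trial(trial, terminology, cues).triplets
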