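"""Parse trial records from a BioC-style JSON dialect and segment eligibility text.

A record is a JSON object with registry-style metadata and an ordered list
of text passages.  Eligibility passages are split at the conventional
``Inclusion Criteria`` / ``Exclusion Criteria`` headers into inclusion,
exclusion and (for text before any header) unsegmented blocks; everything
else is an ``other`` passage.  Segmentation is a partition — concatenating
the passage texts reproduces the input byte for byte — so no text is ever
dropped.

The accepted record schema (also available as JSON Schema via
:func:`record_json_schema`)::

    {
      "trial_id": "NCT01234567",
      "title": "...",
      "metadata": {
        "status": "Recruiting", "phase": "Phase 2", "gender": "All",
        "min_age": "18 Years", "max_age": "N/A", "countries": ["US"]
      },
      "passages": [
        {"type": "eligibility", "text": "Inclusion Criteria: ..."},
        {"type": "other", "text": "Brief summary ..."}
      ]
    }
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pydantic

from .errors import MetadataError, TrialParseError

SECTIONS = (
    "eligibility_inclusion",
    "eligibility_exclusion",
    "eligibility_unsegmented",
    "other",
)
ELIGIBILITY_SECTIONS = SECTIONS[:3]

STATUSES = (
    "not_yet_recruiting",
    "recruiting",
    "active_not_recruiting",
    "completed",
    "terminated",
    "unknown",
)
PHASES = ("early1", "1", "1_2", "2", "2_3", "3", "4", "na")
GENDERS = ("all", "male", "female")

_STATUS_MAP = {
    "not yet recruiting": "not_yet_recruiting",
    "recruiting": "recruiting",
    "active, not recruiting": "active_not_recruiting",
    "active not recruiting": "active_not_recruiting",
    "completed": "completed",
    "terminated": "terminated",
    "unknown": "unknown",
    "unknown status": "unknown",
}
_STATUS_MAP.update({s.replace("_", " "): s for s in STATUSES})
_STATUS_MAP.update({s: s for s in STATUSES})

_PHASE_MAP = {
    "early phase 1": "early1",
    "phase 1": "1",
    "phase 1/phase 2": "1_2",
    "phase 2": "2",
    "phase 2/phase 3": "2_3",
    "phase 3": "3",
    "phase 4": "4",
    "n/a": "na",
    "not applicable": "na",
}
_PHASE_MAP.update({p: p for p in PHASES})

_GENDER_MAP = {"all": "all", "male": "male", "female": "female", "": "all"}

_AGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(year|month|week|day|hour)s?\s*$", re.I)
_AGE_FACTOR = {"year": 1.0, "month": 1 / 12, "week": 1 / 52, "day": 1 / 365, "hour": 1 / 8760}


def parse_age(value) -> float | None:
    """Parse a registry age string to years; ``None`` means unbounded."""
    if value is None:
        return None
    if isinstance(value, (int, float)):
        if value < 0:
            raise MetadataError(f"negative age {value!r}")
        return float(value)
    s = str(value).strip()
    if s == "" or s.upper() == "N/A":
        return None
    m = _AGE_RE.match(s)
    if m is None:
        raise MetadataError(f"unparseable age string {value!r}")
    return float(m.group(1)) * _AGE_FACTOR[m.group(2).lower()]


@dataclass(frozen=True)
class TrialMetadata:
    status: str = "unknown"
    phase: str = "na"
    gender: str = "all"
    min_age_years: float | None = None  # None = unbounded
    max_age_years: float | None = None
    countries: frozenset[str] = frozenset()

    def __post_init__(self):
        if (
            self.min_age_years is not None
            and self.max_age_years is not None
            and self.min_age_years > self.max_age_years
        ):
            raise MetadataError(
                f"min_age {self.min_age_years} exceeds max_age {self.max_age_years}"
            )


@dataclass(frozen=True)
class Passage:
    """A block of trial text; offsets in mentions are 0-based within ``text``."""

    passage_id: str
    section: str
    text: str


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    title: str
    metadata: TrialMetadata
    passages: tuple[Passage, ...]

    def eligibility_passages(self) -> tuple[Passage, ...]:
        return tuple(p for p in self.passages if p.section in ELIGIBILITY_SECTIONS)


# -- segmentation -----------------------------------------------------------

_HEADER_RE = re.compile(r"(inclusion|exclusion)\s+criteria\s*:?", re.IGNORECASE)


def segment_eligibility(text: str, trial_id: str = "", start_index: int = 0) -> list[Passage]:
    """Split raw eligibility text at inclusion/exclusion headers.

    Every header starts a new passage of its type (header text included, so
    the passages partition the input exactly); text before the first header
    becomes an ``eligibility_unsegmented`` passage.  The empty string yields
    no passages.
    """
    if text == "":
        return []
    cuts: list[tuple[int, str]] = [
        (m.start(), "eligibility_" + m.group(1).lower()) for m in _HEADER_RE.finditer(text)
    ]
    spans: list[tuple[int, int, str]] = []
    if not cuts or cuts[0][0] > 0:
        end = cuts[0][0] if cuts else len(text)
        spans.append((0, end, "eligibility_unsegmented"))
    for i, (start, section) in enumerate(cuts):
        end = cuts[i + 1][0] if i + 1 < len(cuts) else len(text)
        spans.append((start, end, section))
    prefix = f"{trial_id}:" if trial_id else ""
    return [
        Passage(passage_id=f"{prefix}{start_index + i}", section=sec, text=text[a:b])
        for i, (a, b, sec) in enumerate(spans)
    ]


# -- record schema ----------------------------------------------------------


class _RawPassage(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    type: str = "other"
    text: str


class _RawMetadata(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    status: str = "unknown"
    phase: str = "na"
    gender: str = "all"
    min_age: str | float | None = None
    max_age: str | float | None = None
    countries: list[str] = []


class _RawTrial(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    trial_id: str = pydantic.Field(pattern=r"^\S+$")
    title: str = ""
    metadata: _RawMetadata = _RawMetadata()
    passages: list[_RawPassage] = []


def record_json_schema() -> dict:
    """JSON Schema of the accepted trial-record dialect."""
    return _RawTrial.model_json_schema()


_PASSAGE_TYPE_ALIASES = {s: s for s in SECTIONS}
_PASSAGE_TYPE_ALIASES["eligibility"] = "eligibility"


def _norm_enum(value: str, mapping: dict, what: str) -> str:
    key = str(value).strip().casefold()
    if key not in mapping:
        raise MetadataError(f"unrecognized {what} {value!r}")
    return mapping[key]


def parse_trial(record: dict) -> TrialRecord:
    """Validate and normalize one raw JSON record into a TrialRecord.

    Passage types may be ``eligibility`` (raw text, segmented here), one of
    the already-segmented section names, or ``other``.  Raises
    :class:`TrialParseError` with a JSON-pointer path on schema violations
    and :class:`MetadataError` on unparseable metadata values.
    """
    try:
        raw = _RawTrial.model_validate(record)
    except pydantic.ValidationError as exc:
        err = exc.errors()[0]
        pointer = "/" + "/".join(str(p) for p in err["loc"])
        raise TrialParseError(err["msg"], pointer) from None
    md = TrialMetadata(
        status=_norm_enum(raw.metadata.status, _STATUS_MAP, "status"),
        phase=_norm_enum(raw.metadata.phase, _PHASE_MAP, "phase"),
        gender=_norm_enum(raw.metadata.gender, _GENDER_MAP, "gender"),
        min_age_years=parse_age(raw.metadata.min_age),
        max_age_years=parse_age(raw.metadata.max_age),
        countries=frozenset(raw.metadata.countries),
    )
    passages: list[Passage] = []
    counter = 0
    for p in raw.passages:
        ptype = p.type.strip().casefold()
        if ptype not in _PASSAGE_TYPE_ALIASES:
            raise TrialParseError(f"unknown passage type {p.type!r}", "/passages")
        if ptype == "eligibility":
            segs = segment_eligibility(p.text, raw.trial_id, start_index=counter)
            passages.extend(segs)
            counter += len(segs)
        else:
            passages.append(
                Passage(passage_id=f"{raw.trial_id}:{counter}", section=ptype, text=p.text)
            )
            counter += 1
    return TrialRecord(
        trial_id=raw.trial_id, title=raw.title, metadata=md, passages=tuple(passages)
    )


def write_trial(trial: TrialRecord) -> dict:
    """Serialize a TrialRecord to the JSON dialect; inverse of parse_trial."""
    return {
        "trial_id": trial.trial_id,
        "title": trial.title,
        "metadata": {
            "status": trial.metadata.status,
            "phase": trial.metadata.phase,
            "gender": trial.metadata.gender,
            "min_age": trial.metadata.min_age_years,
            "max_age": trial.metadata.max_age_years,
            "countries": sorted(trial.metadata.countries),
        },
        "passages": [{"type": p.section, "text": p.text} for p in trial.passages],
    }


def read_trials(path: str | Path) -> Iterator[TrialRecord]:
    """Read trial records from a JSON-lines file or a directory of ``*.json``."""
    path = Path(path)
    if path.is_dir():
        for f in sorted(path.glob("*.json")):
            yield parse_trial(json.loads(f.read_text()))
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield parse_trial(json.loads(line))


def write_trials(trials: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trials as JSON-lines (one record per line)."""
    with open(path, "w") as fh:
        for t in trials:
            fh.write(json.dumps(write_trial(t), sort_keys=True) + "\n")
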