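"""Terminologies of standard entries and surface-form normalization.

Six categories of biological entities are handled: cancers, genes,
alterations, drugs, biomarkers and therapies.  Each terminology row is a
*standard entry* — a normalized concept with a canonical name, a synonym
set, optional parent links (same-category, acyclic) and optional
cross-references to source vocabularies.  Mentions found in trial text are
mapped onto standard entries by case-insensitive, whitespace-normalized
exact matching against the synonym closure; fuzzy matching is deliberately
not performed so every normalization step is auditable.

Alteration entries follow the compound convention ``GENE:class`` (for
example ``KEAP1:mutation`` or ``EGFR:exon21mut``): the gene half is expected
to resolve in the gene terminology.

File format: UTF-8 TSV with columns ``entry_id``, ``category``,
``canonical_name``, ``synonyms``, ``parents``, ``xrefs``; multi-valued
columns are pipe-separated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import CycleError, LookupError_, TerminologyError

CATEGORIES = ("cancer", "gene", "alteration", "drug", "biomarker", "therapy")

COLUMNS = ("entry_id", "category", "canonical_name", "synonyms", "parents", "xrefs")

_WS = re.compile(r"\s+")


def normalize_surface(surface: str) -> str:
    """Case-fold and collapse internal whitespace; the index key for a synonym."""
    return _WS.sub(" ", surface.strip()).casefold()


@dataclass(frozen=True)
class StandardEntry:
    """One normalized term in a terminology."""

    entry_id: str
    category: str
    canonical_name: str
    synonyms: frozenset[str] = frozenset()
    parents: frozenset[str] = frozenset()
    xrefs: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise TerminologyError(
                f"unknown category {self.category!r} for entry {self.entry_id!r}"
            )

    @property
    def surfaces(self) -> frozenset[str]:
        """Canonical name plus synonyms (the synonym closure)."""
        return self.synonyms | {self.canonical_name}


class Terminology:
    """A set of standard entries with per-category and surface indexes.

    ``surface_index`` maps a normalized surface form to the sorted list of
    entry ids whose synonym closure contains it.  Ambiguous synonyms (one
    surface owned by several entries) are preserved as list-valued hits;
    downstream consumers decide how to use them.
    """

    def __init__(self, entries: Iterable[StandardEntry]):
        self.entries: dict[str, StandardEntry] = {}
        for e in sorted(entries, key=lambda e: e.entry_id):
            if e.entry_id in self.entries:
                raise TerminologyError(f"duplicate entry_id {e.entry_id!r}")
            self.entries[e.entry_id] = e
        self.by_category: dict[str, list[str]] = {c: [] for c in CATEGORIES}
        self.surface_index: dict[str, list[str]] = {}
        for eid, e in self.entries.items():
            self.by_category[e.category].append(eid)
            for s in e.surfaces:
                key = normalize_surface(s)
                if not key:
                    continue
                hits = self.surface_index.setdefault(key, [])
                if eid not in hits:
                    hits.append(eid)
        for hits in self.surface_index.values():
            hits.sort()
        self._check_parents()
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._pattern: re.Pattern | None = None

    # -- construction checks ------------------------------------------------

    def _check_parents(self) -> None:
        for e in self.entries.values():
            for p in e.parents:
                if p not in self.entries:
                    raise TerminologyError(
                        f"entry {e.entry_id!r} references unknown parent {p!r}"
                    )
                if self.entries[p].category != e.category:
                    raise TerminologyError(
                        f"parent link {e.entry_id!r} -> {p!r} crosses categories"
                    )
        # iterative DFS cycle detection, reporting the cycle path
        color: dict[str, int] = {}
        for root in self.entries:
            if color.get(root):
                continue
            stack = [(root, iter(sorted(self.entries[root].parents)))]
            color[root] = 1
            path = [root]
            while stack:
                node, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    color[node] = 2
                    stack.pop()
                    path.pop()
                    continue
                if color.get(nxt) == 1:
                    raise CycleError(path[path.index(nxt):] + [nxt])
                if not color.get(nxt):
                    color[nxt] = 1
                    path.append(nxt)
                    stack.append((nxt, iter(sorted(self.entries[nxt].parents))))

    # -- queries ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self.entries

    def get(self, entry_id: str) -> StandardEntry:
        try:
            return self.entries[entry_id]
        except KeyError:
            raise LookupError_(f"unknown entry_id {entry_id!r}") from None

    def normalize_mention(self, surface: str, category: str | None = None) -> list[str]:
        """Resolve a surface mention to standard entries.

        Returns all entry ids whose synonym closure contains the case-folded,
        whitespace-normalized surface, restricted to ``category`` when given,
        sorted ascending.  An unknown surface yields an empty list (not an
        error).
        """
        hits = self.surface_index.get(normalize_surface(surface), [])
        if category is None:
            return list(hits)
        return [h for h in hits if self.entries[h].category == category]

    def ancestors(self, entry_id: str) -> frozenset[str]:
        """Transitive closure over parent links (the entry itself excluded)."""
        if entry_id not in self.entries:
            raise LookupError_(f"unknown entry_id {entry_id!r}")
        cached = self._ancestor_cache.get(entry_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.entries[entry_id].parents:
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[entry_id] = result
        return result

    def is_or_subtype_of(self, a: str, b: str) -> bool:
        """True when ``a`` equals ``b`` or ``b`` is an ancestor of ``a``."""
        if b not in self.entries:
            raise LookupError_(f"unknown entry_id {b!r}")
        return a == b or b in self.ancestors(a)

    def surface_pattern(self) -> re.Pattern:
        """Compiled alternation over every indexed surface form.

        Alternatives are ordered longest-first so that scanning with
        ``finditer`` yields leftmost-longest, non-overlapping matches on
        word boundaries.  Spaces in a synonym match any whitespace run.
        """
        if self._pattern is None:
            alts = sorted(self.surface_index, key=lambda s: (-len(s), s))
            if not alts:
                self._pattern = re.compile(r"(?!x)x")  # matches nothing
            else:
                body = "|".join(re.escape(a).replace(r"\ ", r"\s+") for a in alts)
                self._pattern = re.compile(
                    r"(?<![A-Za-z0-9])(?:" + body + r")(?![A-Za-z0-9])",
                    re.IGNORECASE,
                )
        return self._pattern


# -- TSV I/O ----------------------------------------------------------------


def _split_multi(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    parts = [p.strip() for p in str(value).split("|")]
    return frozenset(p for p in parts if p)


def load_terminology(files: str | Path | Iterable[str | Path]) -> Terminology:
    """Load one or more terminology TSV files into a single Terminology.

    Rows from all files are merged; the result is independent of row and
    file order.  Raises :class:`TerminologyError` on a missing required
    column or unknown category token, :class:`CycleError` on cyclic parent
    links.
    """
    if isinstance(files, (str, Path)):
        files = [files]
    frames = []
    for f in files:
        df = pd.read_csv(f, sep="\t", dtype=str, keep_default_na=False, na_values=[])
        missing = {"entry_id", "category", "canonical_name"} - set(df.columns)
        if missing:
            raise TerminologyError(f"{f}: missing columns {sorted(missing)}")
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=COLUMNS)
    entries = []
    for row in merged.itertuples(index=False):
        d = row._asdict()
        entries.append(
            StandardEntry(
                entry_id=d["entry_id"],
                category=d["category"],
                canonical_name=d["canonical_name"],
                synonyms=_split_multi(d.get("synonyms", "")),
                parents=_split_multi(d.get("parents", "")),
                xrefs=_split_multi(d.get("xrefs", "")),
            )
        )
    return Terminology(entries)


def write_terminology(term: Terminology, path: str | Path) -> None:
    """Write a terminology back to a single TSV (inverse of load)."""
    rows = []
    for eid in sorted(term.entries):
        e = term.entries[eid]
        rows.append(
            {
                "entry_id": e.entry_id,
                "category": e.category,
                "canonical_name": e.canonical_name,
                "synonyms": "|".join(sorted(e.synonyms)),
                "parents": "|".join(sorted(e.parents)),
                "xrefs": "|".join(sorted(e.xrefs)),
            }
        )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)
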