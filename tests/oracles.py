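"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — linear scans, nested loops,
boolean-matrix reachability — and shares no code path with the package
internals it checks.
"""

from __future__ import annotations

import numpy as np


def linear_scan_normalize(entries, surface: str, category: str | None = None) -> list[str]:
    """Resolve a surface by scanning every entry's synonym closure."""

    def norm(s: str) -> str:
        return " ".join(s.split()).casefold()

    key = norm(surface)
    hits = []
    for e in entries:
        if category is not None and e.category != category:
            continue
        if any(norm(s) == key for s in set(e.synonyms) | {e.canonical_name}):
            hits.append(e.entry_id)
    return sorted(hits)


def reachability_closure(ids: list[str], parent_edges: set[tuple[str, str]]) -> dict[str, set[str]]:
    """Ancestor sets via boolean matrix repeated squaring."""
    index = {eid: i for i, eid in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for child, parent in parent_edges:
        adj[index[child], index[parent]] = True
    closure = adj.copy()
    for _ in range(max(1, n.bit_length())):
        closure = closure | (closure @ closure)
    return {eid: {ids[j] for j in np.flatnonzero(closure[i])} for eid, i in index.items()}


def enumerate_leftmost_longest(text: str, surfaces: list[str]) -> list[tuple[int, int]]:
    """All substring dictionary matches, then greedy leftmost-longest selection."""

    def is_boundary(i: int) -> bool:
        return i < 0 or i >= len(text) or not text[i].isalnum()

    folded = text.casefold()
    candidates = []
    for s in surfaces:
        sf = s.casefold()
        start = 0
        while True:
            i = folded.find(sf, start)
            if i < 0:
                break
            if is_boundary(i - 1) and is_boundary(i + len(sf)):
                candidates.append((i, i + len(sf)))
            start = i + 1
    candidates.sort(key=lambda span: (span[0], span[0] - span[1]))
    chosen: list[tuple[int, int]] = []
    last_end = 0
    for a, b in candidates:
        if a >= last_end:
            chosen.append((a, b))
            last_end = b
    return chosen


def brute_force_category(
    triplets: list,
    trial_id: str,
    cancer_entries: set[str],
    variation_entries: set[str],
    prior_entries: set[str],
    mode: str,
) -> str | None:
    """Candidate status + category by nested loops over the triplet table.

    Returns None when the trial is not a candidate under the mode.
    Mirrors the matching rules: inclusion-or-NA makes a dimension match
    for candidacy; any exclusion hit on any profile item vetoes; positive
    needs inclusion evidence on the confirming dimension (both dimensions
    at least candidate-level in combination mode); NC is ignored.
    """
    mine = [t for t in triplets if t.trial_id == trial_id]

    def dim_hit(entries: set[str], classes: tuple[str, ...]) -> bool:
        for t in mine:
            for e in entries:
                if t.entry_id == e and t.criteria_class in classes:
                    return True
        return False

    var_cand = dim_hit(variation_entries, ("inclusion", "NA"))
    can_cand = dim_hit(cancer_entries, ("inclusion", "NA"))
    candidate = {
        "basket": var_cand,
        "umbrella": can_cand,
        "combination": var_cand or can_cand,
    }[mode]
    if not candidate:
        return None
    everything = cancer_entries | variation_entries | prior_entries
    if dim_hit(everything, ("exclusion",)):
        return "negative"
    var_incl = dim_hit(variation_entries, ("inclusion",))
    can_incl = dim_hit(cancer_entries, ("inclusion",))
    positive = {
        "basket": can_incl,
        "umbrella": var_incl,
        "combination": (can_incl and var_cand) or (var_incl and can_cand),
    }[mode]
    return "positive" if positive else "unclassified"


def passes_filters(metadata, filters) -> bool:
    """Metadata filter predicate, re-stated from the documented semantics."""
    if filters.statuses is not None and metadata.status not in filters.statuses:
        return False
    if filters.phases is not None and metadata.phase not in filters.phases:
        return False
    if filters.countries is not None:
        if not set(filters.countries) & set(metadata.countries):
            return False
    if filters.gender is not None and metadata.gender not in ("all", filters.gender):
        return False
    if filters.age_years is not None:
        lo = metadata.min_age_years if metadata.min_age_years is not None else -1e9
        hi = metadata.max_age_years if metadata.max_age_years is not None else 1e9
        if not (lo <= filters.age_years <= hi):
            return False
    return True
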