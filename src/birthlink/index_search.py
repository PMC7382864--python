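"""Blocking via a purpose-built inverted index with a tiered query cascade.

Comparing every birth against every cohort person is quadratic and
infeasible at register scale; instead the cohort is indexed once and each
birth probes it with a cascade of three query tiers of decreasing
strictness:

* **exact** — candidates equal to the probe on *every* supplied attribute
  (full standardized name, municipality code, and mother date of birth
  when the probe carries one);
* **semi-fuzzy** — candidates that disagree on exactly one supplied
  attribute (union of leave-one-attribute-out exact intersections, minus
  the exact tier);
* **fuzzy** — candidates sharing at least one name token with the probe,
  ranked by shared-token count then normalized Damerau-Levenshtein
  similarity of the full name, with candidates at or below a similarity
  floor (default 0.5) discarded.

The cascade concatenates exact, then semi-fuzzy, then fuzzy candidates,
deduplicates keeping the highest tier, and truncates to the ``k`` best
(default 1000).  All tie-breaks are deterministic.
"""

from __future__ import annotations

from bisect import insort
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .similarity import normalized_dl_similarity

__all__ = [
    "InvertedIndex",
    "Candidate",
    "CandidateSet",
    "build_index",
    "query_exact",
    "query_semi_fuzzy",
    "query_fuzzy",
    "retrieve_candidates",
]

TIER_ORDER = {"exact": 0, "semi_fuzzy": 1, "fuzzy": 2}


@dataclass(frozen=True)
class Candidate:
    cohort_id: str
    tier: str  # exact | semi_fuzzy | fuzzy
    score: float  # retrieval score (fuzzy: normalized DL; other tiers: 1.0)


@dataclass(frozen=True)
class CandidateSet:
    probe_id: str
    candidates: tuple[Candidate, ...]

    def ids(self) -> list[str]:
        return [c.cohort_id for c in self.candidates]


@dataclass
class InvertedIndex:
    """Token postings over the cohort register.

    ``postings`` maps ``(field, token)`` to a sorted duplicate-free list
    of cohort ids.  Indexed fields: individual name tokens (``name``),
    the full standardized name (``name_exact``), ``municipality``,
    ``state`` and ``dob`` (ISO text; missing values are simply absent
    from the postings).  ``names`` keeps each record's full name for
    fuzzy re-ranking.
    """

    postings: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def posting(self, fieldname: str, token: str) -> list[str]:
        return self.postings.get((fieldname, token), [])

    def _add(self, fieldname: str, token: str, cohort_id: str) -> None:
        lst = self.postings.setdefault((fieldname, token), [])
        if not lst or lst[-1] < cohort_id:
            lst.append(cohort_id)
        elif cohort_id not in lst:
            insort(lst, cohort_id)


def build_index(cohort: pd.DataFrame) -> InvertedIndex:
    """Single-pass deterministic index build over preprocessed cohort rows.

    Expects columns ``person_id``, ``name``, ``municipality``, ``state``,
    ``dob``.  Duplicate person ids are an error.
    """
    index = InvertedIndex()
    seen: set[str] = set()
    for row in cohort.itertuples(index=False):
        pid = str(row.person_id)
        if pid in seen:
            raise ValueError(f"duplicate cohort id {pid!r}")
        seen.add(pid)
        name = str(row.name) if pd.notna(row.name) else ""
        index.names[pid] = name
        if name:
            index._add("name_exact", name, pid)
            for tok in set(name.split(" ")):
                index._add("name", tok, pid)
        for fieldname in ("municipality", "state", "dob"):
            val = getattr(row, fieldname, None)
            if val is None or (isinstance(val, float) and pd.isna(val)) or str(val) == "":
                continue
            index._add(fieldname, str(val), pid)
    return index


def _probe_attrs(probe: Mapping[str, str]) -> list[tuple[str, str]]:
    """Supplied (field, value) pairs in canonical order; empty values dropped."""
    attrs: list[tuple[str, str]] = []
    for fieldname, key in (("name_exact", "name"), ("municipality", "municipality"), ("dob", "dob")):
        val = probe.get(key)
        if val is not None and str(val) != "" and not (isinstance(val, float) and pd.isna(val)):
            attrs.append((fieldname, str(val)))
    return attrs


def _intersect(index: InvertedIndex, attrs: Sequence[tuple[str, str]]) -> list[str]:
    if not attrs:
        return []
    lists = [index.posting(f, v) for f, v in attrs]
    out = set(lists[0])
    for lst in lists[1:]:
        out &= set(lst)
        if not out:
            break
    return sorted(out)


def query_exact(index: InvertedIndex, probe: Mapping[str, str]) -> list[str]:
    """Cohort ids equal to the probe on every supplied attribute (sorted)."""
    return _intersect(index, _probe_attrs(probe))


def query_semi_fuzzy(index: InvertedIndex, probe: Mapping[str, str]) -> list[str]:
    """Ids agreeing on all but exactly one supplied attribute (sorted).

    Empty by construction when fewer than two attributes are supplied.
    """
    attrs = _probe_attrs(probe)
    if len(attrs) < 2:
        return []
    exact = set(query_exact(index, probe))
    out: set[str] = set()
    for leave in range(len(attrs)):
        rest = [a for i, a in enumerate(attrs) if i != leave]
        out |= set(_intersect(index, rest))
    return sorted(out - exact)


def query_fuzzy(
    index: InvertedIndex,
    probe: Mapping[str, str],
    dl_floor: float = 0.5,
) -> list[tuple[str, float]]:
    """Name-token candidates ranked by fuzzy name agreement.

    Candidates share >= 1 name token with the probe; ranking key is
    (shared-token count desc, normalized Damerau-Levenshtein similarity
    of the full names desc, cohort id asc).  Candidates whose similarity
    is <= ``dl_floor`` are removed.  Returns (cohort id, similarity).
    """
    name = str(probe.get("name", "") or "")
    if not name:
        return []
    tokens = set(name.split(" "))
    shared: dict[str, int] = {}
    for tok in tokens:
        for pid in index.posting("name", tok):
            shared[pid] = shared.get(pid, 0) + 1
    scored = []
    for pid, count in shared.items():
        sim = normalized_dl_similarity(name, index.names[pid])
        if sim > dl_floor:
            scored.append((pid, count, sim))
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [(pid, sim) for pid, _, sim in scored]


def retrieve_candidates(
    index: InvertedIndex,
    probe: Mapping[str, str],
    k: int = 1000,
    dl_floor: float = 0.5,
    probe_id: str = "",
) -> CandidateSet:
    """Tiered cascade: exact, then semi-fuzzy, then fuzzy, truncated to k.

    Duplicates keep their highest tier.  ``probe`` supplies ``name`` (and
    usually ``municipality``; ``dob`` when the record carries one).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    out: list[Candidate] = []
    seen: set[str] = set()
    for pid in query_exact(index, probe):
        out.append(Candidate(pid, "exact", 1.0))
        seen.add(pid)
    for pid in query_semi_fuzzy(index, probe):
        if pid not in seen:
            out.append(Candidate(pid, "semi_fuzzy", 1.0))
            seen.add(pid)
    for pid, sim in query_fuzzy(index, probe, dl_floor=dl_floor):
        if pid not in seen:
            out.append(Candidate(pid, "fuzzy", sim))
            seen.add(pid)
    return CandidateSet(probe_id=probe_id, candidates=tuple(out[:k]))
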