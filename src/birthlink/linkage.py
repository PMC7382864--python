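"""Pairwise scoring and one-to-one link assignment.

Each (birth, cohort-candidate) pair is scored as a weight-normalized mean
of per-attribute similarities:

    score = sum_i w_i * s_i / sum_i w_i      over *available* attributes

with default weights reflecting discriminatory power: mother name 1.0,
mother date of birth or age 1.0, municipality 0.16, state 0.008.  Names
compare by Jaro-Winkler; dates by normalized positional agreement of the
8-digit compact form; municipality and state are administrative codes and
compare as 0/1 equality.  Restricting the mean to available attributes
keeps scores in [0, 1] and comparable across the era in which the birth
form did not collect the mother's date of birth.

Two eras (routes):

* ``dob`` — the birth record carries the mother's date of birth; its
  similarity to the candidate's date of birth enters the score directly;
* ``age`` — no mother DOB on the birth record; the mother's age derived
  from the candidate's DOB and the child's DOB must equal the recorded
  age *exactly* for the candidate to survive
  (:func:`age_consistency_filter`), and the age attribute then
  contributes similarity 1.  ``auto`` picks per record.

Assignment is globally greedy one-to-one: all scored pairs sorted by
score descending, a pair accepted only if both its birth and its cohort
record are still free; ties break on (birth id, cohort id) so the result
is order-independent.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import pandas as pd

from .index_search import Candidate, InvertedIndex, retrieve_candidates
from .similarity import jaro_winkler, normalized_date_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "AttributeWeights",
    "ComparisonPair",
    "LinkDecision",
    "derive_maternal_age",
    "age_consistency_filter",
    "score_pair",
    "assign_best_links",
    "find_offspring",
    "link_registers",
]


@dataclass(frozen=True)
class AttributeWeights:
    """Dimensionless attribute weights; defaults are the operational values."""

    name: float = 1.0
    mother_dob_or_age: float = 1.0
    state: float = 0.008
    municipality: float = 0.16

    def __post_init__(self) -> None:
        for f in ("name", "mother_dob_or_age", "state", "municipality"):
            if getattr(self, f) <= 0:
                raise ValueError(f"weight {f} must be positive")


@dataclass(frozen=True)
class ComparisonPair:
    birth_id: str
    cohort_id: str
    name_sim: float
    dob_or_age_sim: float | None  # None = attribute not comparable
    municipality_sim: float
    state_sim: float
    score: float


@dataclass(frozen=True)
class LinkDecision:
    birth_id: str
    cohort_id: str | None
    score: float
    classification: str = "non_link"  # link | non_link


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def derive_maternal_age(child_dob, mother_dob) -> int:
    """Completed years between the mother's and the child's dates of birth.

    Calendar arithmetic (year difference, minus one if the child's
    month/day precedes the mother's birthday) — an exact-equality filter
    downstream is sensitive to off-by-one ages, so no day-count division
    is used.
    """
    child = _parse_date(child_dob)
    mother = _parse_date(mother_dob)
    if mother >= child:
        raise ValueError(
            f"mother DOB {mother} is not before child DOB {child}"
        )
    years = child.year - mother.year
    if (child.month, child.day) < (mother.month, mother.day):
        years -= 1
    return years


def age_consistency_filter(
    candidates: list[Candidate],
    cohort_dobs: dict[str, str],
    child_dob,
    recorded_age,
) -> list[Candidate]:
    """Keep candidates whose derived maternal age equals the recorded age.

    Applied on the age route (no mother DOB on the birth record).  When
    the recorded age itself is missing the filter is skipped — every
    candidate passes (logged), and the age attribute is simply not
    comparable downstream.
    """
    if recorded_age is None or (isinstance(recorded_age, float) and pd.isna(recorded_age)):
        logger.debug("recorded mother age missing; age filter skipped")
        return list(candidates)
    recorded = int(recorded_age)
    kept = []
    for cand in candidates:
        dob = cohort_dobs.get(cand.cohort_id)
        if dob is None or dob == "":
            continue
        try:
            derived = derive_maternal_age(child_dob, dob)
        except ValueError:
            continue  # impossible mother (born after child)
        if derived == recorded:
            kept.append(cand)
    return kept


def _compact(date_text: str) -> str:
    return str(date_text).replace("-", "")


def score_pair(
    birth: dict,
    candidate: dict,
    weights: AttributeWeights = AttributeWeights(),
    era: str = "auto",
    age_passed: bool = True,
) -> ComparisonPair:
    """Weighted-mean similarity score for one (birth, candidate) pair.

    ``birth`` needs ``birth_id``, ``mother_name``, ``municipality``,
    ``state`` and (era-dependent) ``mother_dob`` / ``mother_age`` +
    ``child_dob``; ``candidate`` needs ``person_id``, ``name``, ``dob``,
    ``municipality``, ``state``.  On the age route the caller states via
    ``age_passed`` whether the candidate survived the exact-age filter;
    survivors contribute similarity 1 on the age attribute.

    Raises ``ValueError`` if no attribute is comparable.
    """
    if era not in ("auto", "dob", "age"):
        raise ValueError(f"era must be auto|dob|age, got {era!r}")

    def _present(v) -> bool:
        return v is not None and str(v) != "" and not (isinstance(v, float) and pd.isna(v))

    mother_dob = birth.get("mother_dob")
    use_dob = era == "dob" or (era == "auto" and _present(mother_dob))
    if era == "dob" and not _present(mother_dob):
        raise ValueError(f"birth {birth.get('birth_id')}: dob era but mother_dob missing")

    sims: list[tuple[float, float]] = []  # (weight, similarity)
    name_sim = 0.0
    if _present(birth.get("mother_name")) and _present(candidate.get("name")):
        name_sim = jaro_winkler(str(birth["mother_name"]), str(candidate["name"]))
        sims.append((weights.name, name_sim))

    dob_or_age_sim: float | None = None
    if use_dob and _present(candidate.get("dob")):
        dob_or_age_sim = normalized_date_similarity(
            _compact(mother_dob), _compact(candidate["dob"])
        )
        sims.append((weights.mother_dob_or_age, dob_or_age_sim))
    elif not use_dob and _present(birth.get("mother_age")):
        # exact-age gate already applied; survivors score 1
        dob_or_age_sim = 1.0 if age_passed else 0.0
        sims.append((weights.mother_dob_or_age, dob_or_age_sim))

    muni_sim = float(
        _present(birth.get("municipality"))
        and _present(candidate.get("municipality"))
        and str(birth["municipality"]) == str(candidate["municipality"])
    )
    if _present(birth.get("municipality")) and _present(candidate.get("municipality")):
        sims.append((weights.municipality, muni_sim))
    state_sim = float(
        _present(birth.get("state"))
        and _present(candidate.get("state"))
        and str(birth["state"]) == str(candidate["state"])
    )
    if _present(birth.get("state")) and _present(candidate.get("state")):
        sims.append((weights.state, state_sim))

    if not sims:
        raise ValueError(
            f"pair ({birth.get('birth_id')}, {candidate.get('person_id')}): "
            "no comparable attribute"
        )
    total_w = sum(w for w, _ in sims)
    score = sum(w * s for w, s in sims) / total_w
    return ComparisonPair(
        birth_id=str(birth["birth_id"]),
        cohort_id=str(candidate["person_id"]),
        name_sim=name_sim,
        dob_or_age_sim=dob_or_age_sim,
        municipality_sim=muni_sim,
        state_sim=state_sim,
        score=score,
    )


def assign_best_links(
    pairs: list[ComparisonPair],
    birth_ids: list[str] | None = None,
) -> list[LinkDecision]:
    """Globally greedy one-to-one assignment over all scored pairs.

    Pairs sorted by (score desc, birth id asc, cohort id asc); a pair is
    accepted iff neither side is taken.  Every birth in ``birth_ids``
    (default: every birth appearing in ``pairs``) gets a decision; births
    left without a free candidate get a null cohort id and score 0.
    No cohort id is assigned twice.
    """
    ordered = sorted(pairs, key=lambda p: (-p.score, p.birth_id, p.cohort_id))
    taken_birth: set[str] = set()
    taken_cohort: set[str] = set()
    decided: dict[str, LinkDecision] = {}
    conflicts = 0
    for p in ordered:
        if p.birth_id in taken_birth:
            continue
        if p.cohort_id in taken_cohort:
            conflicts += 1
            continue
        taken_birth.add(p.birth_id)
        taken_cohort.add(p.cohort_id)
        decided[p.birth_id] = LinkDecision(p.birth_id, p.cohort_id, p.score)
    all_births = birth_ids if birth_ids is not None else sorted({p.birth_id for p in pairs})
    out = []
    for b in all_births:
        out.append(decided.get(b, LinkDecision(str(b), None, 0.0)))
    if conflicts:
        logger.info("assignment: %d candidate conflicts resolved greedily", conflicts)
    return out


def find_offspring(
    cohort: pd.DataFrame,
    family_id: str,
    child_dob: str,
    child_sex: str,
    mother_id: str | None = None,
) -> tuple[str | None, bool]:
    """Locate the linked mother's child in the cohort by DOB and sex.

    Searches the mother's family for members with equal date of birth and
    sex (excluding the mother's own record).  Returns ``(person_id,
    ambiguous)``: a unique hit yields the id; no hit yields ``(None,
    False)``; several hits (same-sex twins) yield ``(None, True)``.
    """
    fam = cohort[cohort["family_id"] == family_id]
    hits = fam[
        (fam["dob"].astype(str) == str(child_dob))
        & (fam["sex"].astype(str) == str(child_sex))
    ]
    if mother_id is not None:
        hits = hits[hits["person_id"].astype(str) != str(mother_id)]
    ids = sorted(hits["person_id"].astype(str))
    if len(ids) == 1:
        return ids[0], False
    if len(ids) > 1:
        return None, True
    return None, False


def link_registers(
    births: pd.DataFrame,
    cohort: pd.DataFrame,
    index: InvertedIndex,
    weights: AttributeWeights = AttributeWeights(),
    era: str = "auto",
    k: int = 1000,
    dl_floor: float = 0.5,
) -> tuple[list[ComparisonPair], list[LinkDecision]]:
    """Retrieve, filter, score and assign for every birth record.

    Returns all retained scored pairs and the one-to-one assignment
    (pre-threshold).  ``era='auto'`` routes each birth by whether it
    carries a mother DOB; ``era='age'`` forces the age route for all
    births (ignoring any recorded mother DOB); ``era='dob'`` requires it.
    """
    cohort_rows = {
        str(r["person_id"]): r for _, r in cohort.iterrows()
    }
    cohort_dobs = {pid: str(r.get("dob", "")) for pid, r in cohort_rows.items()}
    pairs: list[ComparisonPair] = []
    birth_ids: list[str] = []
    for _, b in births.iterrows():
        birth = b.to_dict()
        birth_ids.append(str(birth["birth_id"]))
        mother_dob = birth.get("mother_dob")
        has_dob = mother_dob is not None and str(mother_dob) != "" and not (
            isinstance(mother_dob, float) and pd.isna(mother_dob)
        )
        route = "dob" if (era == "dob" or (era == "auto" and has_dob)) else "age"
        probe = {
            "name": birth.get("mother_name", ""),
            "municipality": birth.get("municipality", ""),
        }
        if route == "dob":
            probe["dob"] = mother_dob
        cands = retrieve_candidates(
            index, probe, k=k, dl_floor=dl_floor, probe_id=str(birth["birth_id"])
        ).candidates
        if route == "age":
            cands = age_consistency_filter(
                list(cands), cohort_dobs, birth.get("child_dob"), birth.get("mother_age")
            )
        for cand in cands:
            crow = cohort_rows[cand.cohort_id]
            pairs.append(
                score_pair(birth, crow, weights=weights, era=route, age_passed=True)
            )
    decisions = assign_best_links(pairs, birth_ids=birth_ids)
    return pairs, decisions
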