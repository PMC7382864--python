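"""Synthetic register generator with ground-truth match labels.

Emulates the two registers the linkage consumes:

* a births register (SINASC-like): one row per live birth carrying the
  child's date of birth and sex plus the *mother's* identifying
  attributes (name, age, optionally date of birth, residence codes) and
  socio-demographic covariates;
* a cohort register (CadUnico-like baseline): one row per person with
  name, date of birth, sex, family code, residence codes and covariates.

A configurable fraction of births have their true mother present in the
cohort; those mothers' children are also planted as cohort members of the
same family, so offspring search is exercisable.  Error structure mirrors
what motivates fuzzy linkage of real registers: typographic name errors,
the pre-2011 regime in which the mother's date of birth was simply not
collected on the birth form (and partial missingness after 2011),
residence-code disagreement between registers, and covariate missingness.

A truth table (birth id -> true cohort person id, family id, planted
child id) accompanies every generated pair of registers; identical config
and seed reproduce byte-identical CSV output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _lexicon

__all__ = ["GeneratorConfig", "generate_population", "inject_name_errors", "write_population"]

DOB_ATTRIBUTE_START_YEAR = 2011  # mother DOB absent from the birth form before this

# Fixed administrative geography: 6 two-digit state codes, 5 seven-digit
# municipality codes each (first two digits = state).
_STATES = ("29", "26", "35", "33", "43", "52")
MUNICIPALITIES: tuple[tuple[str, str], ...] = tuple(
    (f"{st}{10000 + 137 * i:05d}", st) for st in _STATES for i in range(5)
)

_COVARIATES: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "race": (
        ("BROWN", "CAUCASIAN", "BLACK", "INDIGENOUS", "ASIAN"),
        (0.58, 0.31, 0.08, 0.02, 0.01),
    ),
    "zone": (("URBAN", "RURAL"), (0.75, 0.25)),
    "water_supply": (("PUBLIC_SUPPLY", "WELL", "OTHER"), (0.66, 0.25, 0.09)),
    "sewage": (
        ("PUBLIC_COLLECTION", "RUDIMENTARY_PIT", "SEPTIC_TANK", "DITCH", "OTHER"),
        (0.40, 0.26, 0.16, 0.15, 0.03),
    ),
    "garbage": (("COLLECTED", "BURNT_BURIED", "LANDFILL", "OTHER"), (0.72, 0.18, 0.08, 0.02)),
}

MISSING = "MISSING"


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic register pair.

    Defaults are the study conditions the rest of the package is exercised
    under: a 1,000-person cohort, 600 births of which 60% have their true
    mother in the cohort, a 5% per-name typo rate, 20% missing mother DOB
    after 2011 (always missing before), 5% residence-code mismatch and 5%
    covariate missingness over the 2001-2015 registration window.
    """

    n_cohort: int = 1000
    n_births: int = 600
    overlap_fraction: float = 0.6
    typo_rate: float = 0.05
    missing_mother_dob_rate: float = 0.2
    municipality_mismatch_rate: float = 0.05
    covariate_missing_rate: float = 0.05
    age_perturb_rate: float = 0.0
    year_range: tuple[int, int] = (2001, 2015)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohort", "n_births"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in (
            "overlap_fraction",
            "typo_rate",
            "missing_mother_dob_rate",
            "municipality_mismatch_rate",
            "covariate_missing_rate",
            "age_perturb_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        lo, hi = self.year_range
        if lo > hi:
            raise ValueError(f"year_range must be (lo, hi) with lo <= hi, got {self.year_range}")
        n_overlap = round(self.overlap_fraction * self.n_births)
        if n_overlap > self.n_cohort:
            raise ValueError(
                "overlap_fraction: overlapping births "
                f"({n_overlap}) exceed n_cohort ({self.n_cohort})"
            )

    @property
    def n_overlap(self) -> int:
        return round(self.overlap_fraction * self.n_births)


def inject_name_errors(name: str, rng: np.random.Generator, n_errors: int = 1) -> str:
    """Apply ``n_errors`` typographic errors to a standardized name.

    Each error is drawn uniformly from {substitution, deletion, insertion,
    adjacent transposition, token drop}.  Operations that would empty the
    name fall back to substitution, so the result is always non-empty.
    """
    if not name:
        raise ValueError("cannot corrupt an empty name")
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for _ in range(n_errors):
        op = rng.integers(0, 5)
        chars = list(name)
        if op == 4:  # token drop
            tokens = name.split(" ")
            if len(tokens) >= 2:
                tokens.pop(int(rng.integers(0, len(tokens))))
                name = " ".join(tokens)
                continue
            op = 0  # single token: fall back
        if op == 1 and len(chars) <= 1:  # deletion would empty the name
            op = 0
        if op == 0:  # substitution
            i = int(rng.integers(0, len(chars)))
            chars[i] = alphabet[int(rng.integers(0, 26))]
        elif op == 1:  # deletion
            chars.pop(int(rng.integers(0, len(chars))))
        elif op == 2:  # insertion
            i = int(rng.integers(0, len(chars) + 1))
            chars.insert(i, alphabet[int(rng.integers(0, 26))])
        else:  # adjacent transposition
            if len(chars) >= 2:
                i = int(rng.integers(0, len(chars) - 1))
                chars[i], chars[i + 1] = chars[i + 1], chars[i]
            else:
                chars[0] = alphabet[int(rng.integers(0, 26))]
        name = "".join(chars).strip()
        if not name:  # pathological all-space outcome
            name = alphabet[int(rng.integers(0, 26))]
    return name


def _random_full_name(rng: np.random.Generator, given_pool: tuple[str, ...], surname_hint: list[str] | None = None) -> str:
    """2-4 token full name: given [+connective] + 1-2 surnames."""
    given = given_pool[int(rng.integers(0, len(given_pool)))]
    if surname_hint is not None:
        surnames = surname_hint
    else:
        n_sur = 1 + int(rng.integers(0, 2))
        surnames = [
            _lexicon.SURNAMES[int(rng.integers(0, len(_lexicon.SURNAMES)))]
            for _ in range(n_sur)
        ]
    tokens = [given]
    if rng.random() < 0.35 and len(tokens) + len(surnames) < 4:
        tokens.append(_lexicon.CONNECTIVES[int(rng.integers(0, len(_lexicon.CONNECTIVES)))])
    tokens.extend(surnames)
    return " ".join(tokens)


def _random_date(rng: np.random.Generator, year_lo: int, year_hi: int) -> dt.date:
    year = int(rng.integers(year_lo, year_hi + 1))
    day = int(rng.integers(0, 365))
    return dt.date(year, 1, 1) + dt.timedelta(days=day)


def _shift_years_back(date: dt.date, years: int, extra_days: int) -> dt.date:
    try:
        anniv = date.replace(year=date.year - years)
    except ValueError:  # Feb 29 in a non-leap year
        anniv = date.replace(year=date.year - years, day=28)
    return anniv - dt.timedelta(days=extra_days)


def _completed_years(earlier: dt.date, later: dt.date) -> int:
    years = later.year - earlier.year
    if (later.month, later.day) < (earlier.month, earlier.day):
        years -= 1
    return years


def _sample_covariates(rng: np.random.Generator, missing_rate: float) -> dict[str, str]:
    out = {}
    for cov, (cats, probs) in _COVARIATES.items():
        if rng.random() < missing_rate:
            out[cov] = MISSING
        else:
            out[cov] = cats[int(rng.choice(len(cats), p=np.asarray(probs) / sum(probs)))]
    return out


def generate_population(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (births, cohort, truth) DataFrames for one configuration.

    Exactly ``round(overlap_fraction * n_births)`` births have a true
    mother in the cohort (distinct mothers, sampled without replacement);
    their children are planted as cohort members of the mother's family.
    All names are emitted in standardized form.
    """
    rng = np.random.default_rng(config.seed)
    year_lo, year_hi = config.year_range
    n_overlap = config.n_overlap

    # --- cohort mothers ---------------------------------------------------
    mothers = []
    for i in range(config.n_cohort):
        muni, state = MUNICIPALITIES[int(rng.integers(0, len(MUNICIPALITIES)))]
        mothers.append(
            {
                "person_id": f"P{i + 1:06d}",
                "family_id": f"F{i + 1:06d}",
                "name": _random_full_name(rng, _lexicon.GIVEN_NAMES),
                "dob": None,  # fixed below
                "sex": "F",
                "municipality": muni,
                "state": state,
                **_sample_covariates(rng, config.covariate_missing_rate),
            }
        )

    overlap_idx = rng.choice(config.n_cohort, size=n_overlap, replace=False)
    overlap_set = {int(i) for i in overlap_idx}

    births: list[dict] = []
    truth: list[dict] = []
    children: list[dict] = []
    next_person = config.n_cohort + 1

    def _make_birth(mother: dict, child_dob: dt.date) -> dict:
        """Birth row copying mother attributes, then corrupting per rates."""
        name = mother["name"]
        if rng.random() < config.typo_rate:
            name = inject_name_errors(name, rng)
        muni, state = mother["municipality"], mother["state"]
        if rng.random() < config.municipality_mismatch_rate:
            others = [m for m in MUNICIPALITIES if m[0] != muni]
            muni, state = others[int(rng.integers(0, len(others)))]
        age = _completed_years(mother["dob"], child_dob)
        if config.age_perturb_rate and rng.random() < config.age_perturb_rate:
            age += int(rng.integers(0, 2)) * 2 - 1  # +-1 year
        mother_dob = ""
        if child_dob.year >= DOB_ATTRIBUTE_START_YEAR:
            if rng.random() >= config.missing_mother_dob_rate:
                mother_dob = mother["dob"].isoformat()
        sex = "M" if rng.random() < 0.5 else "F"
        return {
            "birth_year": child_dob.year,
            "child_dob": child_dob.isoformat(),
            "child_sex": sex,
            "mother_name": name,
            "mother_age": age,
            "mother_dob": mother_dob,
            "municipality": muni,
            "state": state,
            "race": mother["race"],
            "zone": mother["zone"],
            "water_supply": mother["water_supply"],
            "sewage": mother["sewage"],
            "garbage": mother["garbage"],
        }

    # --- overlapping births (true mother in cohort) -----------------------
    for i in range(config.n_births):
        child_dob = _random_date(rng, year_lo, year_hi)
        if i < n_overlap:
            mother = mothers[int(overlap_idx[i])]
        else:
            # mother exists only outside the cohort
            muni, state = MUNICIPALITIES[int(rng.integers(0, len(MUNICIPALITIES)))]
            mother = {
                "name": _random_full_name(rng, _lexicon.GIVEN_NAMES),
                "municipality": muni,
                "state": state,
                **_sample_covariates(rng, config.covariate_missing_rate),
            }
        # mother's DOB tied to this child: completed age 15-42 at delivery
        age_years = int(rng.integers(15, 43))
        extra = int(rng.integers(0, 365))
        mother = dict(mother)
        mother["dob"] = _shift_years_back(child_dob, age_years, extra)
        if i < n_overlap:
            mothers[int(overlap_idx[i])]["dob"] = mother["dob"]

        row = _make_birth(mother, child_dob)
        births.append(row)
        if i < n_overlap:
            m = mothers[int(overlap_idx[i])]
            child_surnames = m["name"].split(" ")[1:] or ["SILVA"]
            child_id = f"P{next_person:06d}"
            next_person += 1
            children.append(
                {
                    "person_id": child_id,
                    "family_id": m["family_id"],
                    "name": _random_full_name(
                        rng, _lexicon.CHILD_NAMES, surname_hint=child_surnames
                    ),
                    "dob": child_dob,
                    "sex": row["child_sex"],
                    "municipality": m["municipality"],
                    "state": m["state"],
                    "race": m["race"],
                    "zone": m["zone"],
                    "water_supply": m["water_supply"],
                    "sewage": m["sewage"],
                    "garbage": m["garbage"],
                }
            )
            truth.append(
                {
                    "true_person_id": m["person_id"],
                    "true_family_id": m["family_id"],
                    "true_child_person_id": child_id,
                }
            )
        else:
            truth.append(
                {"true_person_id": "", "true_family_id": "", "true_child_person_id": ""}
            )

    # cohort mothers never linked to a birth still need a DOB
    for i, m in enumerate(mothers):
        if m["dob"] is None:
            m["dob"] = _random_date(rng, year_lo - 45, year_lo - 16)

    # shuffle births so overlap status is not positional, then assign ids
    order = rng.permutation(config.n_births)
    births = [births[int(i)] for i in order]
    truth = [truth[int(i)] for i in order]
    for i, (b, t) in enumerate(zip(births, truth)):
        b_id = f"B{i + 1:06d}"
        b["birth_id"] = b_id
        t["birth_id"] = b_id

    births_df = pd.DataFrame(births)[
        [
            "birth_id", "birth_year", "child_dob", "child_sex", "mother_name",
            "mother_age", "mother_dob", "municipality", "state",
            "race", "zone", "water_supply", "sewage", "garbage",
        ]
    ]
    cohort_rows = mothers + children
    for r in cohort_rows:
        r["dob"] = r["dob"].isoformat()
    cohort_df = pd.DataFrame(cohort_rows)[
        [
            "person_id", "family_id", "name", "dob", "sex",
            "municipality", "state",
            "race", "zone", "water_supply", "sewage", "garbage",
        ]
    ]
    truth_df = pd.DataFrame(truth)[
        ["birth_id", "true_person_id", "true_family_id", "true_child_person_id"]
    ]
    return births_df, cohort_df, truth_df


def write_population(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write births.csv, cohort.csv and truth.csv to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    births, cohort, truth = generate_population(config)
    paths = {
        "births": outdir / "births.csv",
        "cohort": outdir / "cohort.csv",
        "truth": outdir / "truth.csv",
    }
    births.to_csv(paths["births"], index=False)
    cohort.to_csv(paths["cohort"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
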