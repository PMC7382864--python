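"""Linkage-quality reports: yearly rates, truth-based accuracy, bias tables.

Three outputs mirror how large administrative linkages are audited:

* a **yearly linkage-rate table** (per birth year: submitted, linked,
  linked %), with a Total row — percentages rounded half-up to two
  decimals;
* **truth-based accuracy metrics** on synthetic data, at the mother-baby
  *pair* level: sensitivity, specificity, PPV, NPV and the two linkage
  error rates (missed-match rate = 1 - sensitivity, false-match rate =
  1 - PPV);
* a **bias report** comparing covariate distributions (with explicit
  Missing rows) between linked and non-linked births, since linkage
  error that falls unevenly across social groups biases downstream
  epidemiology even when overall accuracy is high.

An ablation report runs the full pipeline twice on identical inputs —
once using the mother-DOB attribute, once with the age-consistency route
only — and reports AUC/threshold/sensitivity/specificity side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .linkage import LinkDecision

__all__ = [
    "round_half_up",
    "linkage_rate_by_year",
    "linkage_rate_from_counts",
    "truth_metrics",
    "compare_characteristics",
    "ablation_report",
]


def round_half_up(value: float | Decimal, digits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as printed report tables use."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numer: int, denom: int) -> float:
    if denom == 0:
        return 0.0
    return float(
        (Decimal(100) * Decimal(numer) / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def linkage_rate_from_counts(counts: dict[int | str, tuple[int, int]]) -> pd.DataFrame:
    """Rate table from precomputed (submitted, linked) counts per year.

    Returns columns ``year, total, linked, linked_pct`` plus a Total row
    summing the years; linked_pct = 100 * linked / total rounded half-up
    to 2 decimals.
    """
    rows = []
    for year in sorted(counts, key=str):
        total, linked = counts[year]
        rows.append(
            {"year": str(year), "total": total, "linked": linked,
             "linked_pct": _pct(linked, total)}
        )
    grand_total = sum(t for t, _ in counts.values())
    grand_linked = sum(l for _, l in counts.values())
    rows.append(
        {"year": "Total", "total": grand_total, "linked": grand_linked,
         "linked_pct": _pct(grand_linked, grand_total)}
    )
    return pd.DataFrame(rows)


def linkage_rate_by_year(
    decisions: list[LinkDecision],
    birth_years: dict[str, int] | pd.Series,
) -> pd.DataFrame:
    """Yearly submitted/linked counts and percentages from final decisions.

    ``birth_years`` maps every birth id to its registration year; a
    missing year is an error rather than a silently dropped record.
    """
    years = dict(birth_years) if not isinstance(birth_years, dict) else birth_years
    counts: dict[int, list[int]] = {}
    for d in decisions:
        if d.birth_id not in years or pd.isna(years[d.birth_id]):
            raise ValueError(f"birth {d.birth_id} has no birth year")
        y = int(years[d.birth_id])
        c = counts.setdefault(y, [0, 0])
        c[0] += 1
        if d.classification == "link":
            c[1] += 1
    return linkage_rate_from_counts({y: (t, l) for y, (t, l) in counts.items()})


@dataclass(frozen=True)
class TruthMetrics:
    true_positives: int
    false_positives: int
    false_negatives: int
    true_negatives: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    missed_match_rate: float
    false_match_rate: float


def truth_metrics(
    decisions: list[LinkDecision],
    truth: pd.DataFrame,
) -> TruthMetrics:
    """Pair-level confusion metrics against the ground-truth table.

    A link is a true positive iff its cohort id equals the truth id; a
    link to any other record is a false positive (and, when the birth had
    a true mother, also a missed true pair).  Sensitivity is over births
    with a true mother; specificity over births without one.  Every birth
    must appear in the truth table.
    """
    lut: dict[str, str] = {}
    for b, t in zip(truth["birth_id"].astype(str), truth["true_person_id"]):
        lut[b] = "" if pd.isna(t) else str(t)
    tp = fp = fn = tn = 0
    for d in decisions:
        if d.birth_id not in lut:
            raise ValueError(f"birth {d.birth_id} absent from truth table")
        true_id = lut[d.birth_id]
        linked_id = d.cohort_id if d.classification == "link" else None
        if linked_id is not None:
            if true_id and linked_id == true_id:
                tp += 1
            else:
                fp += 1
                if true_id:
                    fn += 1  # true pair missed by linking elsewhere
        else:
            if true_id:
                fn += 1
            else:
                tn += 1
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    ppv = tp / (tp + fp) if tp + fp else 1.0
    npv = tn / (tn + fn) if tn + fn else 1.0
    return TruthMetrics(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        true_negatives=tn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        missed_match_rate=1.0 - sens,
        false_match_rate=1.0 - ppv,
    )


def compare_characteristics(
    decisions: list[LinkDecision],
    births: pd.DataFrame,
    covariates: list[str],
    years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Covariate distributions among linked vs non-linked births.

    Long-format table: covariate, category (Missing kept explicit, never
    dropped), counts and column percentages within each group.  ``years``
    optionally restricts to a contrast pair (e.g. an early vs a late
    registration year); percentages within each covariate and group sum
    to 100 up to rounding.
    """
    available = [c for c in births.columns]
    for cov in covariates:
        if cov not in births.columns:
            raise ValueError(f"unknown covariate {cov!r}; available: {available}")
    linked_ids = {d.birth_id for d in decisions if d.classification == "link"}
    df = births.copy()
    df["birth_id"] = df["birth_id"].astype(str)
    if years is not None:
        df = df[df["birth_year"].astype(int).isin([int(y) for y in years])]
    df["group"] = [
        "linked" if b in linked_ids else "non_linked" for b in df["birth_id"]
    ]
    rows = []
    for cov in covariates:
        vals = df[cov].fillna("MISSING").replace("", "MISSING").astype(str)
        for group in ("linked", "non_linked"):
            sub = vals[df["group"] == group]
            n_group = len(sub)
            for cat, n in sub.value_counts().sort_index().items():
                rows.append(
                    {
                        "covariate": cov,
                        "category": cat,
                        "group": group,
                        "n": int(n),
                        "pct": _pct(int(n), n_group),
                    }
                )
    return pd.DataFrame(rows)


def ablation_report(
    births: pd.DataFrame,
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    sample_size: int = 2000,
    seed: int = 0,
    k: int = 1000,
    dl_floor: float = 0.5,
) -> pd.DataFrame:
    """Paired pipeline runs: mother-DOB route vs age-only route.

    Both routes see identical inputs; for the age route the mother-DOB
    column is withheld.  Returns one row per metric (auc, threshold,
    sensitivity, specificity, linked_pct) with a column per route.
    """
    from .pipeline import run_linkage_stage  # local import: avoids cycle

    # identical inputs for both routes: births that actually carry a mother DOB
    has_dob = births["mother_dob"].fillna("").astype(str) != ""
    eligible = births[has_dob].reset_index(drop=True)
    if eligible.empty:
        raise ValueError("ablation needs births with a recorded mother DOB")
    results = {}
    for route, frame in (("dob", eligible), ("age", eligible.assign(mother_dob=""))):
        res = run_linkage_stage(
            frame, cohort, truth,
            era="dob" if route == "dob" else "age",
            sample_size=sample_size, seed=seed, k=k, dl_floor=dl_floor,
        )
        results[route] = {
            "auc": res.model.auc,
            "threshold": res.model.threshold,
            "sensitivity": res.metrics.sensitivity,
            "specificity": res.metrics.specificity,
            "linked_pct": res.linked_pct,
        }
    metrics = ["auc", "threshold", "sensitivity", "specificity", "linked_pct"]
    return pd.DataFrame(
        {
            "metric": metrics,
            "with_mother_dob": [results["dob"][m] for m in metrics],
            "age_only": [results["age"][m] for m in metrics],
        }
    )
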