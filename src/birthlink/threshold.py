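"""Link/non-link threshold selection from a stratified labeled sample.

Manual review of every candidate pair is infeasible at register scale, so
a fixed-size sample (default 2000 pairs) is drawn from the assigned
potential links, stratified by score — low (< 0.90), intermediate
([0.90, 0.95]) and high (> 0.95) — with allocation proportional to
stratum size and a floor of 10 pairs per non-empty stratum.  Each sampled
pair is labeled likely-true / likely-false (from a review file, or from
the truth table on synthetic data); a ROC curve over the scores gives the
AUC, and the operating threshold maximizes Youden's J = sensitivity +
specificity - 1, ties resolved toward the higher threshold (favoring
specificity).  Pairs scoring >= the threshold are classified as links.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .linkage import LinkDecision

__all__ = [
    "StratifiedSample",
    "ThresholdModel",
    "stratify_sample",
    "attach_labels",
    "build_roc",
    "choose_threshold",
    "classify_links",
]

STRATA = ("low", "intermediate", "high")


@dataclass
class StratifiedSample:
    """Sampled pairs with stratum tags; labels attach separately."""

    pairs: pd.DataFrame  # birth_id, cohort_id, score, stratum [, label]
    bounds: tuple[float, float] = (0.90, 0.95)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ThresholdModel:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    degenerate: bool = False


def _stratum(score: float, bounds: tuple[float, float]) -> str:
    lo, hi = bounds
    if score < lo:
        return "low"
    if score <= hi:
        return "intermediate"
    return "high"


def stratify_sample(
    decisions: list[LinkDecision] | pd.DataFrame,
    sample_size: int = 2000,
    bounds: tuple[float, float] = (0.90, 0.95),
    seed: int = 0,
    min_per_stratum: int = 10,
) -> StratifiedSample:
    """Draw a score-stratified sample of assigned pairs without replacement.

    Allocation is proportional to stratum sizes with at least
    ``min_per_stratum`` from each non-empty stratum (capped at the
    stratum's size); deterministic under ``seed``.  Only decisions with a
    non-null cohort id (actual potential links) are sampled.
    """
    if isinstance(decisions, pd.DataFrame):
        df = decisions.copy()
    else:
        df = pd.DataFrame(
            [
                {"birth_id": d.birth_id, "cohort_id": d.cohort_id, "score": d.score}
                for d in decisions
            ]
        )
    df = df[df["cohort_id"].notna() & (df["cohort_id"].astype(str) != "")]
    if df.empty:
        raise ValueError("no assigned pairs to sample from")
    df = df.sort_values(["birth_id"]).reset_index(drop=True)
    df["stratum"] = [_stratum(s, bounds) for s in df["score"]]

    sizes = {s: int((df["stratum"] == s).sum()) for s in STRATA}
    nonempty = [s for s in STRATA if sizes[s] > 0]
    floor_total = sum(min(min_per_stratum, sizes[s]) for s in nonempty)
    if sample_size < floor_total:
        raise ValueError(
            f"sample_size {sample_size} below the per-stratum floor total {floor_total}"
        )
    total = len(df)
    n_take = min(sample_size, total)
    # proportional allocation, then enforce floors and repair the total
    alloc = {
        s: max(min(min_per_stratum, sizes[s]), round(n_take * sizes[s] / total))
        for s in nonempty
    }
    alloc = {s: min(alloc[s], sizes[s]) for s in nonempty}
    # adjust to hit n_take exactly where possible, trimming/padding the
    # largest stratum with slack
    drift = sum(alloc.values()) - n_take
    for s in sorted(nonempty, key=lambda s: -sizes[s]):
        if drift == 0:
            break
        if drift > 0:
            reducible = alloc[s] - min(min_per_stratum, sizes[s])
            take = min(drift, reducible)
            alloc[s] -= take
            drift -= take
        else:
            headroom = sizes[s] - alloc[s]
            add = min(-drift, headroom)
            alloc[s] += add
            drift += add

    rng = np.random.default_rng(seed)
    parts = []
    for s in nonempty:
        stratum_df = df[df["stratum"] == s]
        idx = rng.choice(len(stratum_df), size=alloc[s], replace=False)
        parts.append(stratum_df.iloc[np.sort(idx)])
    sample = pd.concat(parts, ignore_index=True)
    return StratifiedSample(pairs=sample, bounds=bounds)


def attach_labels(
    sample: StratifiedSample,
    truth: pd.DataFrame | None = None,
    review: pd.DataFrame | None = None,
) -> StratifiedSample:
    """Label each sampled pair likely-true (1) / likely-false (0).

    Exactly one source must be given: ``truth`` (columns ``birth_id``,
    ``true_person_id``; label = assigned id equals true id) or ``review``
    (columns ``birth_id``, ``cohort_id``, ``label`` in {0, 1}).  Every
    sampled pair must be covered.
    """
    if (truth is None) == (review is None):
        raise ValueError("provide exactly one of truth= or review=")
    pairs = sample.pairs.copy()
    if truth is not None:
        lut = dict(
            zip(truth["birth_id"].astype(str), truth["true_person_id"].astype(str))
        )
        missing = [b for b in pairs["birth_id"].astype(str) if b not in lut]
        if missing:
            raise ValueError(f"births missing from truth table: {missing[:5]}...")
        pairs["label"] = [
            int(lut[str(b)] == str(c))
            for b, c in zip(pairs["birth_id"], pairs["cohort_id"])
        ]
    else:
        lut = {
            (str(b), str(c)): int(v)
            for b, c, v in zip(review["birth_id"], review["cohort_id"], review["label"])
        }
        missing_pairs = [
            (str(b), str(c))
            for b, c in zip(pairs["birth_id"], pairs["cohort_id"])
            if (str(b), str(c)) not in lut
        ]
        if missing_pairs:
            raise ValueError(f"unlabeled sampled pairs: {missing_pairs[:5]}...")
        pairs["label"] = [
            lut[(str(b), str(c))] for b, c in zip(pairs["birth_id"], pairs["cohort_id"])
        ]
    return StratifiedSample(pairs=pairs, bounds=sample.bounds)


def build_roc(sample: StratifiedSample) -> ThresholdModel:
    """ROC over all distinct score cut points; AUC by trapezoidal rule.

    Requires both label classes in the sample (AUC is undefined
    otherwise).
    """
    if "label" not in sample.pairs.columns:
        raise ValueError("sample is unlabeled; call attach_labels first")
    labels = sample.pairs["label"].to_numpy()
    scores = sample.pairs["score"].to_numpy(dtype=float)
    if labels.min() == labels.max():
        raise ValueError("single-class sample: AUC undefined")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ThresholdModel(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def choose_threshold(model: ThresholdModel) -> ThresholdModel:
    """Operating point maximizing Youden's J; ties -> higher threshold.

    The chosen cut is clamped to [0, 1] (ROC machinery emits a sentinel
    above the top score for the all-negative point).  Sensitivity and
    specificity at the cut are recorded on the model.
    """
    j = model.tpr - model.fpr
    best = np.flatnonzero(j == j.max())
    # thresholds from roc_curve are decreasing; the smallest index among
    # maxima is the highest threshold
    pick = int(best.min())
    raw = float(model.thresholds[pick])
    model.threshold = min(max(raw, 0.0), 1.0)
    model.sensitivity = float(model.tpr[pick])
    model.specificity = 1.0 - float(model.fpr[pick])
    return model


def classify_links(
    decisions: list[LinkDecision],
    threshold: float,
) -> list[LinkDecision]:
    """Final classification: assigned pair with score >= threshold -> link.

    Births without an assigned candidate stay non-links.  The threshold
    is clamped to [0, 1].
    """
    t = min(max(threshold, 0.0), 1.0)
    out = []
    for d in decisions:
        is_link = d.cohort_id is not None and d.score >= t
        out.append(
            LinkDecision(d.birth_id, d.cohort_id, d.score, "link" if is_link else "non_link")
        )
    return out
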