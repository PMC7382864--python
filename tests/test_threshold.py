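"""Stratified sampling, ROC/AUC and Youden threshold tests."""

import numpy as np
import pandas as pd
import pytest

from _oracles import mann_whitney_auc
from birthlink.linkage import LinkDecision
from birthlink.threshold import (
    StratifiedSample,
    attach_labels,
    build_roc,
    choose_threshold,
    classify_links,
    stratify_sample,
)


def _decisions(scores, prefix="B"):
    return [
        LinkDecision(f"{prefix}{i:04d}", f"P{i:04d}", s) for i, s in enumerate(scores)
    ]


def test_stratified_allocation_proportional_with_floor():
    rng = np.random.default_rng(0)
    scores = np.concatenate(
        [rng.uniform(0, 0.89, 800), rng.uniform(0.90, 0.95, 100), rng.uniform(0.951, 1.0, 100)]
    )
    sample = stratify_sample(_decisions(scores), sample_size=100, seed=1)
    counts = sample.pairs["stratum"].value_counts()
    assert len(sample) == 100
    assert abs(counts["low"] - 80) <= 2
    assert counts["intermediate"] >= 10 and counts["high"] >= 10
    # sampling without replacement
    assert sample.pairs["birth_id"].is_unique


def test_stratified_sampling_deterministic_and_single_stratum():
    scores = list(np.linspace(0.96, 1.0, 50))
    s1 = stratify_sample(_decisions(scores), sample_size=20, seed=3)
    s2 = stratify_sample(_decisions(scores), sample_size=20, seed=3)
    pd.testing.assert_frame_equal(s1.pairs, s2.pairs)
    assert (s1.pairs["stratum"] == "high").all()  # all scores > 0.95


def test_stratified_boundaries_closed_intermediate():
    scores = [0.899999, 0.90, 0.95, 0.950001]
    s = stratify_sample(_decisions(scores), sample_size=4, min_per_stratum=1, seed=0)
    strata = dict(zip(s.pairs["score"], s.pairs["stratum"]))
    assert strata[0.899999] == "low"
    assert strata[0.90] == "intermediate"
    assert strata[0.95] == "intermediate"
    assert strata[0.950001] == "high"


def test_stratified_sample_size_floor_error():
    scores = [0.5] * 50 + [0.92] * 50 + [0.99] * 50
    with pytest.raises(ValueError):
        stratify_sample(_decisions(scores), sample_size=5, seed=0)


def test_attach_labels_from_truth_and_review():
    scores = [0.99, 0.5]
    sample = stratify_sample(_decisions(scores), sample_size=2, min_per_stratum=1, seed=0)
    truth = pd.DataFrame(
        {"birth_id": ["B0000", "B0001"], "true_person_id": ["P0000", "PXXXX"]}
    )
    labeled = attach_labels(sample, truth=truth)
    lut = dict(zip(labeled.pairs["birth_id"], labeled.pairs["label"]))
    assert lut == {"B0000": 1, "B0001": 0}
    # review file covering all pairs
    review = pd.DataFrame(
        {"birth_id": ["B0000", "B0001"], "cohort_id": ["P0000", "P0001"], "label": [1, 0]}
    )
    labeled2 = attach_labels(sample, review=review)
    assert list(labeled2.pairs["label"]) == list(labeled.pairs["label"])
    # partial coverage is an error
    with pytest.raises(ValueError):
        attach_labels(sample, review=review.iloc[:1])
    with pytest.raises(ValueError):
        attach_labels(sample)


def _labeled(scores, labels):
    df = pd.DataFrame(
        {
            "birth_id": [f"B{i}" for i in range(len(scores))],
            "cohort_id": [f"P{i}" for i in range(len(scores))],
            "score": scores,
            "stratum": "high",
            "label": labels,
        }
    )
    return StratifiedSample(pairs=df)


def test_roc_auc_perfect_separation():
    model = build_roc(_labeled([0.9, 0.95, 0.3, 0.2], [1, 1, 0, 0]))
    assert model.auc == pytest.approx(1.0)


def test_roc_auc_equals_mann_whitney_enumeration():
    rng = np.random.default_rng(5)
    scores = np.round(rng.uniform(0, 1, 120), 2)  # rounding forces ties
    labels = (scores + rng.normal(0, 0.3, 120) > 0.5).astype(int)
    model = build_roc(_labeled(list(scores), list(labels)))
    assert model.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)


def test_roc_auc_near_half_for_uninformative_scores():
    rng = np.random.default_rng(11)
    scores = rng.uniform(0, 1, 2000)
    labels = rng.integers(0, 2, 2000)
    model = build_roc(_labeled(list(scores), list(labels)))
    assert model.auc == pytest.approx(0.5, abs=0.05)


def test_roc_single_class_is_an_error():
    with pytest.raises(ValueError):
        build_roc(_labeled([0.9, 0.8], [1, 1]))
    with pytest.raises(ValueError):
        build_roc(_labeled([0.9], [1]))  # unlabeled frame error path
    with pytest.raises(ValueError):
        build_roc(StratifiedSample(pairs=pd.DataFrame({"score": [0.5]})))


def test_roc_monotone_and_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores = rng.uniform(0, 1, 300)
    labels = (scores + rng.normal(0, 0.2, 300) > 0.5).astype(int)
    m1 = build_roc(_labeled(list(scores), list(labels)))
    m2 = build_roc(_labeled(list(scores**2), list(labels)))
    assert m1.auc == pytest.approx(m2.auc, abs=1e-12)
    assert np.all(np.diff(m1.tpr) >= 0) and np.all(np.diff(m1.fpr) >= 0)


def test_youden_threshold_in_interclass_gap():
    model = choose_threshold(
        build_roc(_labeled([0.97, 0.96, 0.95, 0.4, 0.3], [1, 1, 1, 0, 0]))
    )
    # J = 1 plateau: tie rule picks the highest cut, i.e. the lowest true score
    assert model.threshold == pytest.approx(0.95)
    assert model.sensitivity == 1.0 and model.specificity == 1.0


def test_youden_matches_confusion_matrix_arithmetic():
    rng = np.random.default_rng(9)
    scores = np.concatenate([rng.normal(0.9, 0.05, 80), rng.normal(0.6, 0.1, 80)])
    labels = np.array([1] * 80 + [0] * 80)
    model = choose_threshold(build_roc(_labeled(list(scores), list(labels))))
    # brute-force J over every distinct cut
    best_j = -1.0
    for cut in np.unique(scores):
        pred = scores >= cut
        tp = int(((pred) & (labels == 1)).sum())
        fn = int((~pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        tn = int((~pred & (labels == 0)).sum())
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        best_j = max(best_j, j)
    assert model.sensitivity + model.specificity - 1 == pytest.approx(best_j, abs=1e-12)


def test_classify_links_threshold_semantics():
    decisions = _decisions([0.95, 0.93]) + [LinkDecision("BX", None, 0.0)]
    out = classify_links(decisions, 0.94)
    cls = {d.birth_id: d.classification for d in out}
    assert cls["B0000"] == "link" and cls["B0001"] == "non_link"
    assert cls["BX"] == "non_link"  # unassigned birth stays in the output
    assert all(d.classification == "link" for d in classify_links(decisions[:2], 0.0))
    # threshold above 1 clamps; only perfect scores would link at 1.0
    assert all(
        d.classification == "non_link" for d in classify_links(decisions[:2], 1.5)
    )
    perfect = _decisions([1.0])
    assert classify_links(perfect, 1.5)[0].classification == "link"
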