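"""Inverted-index construction and tiered-query tests."""

import pandas as pd
import pytest

from birthlink.index_search import (
    build_index,
    query_exact,
    query_fuzzy,
    query_semi_fuzzy,
    retrieve_candidates,
)
from birthlink.similarity import normalized_dl_similarity


def _cohort(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "name", "municipality", "state", "dob"]
    )


@pytest.fixture
def tiny_index():
    cohort = _cohort(
        [
            ("P1", "MARIA DA SILVA", "2910000", "29", "1980-01-01"),
            ("P2", "MARIA DE SILVA", "2910000", "29", "1985-05-05"),
            ("P3", "ANA SANTOS", "2910137", "29", "1980-01-01"),
            ("P4", "MARIA DA SILVA", "2910137", "29", "1990-09-09"),
            ("P5", "JOSE COSTA", "3510000", "35", ""),
        ]
    )
    return cohort, build_index(cohort)


def test_postings_counts_and_missing_fields(tiny_index):
    _, idx = tiny_index
    assert idx.posting("name", "MARIA") == ["P1", "P2", "P4"]
    assert idx.posting("name_exact", "MARIA DA SILVA") == ["P1", "P4"]
    # P5's missing DOB keeps it out of DOB postings only
    assert all("P5" not in ids for (f, _), ids in idx.postings.items() if f == "dob")
    assert "P5" in idx.posting("municipality", "3510000")


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        build_index(_cohort([("P1", "A B", "1", "1", ""), ("P1", "C D", "1", "1", "")]))


def test_empty_cohort_yields_empty_queries():
    idx = build_index(_cohort([]))
    probe = {"name": "MARIA", "municipality": "1"}
    assert query_exact(idx, probe) == []
    assert retrieve_candidates(idx, probe).candidates == ()


def test_exact_tier(tiny_index):
    _, idx = tiny_index
    probe = {"name": "MARIA DA SILVA", "municipality": "2910000", "dob": "1980-01-01"}
    assert query_exact(idx, probe) == ["P1"]
    # two records identical on all supplied probe attributes -> both returned
    assert query_exact(idx, {"name": "MARIA DA SILVA"}) == ["P1", "P4"]
    assert query_exact(idx, {"name": "MARIA DA SILVA", "municipality": "2910137"}) == ["P4"]
    # no shared municipality anywhere -> empty
    assert query_exact(idx, {"name": "MARIA DA SILVA", "municipality": "9999999"}) == []


def test_semi_fuzzy_is_exactly_one_attribute_off(tiny_index):
    cohort, idx = tiny_index
    probe = {"name": "MARIA DA SILVA", "municipality": "2910000", "dob": "1990-09-09"}
    semi = query_semi_fuzzy(idx, probe)
    # P4 agrees on name+dob (different municipality); P1 agrees on name+municipality
    assert "P4" in semi and "P1" in semi
    # P3 agrees on nothing but dob-adjacent attributes -> excluded
    assert "P3" not in semi
    # exact-tier results never reappear
    assert set(query_exact(idx, probe)).isdisjoint(semi)
    # single supplied attribute -> empty by construction
    assert query_semi_fuzzy(idx, {"name": "MARIA DA SILVA"}) == []


def test_semi_fuzzy_brute_force_soundness(tiny_index):
    """Every semi-fuzzy candidate disagrees on exactly one supplied attribute."""
    cohort, idx = tiny_index
    probe = {"name": "MARIA DA SILVA", "municipality": "2910000", "dob": "1980-01-01"}
    rows = cohort.set_index("person_id")
    for pid in query_semi_fuzzy(idx, probe):
        r = rows.loc[pid]
        agreements = [
            r["name"] == probe["name"],
            r["municipality"] == probe["municipality"],
            str(r["dob"]) == probe["dob"],
        ]
        assert sum(agreements) == 2


def test_fuzzy_tier_filter_and_ranking(tiny_index):
    _, idx = tiny_index
    probe = {"name": "MARIA DA SILVA", "municipality": "0"}
    fuzzy = query_fuzzy(idx, probe, dl_floor=0.5)
    ids = [pid for pid, _ in fuzzy]
    # DL similarity of P2's name = 1 - 1/14 > 0.5 -> retained
    assert "P2" in ids
    # zero shared tokens -> never retrieved
    assert "P5" not in ids and "P3" not in ids
    # ranking: more shared tokens first, then DL similarity, then id
    assert ids[:2] == ["P1", "P4"]
    # dl_floor=1.0 keeps only identical names
    strict = [pid for pid, _ in query_fuzzy(idx, probe, dl_floor=0.99)]
    assert strict == ["P1", "P4"]
    for pid, sim in fuzzy:
        assert sim == pytest.approx(
            normalized_dl_similarity(probe["name"], idx.names[pid])
        )
        assert sim > 0.5


def test_cascade_dedup_tier_order_and_truncation(tiny_index):
    _, idx = tiny_index
    probe = {"name": "MARIA DA SILVA", "municipality": "2910000", "dob": "1980-01-01"}
    cs = retrieve_candidates(idx, probe, k=1000)
    ids = cs.ids()
    assert ids[0] == "P1" and cs.candidates[0].tier == "exact"
    assert len(ids) == len(set(ids))  # no duplicates across tiers
    tiers = [c.tier for c in cs.candidates]
    assert tiers == sorted(tiers, key=["exact", "semi_fuzzy", "fuzzy"].index)
    # k=1 keeps only the single best candidate
    assert retrieve_candidates(idx, probe, k=1).ids() == ["P1"]
    with pytest.raises(ValueError):
        retrieve_candidates(idx, probe, k=0)


def test_cascade_with_floor_zero_contains_every_token_sharer(tiny_index):
    cohort, idx = tiny_index
    probe = {"name": "MARIA DA SILVA", "municipality": "0"}
    got = set(retrieve_candidates(idx, probe, k=1000, dl_floor=0.0).ids())
    expected = {
        pid
        for pid, name in zip(cohort["person_id"], cohort["name"])
        if set(name.split()) & set(probe["name"].split())
        and normalized_dl_similarity(probe["name"], name) > 0
    }
    assert got == expected


def test_blocking_recall_small(small_population):
    """True mother retrieved for every overlapping birth at 5% typo rate."""
    from birthlink.pipeline import standardize_registers

    _, births, cohort, truth = small_population
    births, cohort = standardize_registers(births, cohort)
    idx = build_index(cohort)
    lut = dict(zip(truth["birth_id"], truth["true_person_id"]))
    hits = total = 0
    for _, row in births.iterrows():
        tid = lut[row["birth_id"]]
        if not tid:
            continue
        total += 1
        probe = {"name": row["mother_name"], "municipality": row["municipality"]}
        if row["mother_dob"]:
            probe["dob"] = row["mother_dob"]
        if tid in retrieve_candidates(idx, probe).ids():
            hits += 1
    assert total > 0
    assert hits / total >= 0.99
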