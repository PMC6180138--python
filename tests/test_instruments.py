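"""Binarization rules, item filtering, scale totals, and paired t-tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from empathnet import (
    BinarizationError,
    binarize_item,
    binarize_table,
    filter_items,
    load_instrument_specs,
    paired_t_test,
    scale_totals,
)
from empathnet.instruments import paired_totals_tests
from empathnet.synth import STUDY_N_PARTICIPANTS, STUDY_PRESENCE_COUNTS

from conftest import likert_table


@pytest.mark.parametrize(
    "instrument,item,score,expected",
    [
        # DASS-21: absence (0) vs presence (1-3)
        ("DASS21", 11, 0, 0),
        ("DASS21", 11, 1, 1),
        ("DASS21", 11, 3, 1),
        # EQ-short: no empathy (0-1) vs empathic (2-3)
        ("EQ_SHORT", 7, 1, 0),
        ("EQ_SHORT", 7, 2, 1),
        # JSE-S ordinary: no empathy 1-3, empathic 4-7
        ("JSE_S", 2, 3, 0),
        ("JSE_S", 2, 4, 1),
        ("JSE_S", 2, 7, 1),
        # JSE-S reversed (item 6): empathic 1-3, no empathy 4-7
        ("JSE_S", 6, 2, 1),
        ("JSE_S", 6, 3, 1),
        ("JSE_S", 6, 4, 0),
        ("JSE_S", 6, 7, 0),
        # EES ordinary (item 13): expressive 3-5
        ("EES", 13, 2, 0),
        ("EES", 13, 3, 1),
        # EES reversed (item 12): expressive 1-2
        ("EES", 12, 2, 1),
        ("EES", 12, 3, 0),
        ("EES", 12, 5, 0),
    ],
)
def test_binarize_item_instrument_rules(specs, instrument, item, score, expected):
    assert binarize_item(score, specs[instrument], item) == expected


def test_reversed_items_are_exact_complements(specs):
    """For every reversed item, the 0/1 map is the complement of an ordinary
    item's map at every score of the scale."""
    for spec in specs.values():
        ordinary = next(i for i in range(1, spec.n_items + 1) if not spec.is_reversed(i))
        for rev in spec.reversed_items:
            for s in range(spec.scale_min, spec.scale_max + 1):
                assert binarize_item(s, spec, rev) == 1 - binarize_item(s, spec, ordinary)
        # preimages partition the scale
        for item in range(1, spec.n_items + 1):
            pres = set(spec.presence_scores(item))
            full = set(range(spec.scale_min, spec.scale_max + 1))
            assert pres and pres < full


@settings(derandomize=True, max_examples=300)
@given(
    instrument=st.sampled_from(["DASS21", "EQ_SHORT", "JSE_S", "EES"]),
    data=st.data(),
)
def test_binarize_agrees_with_preimage_partition(instrument, data):
    """binarize_item(s, item) is 1 exactly when s lies in the item's declared
    presence preimage, for every instrument, item and in-range score."""
    spec = _ALL_SPECS[instrument]
    item = data.draw(st.integers(1, spec.n_items))
    score = data.draw(st.integers(spec.scale_min, spec.scale_max))
    expected = 1.0 if score in spec.presence_scores(item) else 0.0
    assert binarize_item(score, spec, item) == expected


_ALL_SPECS = load_instrument_specs()


def test_binarize_item_rejects_out_of_range(specs):
    with pytest.raises(BinarizationError) as err:
        binarize_item(9, specs["DASS21"], 4)
    assert "DASS21" in str(err.value) and "4" in str(err.value) and "9" in str(err.value)
    assert math.isnan(binarize_item(float("nan"), specs["DASS21"], 4))


def test_binarize_table_matches_elementwise_rule(specs):
    table = likert_table(
        specs,
        {"DASS-21: 1": [0, 2, 3], "DASS-21: 16": [1, 0, 2], "EES: 12": [1, 3, 5]},
    )
    binary = binarize_table(table, specs)
    for col in ["DASS-21: 1", "DASS-21: 16", "EES: 12"]:
        prefix, item = col.rsplit(": ", 1)
        spec = next(s for s in specs.values() if s.label == prefix)
        for i in range(3):
            assert binary[col].iloc[i] == binarize_item(table[col].iloc[i], spec, int(item))
    # all-minimum scores on ordinary items binarize to all zeros
    zeros = binarize_table(likert_table(specs, {"DASS-21: 2": [0, 0], "EES: 13": [1, 1]}), specs)
    assert (zeros[["DASS-21: 2", "EES: 13"]].to_numpy() == 0).all()


def test_binarize_table_errors(specs):
    with pytest.raises(BinarizationError):
        binarize_table(likert_table(specs, {"DASS-21: 3": [0, 9]}), specs)
    with pytest.raises(BinarizationError):
        binarize_table(likert_table(specs, {"NOPE: 1": [0, 1]}), specs)


def _table_with_counts(counts_by_label):
    """Binary table (PRE+POST) whose per-item 1-counts match the given counts."""
    n = STUDY_N_PARTICIPANTS
    frames = []
    for tp_idx, tp in enumerate(("PRE", "POST")):
        data = {"participant_id": [f"P{i:03d}" for i in range(n)], "time_point": [tp] * n}
        for label, counts in counts_by_label.items():
            c = counts[tp_idx]
            data[label] = [1.0] * c + [0.0] * (n - c)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def test_filter_retains_all_24_study_items():
    """The printed per-item presence counts all satisfy the dual >=30% rule."""
    table = _table_with_counts(STUDY_PRESENCE_COUNTS)
    retained = filter_items(table, 0.30, per_time_point=True)
    assert retained == list(STUDY_PRESENCE_COUNTS)


def test_filter_threshold_boundaries():
    """With N = 40 and fraction 0.30 an item needs 12 <= ones <= 28 at every
    time point."""
    counts = {
        "DASS-21: 1": (11, 20),  # fails PRE
        "DASS-21: 2": (12, 12),  # boundary pass
        "DASS-21: 3": (28, 28),  # boundary pass
        "DASS-21: 4": (29, 20),  # fails PRE (too few zeros)
        "DASS-21: 5": (40, 20),  # one category empty
        "DASS-21: 6": (20, 11),  # fails POST
    }
    table = _table_with_counts(counts)
    assert filter_items(table, 0.30) == ["DASS-21: 2", "DASS-21: 3"]


def test_filter_matches_counting_oracle():
    rng = np.random.default_rng(7)
    n = 40
    cols = {f"EES: {i + 1}": rng.integers(0, 2, size=2 * n).astype(float) for i in range(10)}
    table = pd.DataFrame({"participant_id": [f"P{i}" for i in range(2 * n)],
                          "time_point": ["PRE"] * n + ["POST"] * n, **cols})
    retained = filter_items(table, 0.30, per_time_point=True)
    expected = []
    for label, vals in cols.items():
        ok = True
        for half in (vals[:n], vals[n:]):
            ones = int(half.sum())
            if ones < 12 or (n - ones) < 12:
                ok = False
        if ok:
            expected.append(label)
    assert retained == expected
    # pooled mode counts all 80 records against ceil(0.3 * 80) = 24
    pooled = filter_items(table, 0.30, per_time_point=False)
    expected_pooled = [lab for lab, v in cols.items() if v.sum() >= 24 and (2 * n - v.sum()) >= 24]
    assert pooled == expected_pooled


def test_filter_empty_table_rejected(specs):
    with pytest.raises(ValueError):
        filter_items(pd.DataFrame(columns=["participant_id", "time_point"]))


def test_scale_totals_sums_and_reverse_scoring(specs):
    rng = np.random.default_rng(3)
    dass = {f"DASS-21: {i}": rng.integers(0, 4, 5).astype(float) for i in range(1, 22)}
    jse = {f"JSE-S: {i}": rng.integers(1, 8, 5).astype(float) for i in range(1, 21)}
    table = likert_table(specs, {**dass, **jse})
    totals = scale_totals(table, specs)
    # DASS: raw sums, subscales partition the total
    dass_mat = np.column_stack([dass[f"DASS-21: {i}"] for i in range(1, 22)])
    assert np.allclose(totals["DASS21_total"], dass_mat.sum(axis=1))
    assert np.allclose(
        totals["DASS21_total"],
        totals["DASS21_depression"] + totals["DASS21_anxiety"] + totals["DASS21_stress"],
    )
    # JSE-S: reversed items recoded to 8 - score before summing
    spec = specs["JSE_S"]
    expected = np.zeros(5)
    for i in range(1, 21):
        v = jse[f"JSE-S: {i}"]
        expected += (8 - v) if spec.is_reversed(i) else v
    assert np.allclose(totals["JSE_S_total"], expected)


def test_scale_totals_trivial_and_missing(specs):
    table = likert_table(specs, {f"DASS-21: {i}": [0.0, 1.0, np.nan] for i in range(1, 22)})
    totals = scale_totals(table, specs)
    assert totals["DASS21_total"].iloc[0] == 0
    assert totals["DASS21_total"].iloc[1] == 21
    assert np.isnan(totals["DASS21_total"].iloc[2]) and totals["incomplete"].iloc[2]


def test_paired_t_test_degenerate_cases():
    res = paired_t_test([3.0, 1.0, 4.0], [3.0, 1.0, 4.0])
    assert res.t == 0.0 and res.p == 1.0 and not res.undefined
    res = paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert res.undefined and math.isnan(res.p)
    with pytest.raises(ValueError):
        paired_t_test([1.0], [2.0])


def test_paired_t_test_matches_formula_oracle():
    rng = np.random.default_rng(11)
    pre = rng.normal(10, 2, size=40)
    post = pre + rng.normal(0.5, 1, size=40)
    res = paired_t_test(pre, post)
    d = post - pre
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
    assert res.df == 39
    assert res.t == pytest.approx(t_oracle, rel=1e-12)
    assert res.p == pytest.approx(p_oracle, rel=1e-12)


def test_paired_totals_tests_wide_pivot(specs):
    rng = np.random.default_rng(5)
    n = 10
    rows = {f"EES: {i}": rng.integers(1, 6, 2 * n).astype(float) for i in range(1, 18)}
    table = pd.DataFrame({
        "participant_id": [f"P{i:02d}" for i in range(n)] * 2,
        "time_point": ["PRE"] * n + ["POST"] * n,
        **rows,
    })
    out = paired_totals_tests(scale_totals(table, specs))
    row = out[out["measure"] == "EES_total"].iloc[0]
    assert row["n"] == n and row["df"] == n - 1
    assert 0.0 <= row["p"] <= 1.0
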