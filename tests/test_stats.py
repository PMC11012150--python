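"""Significance labelling, tests, replicate summaries, comparison matrix."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bifor.errors import ConfigError, ManifestError
from bifor.stats import (
    compare_conditions,
    compare_replicate_means,
    run_condition_matrix,
    significance_label,
    summarize_by_replicate,
)


@pytest.mark.parametrize(
    "p,expected",
    [(1e-5, "***"), (1e-4, "***"), (0.0002, "*"), (0.005, "*"), (0.01, "*"), (0.0101, "ns"), (0.5, "ns")],
)
def test_significance_labels(p, expected):
    assert significance_label(p) == expected


@given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
@settings(max_examples=200, derandomize=True)
def test_label_is_total_and_consistent(p):
    label = significance_label(p)
    assert label == ("***" if p <= 1e-4 else "*" if p <= 0.01 else "ns")


@pytest.mark.parametrize("test", ["mannwhitney", "permutation"])
def test_identical_groups_are_ns(test):
    scores = [0.2, 0.4, 0.6, 0.8, 1.0] * 4
    res = compare_conditions(scores, list(scores), test=test, seed=1)
    assert res.label == "ns"
    assert res.p_value > 0.5


def test_insufficient_data_flag():
    res = compare_conditions([0.5], [0.4, 0.6])
    assert res.insufficient and res.p_value is None and res.label is None


def test_permutation_matches_exhaustive_enumeration(rng):
    """On <= 8 scores total the permutation p equals the exact enumeration
    over all label assignments, computed here independently."""
    for _ in range(5):
        a = rng.uniform(0, 1, size=4)
        b = rng.uniform(0, 1, size=4)
        res = compare_conditions(a, b, test="permutation", seed=0)
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        hits = sum(
            abs(pooled[list(idx)].mean() - np.delete(pooled, list(idx)).mean()) >= observed - 1e-12
            for idx in combinations(range(8), 4)
        )
        assert res.test_name == "permutation_exact"
        assert res.p_value == pytest.approx(hits / math.comb(8, 4), abs=0)


def test_sampled_permutation_is_seed_reproducible(rng):
    a = rng.normal(0.6, 0.1, size=40)
    b = rng.normal(0.5, 0.1, size=40)
    r1 = compare_conditions(a, b, test="permutation", seed=7)
    r2 = compare_conditions(a, b, test="permutation", seed=7)
    assert r1.test_name == "permutation_mc"
    assert r1.p_value == r2.p_value


def test_mannwhitney_and_permutation_agree_on_clear_cases(rng):
    strong_a = rng.normal(0.95, 0.02, size=30)
    strong_b = rng.normal(0.70, 0.08, size=30)
    null_a = rng.normal(0.7, 0.08, size=30)
    null_b = rng.normal(0.7, 0.08, size=30)
    for a, b, expect_sig in [(strong_a, strong_b, True), (null_a, null_b, False)]:
        mw = compare_conditions(a, b, test="mannwhitney")
        pm = compare_conditions(a, b, test="permutation", seed=3)
        assert (mw.p_value <= 0.01) == expect_sig
        assert (pm.p_value <= 0.01) == expect_sig


def test_type_i_error_on_synthetic_scores():
    """Monte-Carlo calibration of the default test at alpha=0.01 on
    exchangeable null score samples."""
    rng = np.random.default_rng(2718)
    rejections = 0
    reps = 300
    for _ in range(reps):
        a = rng.beta(8, 3, size=30)
        b = rng.beta(8, 3, size=30)
        if compare_conditions(a, b).p_value <= 0.01:
            rejections += 1
    assert 0.002 <= rejections / reps <= 0.03


def _score_table():
    rows = []
    for cond, base in [("A", 0.9), ("B", 0.6)]:
        for rep in (1, 2, 3):
            for i in range(10):
                rows.append({"condition": cond, "replicate": rep, "value": base + 0.001 * i})
    return pd.DataFrame(rows)


def test_replicate_summary_shape_and_means():
    table = _score_table()
    summary = summarize_by_replicate(table)
    assert len(summary) == 6
    assert (summary["n"] == 10).all()
    const = pd.DataFrame({"condition": "A", "replicate": [1, 1, 2, 2], "value": 0.42})
    s = summarize_by_replicate(const)
    assert (s["mean"] == 0.42).all()


def test_replicate_summary_requires_replicate_column():
    with pytest.raises(ManifestError):
        summarize_by_replicate(pd.DataFrame({"condition": ["A"], "value": [0.5]}))


def test_pooled_and_replicate_level_agree_on_strong_effect():
    table = _score_table()
    pooled = compare_conditions(
        table.loc[table.condition == "A", "value"],
        table.loc[table.condition == "B", "value"],
    )
    by_rep = compare_replicate_means(table, "A", "B")
    assert pooled.p_value <= 0.01
    assert by_rep.p_value <= 0.01
    assert by_rep.n_a == 3 and by_rep.n_b == 3


def test_condition_matrix_validation_and_holm():
    table = _score_table()
    assert len(run_condition_matrix(table, [])) == 0
    with pytest.raises(ConfigError):
        run_condition_matrix(table, [("A", "MISSING")])
    raw = run_condition_matrix(table, [("A", "B"), ("B", "A")], holm=False)
    adj = run_condition_matrix(table, [("A", "B"), ("B", "A")], holm=True)
    assert "adjusted_p" in adj.columns
    assert (adj["adjusted_p"].to_numpy() >= raw["p_value"].to_numpy() - 1e-15).all()
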