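"""The enrichment ratio against brute-force oracles, plus dataset scoring."""

import numpy as np
import pandas as pd
import pytest

from bifor.enrichment import QuantifyParams, enrichment_ratio, score_dataset
from bifor.errors import DegenerateSignal, PipelineError
from bifor.io import empty_manifest
from bifor.pipeline import simulate_condition_scores
from bifor.synthetic import PRESETS, generate_condition_dataset
from helpers import brute_force_ratio, make_toy_scene, region_objects


def test_uniform_green_gives_one():
    nucleus = np.zeros((9, 9), bool)
    nucleus[2:7, 2:7] = True
    locus = np.zeros((9, 9), bool)
    locus[4, 4] = True
    nuc, loc = region_objects(nucleus, locus)
    score = enrichment_ratio(np.full((9, 9), 3.7), loc, nuc)
    assert score.value == 1.0


def test_locus_containing_global_max_gives_one(rng):
    green, nucleus, locus = make_toy_scene(rng, force_max_in_locus=True)
    nuc, loc = region_objects(nucleus, locus)
    assert enrichment_ratio(green, loc, nuc).value == 1.0


def test_enumerated_5x5_toy():
    """A fully written-out 5x5 nucleus with a 2x2 locus, checked against an
    exhaustive scan over the two voxel lists."""
    green = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [6.0, 7.0, 8.0, 9.0, 10.0],
            [11.0, 40.0, 13.0, 14.0, 15.0],
            [16.0, 17.0, 90.0, 19.0, 20.0],
            [21.0, 22.0, 23.0, 24.0, 25.0],
        ]
    )
    nucleus = np.ones((5, 5), bool)
    locus = np.zeros((5, 5), bool)
    locus[1:3, 1:3] = True  # values {7, 8, 40, 13}
    nuc, loc = region_objects(nucleus, locus)
    score = enrichment_ratio(green, loc, nuc)
    assert score.value == brute_force_ratio(green, nucleus, locus)
    assert score.value == pytest.approx(40.0 / 90.0)
    assert score.locus_max == 40.0 and score.nucleus_max == 90.0


def test_matches_brute_force_on_random_toys(rng):
    for _ in range(50):
        green, nucleus, locus = make_toy_scene(rng)
        nuc, loc = region_objects(nucleus, locus)
        score = enrichment_ratio(green, loc, nuc)
        assert score.value == brute_force_ratio(green, nucleus, locus)
        assert 0.0 < score.value <= 1.0


def test_shift_moves_ratio_toward_one(rng):
    """Adding a constant background c >= 0 increases (m+c)/(M+c) monotonically:
    uncorrected background compresses real enrichment differences."""
    green, nucleus, locus = make_toy_scene(rng, force_max_in_locus=False)
    nuc, loc = region_objects(nucleus, locus)
    values = [enrichment_ratio(green + c, loc, nuc).value for c in (0.0, 10.0, 100.0, 1000.0)]
    assert all(b > a for a, b in zip(values, values[1:]))
    assert values[-1] < 1.0


def test_quantile_estimator():
    nucleus = np.ones((8, 8), bool)
    locus = np.zeros((8, 8), bool)
    locus[3:5, 3:5] = True
    green = np.arange(64, dtype=float).reshape(8, 8)
    nuc, loc = region_objects(nucleus, locus)
    score = enrichment_ratio(green, loc, nuc, estimator="quantile", quantile=0.5)
    expected = np.quantile(green[locus], 0.5) / np.quantile(green, 0.5)
    assert score.value == pytest.approx(expected)
    assert score.estimator == "quantile(0.5)"


def test_zero_nucleus_signal_is_degenerate():
    nucleus = np.ones((6, 6), bool)
    locus = np.zeros((6, 6), bool)
    locus[2, 2] = True
    nuc, loc = region_objects(nucleus, locus)
    with pytest.raises(DegenerateSignal):
        enrichment_ratio(np.zeros((6, 6)), loc, nuc)


def test_empty_manifest_scores_empty():
    scores, exclusions = score_dataset(empty_manifest())
    assert len(scores) == 0 and len(exclusions) == 0


def test_score_dataset_bounds_and_determinism(tmp_path, small_spec):
    _, manifest = generate_condition_dataset(
        PRESETS["SCR_EXD_WT"], 5, 2, seed=4, outdir=tmp_path / "ds", base=small_spec
    )
    scores1, excl1 = score_dataset(manifest)
    scores2, _ = score_dataset(manifest)
    assert len(scores1) + len(excl1) == len(manifest)
    assert ((scores1["value"] > 0) & (scores1["value"] <= 1)).all()
    pd.testing.assert_frame_equal(scores1, scores2)


def test_unreadable_row_is_recorded_not_fatal(tmp_path, small_spec):
    _, manifest = generate_condition_dataset(
        PRESETS["SCR_EXD_WT"], 2, 1, seed=4, outdir=tmp_path / "ds", base=small_spec
    )
    manifest.loc[0, "path"] = str(tmp_path / "missing.tif")
    scores, exclusions = score_dataset(manifest)
    assert len(scores) == 1
    assert len(exclusions) == 1 and "FileNotFoundError" in exclusions["reason"].iloc[0]
    # every row failing is fatal
    manifest["path"] = str(tmp_path / "missing.tif")
    with pytest.raises(PipelineError):
        score_dataset(manifest)


def test_enriched_scores_exceed_null(small_spec):
    """Effect recovery: positive beta shifts the measured score distribution up."""
    params = QuantifyParams()
    enriched = simulate_condition_scores("SCR_EXD_WT", 15, 1, seed=21, params=params, base=small_spec)
    null = simulate_condition_scores("SCR_ALONE_WT", 15, 1, seed=21, params=params, base=small_spec)
    assert enriched["value"].mean() > null["value"].mean()
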