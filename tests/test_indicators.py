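import numpy as np
import pandas as pd
import pytest

import pupilload as pl
from pupilload.indicators import (accuracy_table, fixation_precision,
                                  fixation_residuals, z_standardize,
                                  z_standardize_records)
from pupilload.model import Segment, StudyDesign


# -- channels --------------------------------------------------------------

def test_channel_examples():
    ch = pl.channels_from_eyes(2.0, 1.0)
    assert ch == {"left": 2.0, "right": 1.0, "mean": 1.5, "diff": 1.0}
    eq = pl.channels_from_eyes(3.2, 3.2)
    assert eq["diff"] == 0.0 and eq["mean"] == 3.2


def test_one_eye_missing_makes_whole_set_missing():
    ch = pl.channels_from_eyes(float("nan"), 1.0)
    assert all(np.isnan(v) for v in ch.values())


def test_channels_match_naive_recomputation_and_eye_swap():
    rng = np.random.default_rng(0)
    for left, right in rng.uniform(0, 5, size=(1000, 2)):
        ch = pl.channels_from_eyes(left, right)
        sw = pl.channels_from_eyes(right, left)
        assert ch["mean"] == (left + right) / 2
        assert ch["diff"] == abs(left - right)
        assert ch["mean"] == sw["mean"] and ch["diff"] == sw["diff"]


# -- z-standardization -----------------------------------------------------

def test_z_of_one_two_three():
    np.testing.assert_allclose(z_standardize([1.0, 2.0, 3.0]),
                               [-1.0, 0.0, 1.0], atol=1e-12)


def test_z_contract_mean_zero_sd_one():
    rng = np.random.default_rng(3)
    z = z_standardize(rng.uniform(0, 4, 200))
    assert abs(z.mean()) < 1e-12
    assert abs(z.std(ddof=1) - 1.0) < 1e-12


def test_z_idempotent_and_affine_invariant():
    rng = np.random.default_rng(4)
    x = rng.normal(2.0, 0.7, 50)
    z = z_standardize(x)
    np.testing.assert_allclose(z_standardize(z), z, atol=1e-12)
    np.testing.assert_allclose(z_standardize(3.5 * x + 10.0), z, atol=1e-12)


def test_constant_indicator_becomes_missing():
    assert np.isnan(z_standardize([2.0, 2.0, 2.0])).all()
    assert np.isnan(z_standardize([1.0])).all()


def test_z_against_direct_formula_with_missing_values():
    x = np.array([1.0, np.nan, 3.0, 5.0, 2.0])
    z = z_standardize(x)
    finite = x[np.isfinite(x)]
    expect = (finite - finite.mean()) / finite.std(ddof=1)
    np.testing.assert_allclose(z[np.isfinite(x)], expect, atol=1e-12)
    assert np.isnan(z[1])


def _records():
    rows = []
    rng = np.random.default_rng(9)
    for pid in ("p1", "p2"):
        for i in range(8):
            left, right = rng.uniform(0.5, 3.0, 2)
            for chan, val in pl.channels_from_eyes(left, right).items():
                rows.append({"participant_id": pid, "label": "a",
                             "segment_id": f"{pid}_s{i}", "channel": chan,
                             "standardized": False, "value": val})
    return pd.DataFrame(rows)


def test_standardized_records_per_participant_channel():
    std = z_standardize_records(_records())
    assert std["standardized"].all()
    for (_, _), grp in std.groupby(["participant_id", "channel"]):
        assert abs(grp["value"].mean()) < 1e-12
        assert abs(grp["value"].std(ddof=1) - 1.0) < 1e-12


def test_diff_of_z_mode_equals_abs_z_difference():
    records = _records()
    std = z_standardize_records(records, diff_mode="diff_of_z")
    wide_raw = records.pivot_table(index=["participant_id", "segment_id"],
                                   columns="channel", values="value")
    expect = {}
    for pid, grp in wide_raw.groupby(level=0):
        zl = z_standardize(grp["left"].to_numpy())
        zr = z_standardize(grp["right"].to_numpy())
        for sid, v in zip(grp.index.get_level_values(1), np.abs(zl - zr)):
            expect[(pid, sid)] = v
    diff = std[std["channel"] == "diff"]
    for row in diff.itertuples():
        assert row.value == pytest.approx(
            expect[(row.participant_id, row.segment_id)], abs=1e-12)


# -- aggregation -----------------------------------------------------------

def test_aggregate_examples_and_groupby_oracle():
    df = pd.DataFrame({
        "participant_id": ["p1"] * 3, "label": ["a", "a", "b"],
        "segment_id": ["s1", "s2", "s3"], "channel": ["mean"] * 3,
        "standardized": [False] * 3, "value": [1.0, 3.0, 5.0]})
    agg = pl.aggregate_by_label(df)
    a = agg[agg["label"] == "a"].iloc[0]
    assert a["value"] == 2.0 and a["n_segments"] == 2
    assert agg[agg["label"] == "b"].iloc[0]["value"] == 5.0


def test_missing_segments_excluded_not_zero_filled():
    df = pd.DataFrame({
        "participant_id": ["p1"] * 3, "label": ["a"] * 3,
        "segment_id": ["s1", "s2", "s3"], "channel": ["mean"] * 3,
        "standardized": [False] * 3, "value": [2.0, np.nan, 4.0]})
    agg = pl.aggregate_by_label(df)
    assert agg.iloc[0]["value"] == 3.0
    assert agg.iloc[0]["n_segments"] == 2


def test_full_cohort_aggregate_matches_independent_groupby(small_cohort):
    samples, segments, _ = small_cohort
    out = pl.run_analysis(samples, segments, pl.RunConfig())
    records = out["indicators"]
    agg = out["aggregates"]
    raw = records[~records["standardized"]]
    for row in agg[~agg["standardized"]].sample(10, random_state=0).itertuples():
        vals = raw[(raw["participant_id"] == row.participant_id)
                   & (raw["label"] == row.label)
                   & (raw["channel"] == row.channel)]["value"].dropna()
        assert row.value == pytest.approx(vals.mean(), abs=1e-12)
        assert row.n_segments == len(vals)


# -- accuracy --------------------------------------------------------------

def _item(pid, sid, level, kind, correct):
    return Segment(participant_id=pid, segment_id=sid, label=level,
                   item_type=kind, response_correct=correct,
                   t_start=float(sid[-1]) * 10, t_end=float(sid[-1]) * 10 + 5)


def test_accuracy_uses_possible_items_only():
    segs = [_item("p1", f"s{i}", "a", "possible", 1.0 if i < 3 else 0.0)
            for i in range(5)]
    segs += [_item("p1", f"t{i}", "a", "impossible", 0.0) for i in range(5)]
    assert pl.accuracy_score(segs, "a") == pytest.approx(0.6)


def test_accuracy_all_correct_and_missing_level():
    segs = [_item("p1", f"s{i}", "b", "possible", 1.0) for i in range(5)]
    assert pl.accuracy_score(segs, "b") == 1.0
    assert np.isnan(pl.accuracy_score(segs, "c"))


def test_unanswered_possible_item_scores_zero():
    segs = [_item("p1", "s1", "a", "possible", 1.0),
            _item("p1", "s2", "a", "possible", float("nan"))]
    assert pl.accuracy_score(segs, "a") == pytest.approx(0.5)


def test_accuracy_table_matches_scores(small_cohort):
    _, segments, manifest = small_cohort
    table = accuracy_table(segments)
    truth = manifest["participants"][0]["segments"]
    pid = manifest["participants"][0]["participant_id"]
    for level in ("a", "f"):
        hits = [v["correct"] for v in truth.values()
                if v.get("item_type") == "possible" and v["label"] == level]
        row = table[(table["participant_id"] == pid)
                    & (table["level"] == level)]
        assert row.iloc[0]["accuracy"] == pytest.approx(np.mean(hits))


# -- fixation precision ----------------------------------------------------

def test_precision_zero_when_on_target():
    assert fixation_precision(np.zeros(10), np.zeros(10)) == (0.0, 0.0)


def test_precision_two_point_example():
    sd_x, sd_y = fixation_precision([0.0, 2.0], [0.0, 0.0])
    assert sd_x == pytest.approx(np.sqrt(2.0))
    assert sd_y == 0.0


def test_precision_below_two_samples_missing():
    sd_x, sd_y = fixation_precision([1.0], [1.0])
    assert np.isnan(sd_x) and np.isnan(sd_y)


def test_precision_recovers_designed_scatter():
    rng = np.random.default_rng(15)
    n = 8100                                   # 9 crosses x 3 s x 300 Hz
    sd_x, sd_y = fixation_precision(rng.normal(0, 15.0, n),
                                    rng.normal(0, 15.0, n))
    assert sd_x == pytest.approx(15.0, rel=0.02)
    assert sd_y == pytest.approx(15.0, rel=0.02)


def test_fixation_residuals_use_cross_windows(small_cohort):
    samples, segments, _ = small_cohort
    fix1 = next(s for s in pl.io.iter_segments(segments)
                if s.label == "fix1")
    design = StudyDesign()
    rx, ry = fixation_residuals(samples, fix1, design)
    # 9 crosses x 3 s x 300 Hz, minus blink-invalidated samples
    assert 7500 <= len(rx) <= 8100
    assert np.std(rx) == pytest.approx(15.0, rel=0.1)
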