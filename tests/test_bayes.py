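import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pupilload as pl
from pupilload.bayes import (DEFAULT_PLAN, classify_evidence, evidence_marker,
                             jzs_bf, jzs_bf_paired, nct_likelihood, paired_t,
                             posterior_effect_size, run_pairwise_comparisons)
from pupilload.errors import DegenerateDataError


# -- paired t --------------------------------------------------------------

def test_paired_t_matches_scipy():
    rng = np.random.default_rng(1)
    d = rng.normal(0.4, 1.0, 30)
    t, n = paired_t(d)
    ref = stats.ttest_1samp(d, 0.0)
    assert t == pytest.approx(ref.statistic, abs=1e-12)
    assert n == 30


def test_degenerate_differences_raise():
    with pytest.raises(DegenerateDataError):
        paired_t([1.0, 1.0, 1.0])
    with pytest.raises(DegenerateDataError):
        paired_t([1.0])


# -- likelihood backbone ---------------------------------------------------

@pytest.mark.parametrize("t,df", [(0.0, 3), (0.3, 5), (2.5, 29), (-1.7, 12),
                                  (8.0, 29), (15.0, 54), (1.2, 2)])
def test_noncentral_t_likelihood_matches_scipy(t, df):
    ncs = np.linspace(t - 6, t + 6, 13)
    mine = nct_likelihood(t, df, ncs)
    ref = stats.nct.pdf(t, df, ncs)
    np.testing.assert_allclose(mine, ref, atol=1e-9)


# -- Bayes factors ---------------------------------------------------------

def test_null_favoring_at_t_zero():
    for n in (5, 20, 55):
        assert jzs_bf(0.0, n) < 1.0


def test_directional_symmetry():
    rng = np.random.default_rng(2)
    d = rng.normal(0.3, 1.0, 24)
    assert jzs_bf_paired(d, direction="greater") == pytest.approx(
        jzs_bf_paired(-d, direction="less"), rel=1e-9)


def test_half_line_bayes_factors_sum_to_twice_two_sided():
    for t in (-2.5, 0.0, 1.3, 4.0):
        g = jzs_bf(t, 30, direction="greater")
        less = jzs_bf(t, 30, direction="less")
        two = jzs_bf(t, 30)
        assert g + less == pytest.approx(2 * two, rel=1e-6)


def test_bf_tends_to_one_as_prior_collapses():
    assert jzs_bf(2.0, 30, r=1e-7) == pytest.approx(1.0, abs=1e-5)


def test_bf_strictly_increasing_in_abs_t():
    bfs = [jzs_bf(t, 30) for t in np.linspace(0.0, 6.0, 13)]
    assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))


@pytest.mark.parametrize("t,n", [(0.0, 20), (1.5, 30), (3.4, 55),
                                 (17.0, 28), (-2.2, 26)])
def test_two_sided_bf_matches_pingouin(t, n):
    pingouin = pytest.importorskip("pingouin")
    ref = float(pingouin.bayesfactor_ttest(t, nx=n, paired=True, r=1.0))
    assert jzs_bf(t, n, r=1.0) == pytest.approx(ref, rel=1e-8)


# -- posterior effect sizes ------------------------------------------------

def test_zero_differences_give_symmetric_zero_posterior():
    es, (lo, hi) = posterior_effect_size(0.0, 30)
    assert es == pytest.approx(0.0, abs=1e-6)
    assert lo == pytest.approx(-hi, abs=1e-6)


def test_directed_posterior_supported_on_half_line():
    es, (lo, hi) = posterior_effect_size(2.0, 30, direction="greater")
    assert lo >= 0.0 and lo <= es <= hi
    es_l, (lo_l, hi_l) = posterior_effect_size(-2.0, 30, direction="less")
    assert hi_l <= 0.0 and lo_l <= es_l <= hi_l


def test_two_sided_posterior_mean_shrinks_toward_zero():
    for t, n in [(2.5, 20), (4.0, 30), (-3.0, 26)]:
        es, _ = posterior_effect_size(t, n)
        raw = t / math.sqrt(n)
        assert 0 < abs(es) < abs(raw)
        assert math.copysign(1, es) == math.copysign(1, raw)


def test_posterior_matches_importance_sampling_oracle():
    # independent oracle: draw delta from the Cauchy prior, weight by the
    # scipy noncentral-t likelihood, summarise the weighted sample
    t, n, r = 2.2, 28, 1.0
    rng = np.random.default_rng(77)
    delta = rng.standard_cauchy(200_000) * r
    delta = delta[np.abs(delta) < 50]
    w = stats.nct.pdf(t, n - 1, delta * math.sqrt(n))
    oracle_mean = float(np.sum(w * delta) / np.sum(w))
    order = np.argsort(delta)
    cdf = np.cumsum(w[order]) / np.sum(w)
    oracle_lo = float(delta[order][np.searchsorted(cdf, 0.025)])
    oracle_hi = float(delta[order][np.searchsorted(cdf, 0.975)])
    sd = math.sqrt(float(np.sum(w * delta ** 2) / np.sum(w)) - oracle_mean ** 2)
    es, (lo, hi) = posterior_effect_size(t, n, r)
    assert abs(es - oracle_mean) < 0.02 * sd
    assert abs(lo - oracle_lo) < 0.1 * sd
    assert abs(hi - oracle_hi) < 0.1 * sd


# -- evidence classification ----------------------------------------------

@pytest.mark.parametrize("bf,expected", [
    (17.36, "strong_H1"),
    (398.98, "extreme_H1"),
    (0.16, "moderate_H0"),
    (0.03, "very_strong_H0"),
    (1.0, "anecdotal_H0"),
    (2.99, "anecdotal_H1"),
    (3.0, "anecdotal_H1"),
    (3.01, "moderate_H1"),
    (1 / 3, "anecdotal_H0"),
    (0.009, "extreme_H0"),
    (101.0, "extreme_H1"),
    (30.0, "strong_H1"),
])
def test_evidence_bands(bf, expected):
    assert classify_evidence(bf) == expected


def test_invalid_bf_rejected():
    with pytest.raises(ValueError):
        classify_evidence(0.0)
    with pytest.raises(ValueError):
        classify_evidence(-2.0)


@pytest.mark.parametrize("bf,marker", [
    (398.98, "****"), (17.36, "**"), (4.0, "*"), (2.0, ""),
    (0.16, "'"), (0.03, "'''"), (0.005, "''''")])
def test_markers_render_like_table_legend(bf, marker):
    assert evidence_marker(classify_evidence(bf)) == marker


# -- comparison battery ----------------------------------------------------

def _aggregate_frame(rng, n=30, effects=None, channels=("mean", "diff")):
    """Aggregate table with N(effect, 1) participant values per label."""
    effects = effects or {}
    labels = pl.LABELS
    rows = []
    for channel in channels:
        for label in labels:
            mu = effects.get((channel, label), 0.0)
            vals = mu + rng.normal(0, 1, n)
            for i, v in enumerate(vals):
                rows.append({"participant_id": f"p{i}", "label": label,
                             "channel": channel, "standardized": False,
                             "value": v, "n_segments": 10})
    return pd.DataFrame(rows)


def test_default_plan_is_the_eight_row_battery():
    assert len(DEFAULT_PLAN) == 8
    assert DEFAULT_PLAN[0] == ("fix2", "fix1", "two_sided")
    assert DEFAULT_PLAN[1] == ("a", "fix1", "greater")
    assert DEFAULT_PLAN[-1] == ("f", "e", "greater")


def test_battery_shape_and_diff_direction_flip():
    rng = np.random.default_rng(5)
    out = run_pairwise_comparisons(_aggregate_frame(rng),
                                   standardized=(False,))
    assert len(out) == 16                      # 8 pairs x 2 channels
    directed = out[out["pair_a"] == "a"]
    assert (directed[directed["channel"] == "mean"]["direction"]
            == "greater").all()
    assert (directed[directed["channel"] == "diff"]["direction"]
            == "less").all()


def test_participants_missing_one_member_dropped_pairwise():
    rng = np.random.default_rng(6)
    agg = _aggregate_frame(rng, n=10, channels=("mean",))
    agg = agg[~((agg["participant_id"] == "p0") & (agg["label"] == "fix1"))]
    out = run_pairwise_comparisons(agg, channels=("mean",),
                                   standardized=(False,))
    by_pair = out.set_index(["pair_a", "pair_b"])["n"]
    assert by_pair[("a", "fix1")] == 9
    assert by_pair[("b", "a")] == 10


def test_zero_variance_pair_flagged_degenerate():
    agg = _aggregate_frame(np.random.default_rng(7), n=5, channels=("mean",))
    agg.loc[agg["label"].isin(["a", "fix1"]), "value"] = 1.0
    out = run_pairwise_comparisons(agg, channels=("mean",),
                                   standardized=(False,))
    row = out[(out["pair_a"] == "a") & (out["pair_b"] == "fix1")].iloc[0]
    assert row["evidence"] == "degenerate" and np.isnan(row["bf10"])


def test_null_aggregates_favor_h0_across_replications():
    h0 = 0
    total = 0
    for rep in range(20):
        rng = np.random.default_rng(500 + rep)
        out = run_pairwise_comparisons(_aggregate_frame(rng),
                                       standardized=(False,))
        h0 += int((out["bf10"] < 1).sum())
        total += len(out)
    assert h0 / total >= 0.9


def test_large_designed_effect_recovered_across_replications():
    wins = 0
    for rep in range(20):
        rng = np.random.default_rng(900 + rep)
        agg = _aggregate_frame(rng, n=30,
                               effects={("mean", lab): 1.3
                                        for lab in "abcdef"},
                               channels=("mean",))
        out = run_pairwise_comparisons(agg, channels=("mean",),
                                       standardized=(False,))
        row = out[(out["pair_a"] == "a") & (out["pair_b"] == "fix1")].iloc[0]
        wins += int(row["bf10"] > 10)
    assert wins >= 18
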