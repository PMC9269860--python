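"""Metrics, sweep bookkeeping, aggregation and the statistical machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iemgprop import evaluate, features, preprocess, synth


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_rmse_examples(rng):
    x = rng.random(1000)
    assert evaluate.rmse_percent(x, x) == 0.0
    assert evaluate.rmse_percent(x, x + 0.1) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        evaluate.rmse_percent(x, x[:-1])


def test_rmse_of_zero_estimate_is_measured_rms():
    t = np.linspace(0, 40, 4000)
    measured = np.clip(np.sin(2 * np.pi * 0.1 * t), 0, None)
    expected = 100 * np.sqrt(np.mean(measured**2))
    assert evaluate.rmse_percent(measured, np.zeros_like(measured)) == pytest.approx(expected)


def test_pearson_affine_invariance(rng):
    x = rng.random(500)
    assert evaluate.zero_lag_pearson(x, 2 * x + 0.3) == pytest.approx(1.0)
    assert evaluate.zero_lag_pearson(x, -x) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        evaluate.zero_lag_pearson(x, np.full_like(x, 0.5))


def test_pearson_null_distribution():
    hits = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        if abs(evaluate.zero_lag_pearson(r.standard_normal(10_000), r.standard_normal(10_000))) < 0.05:
            hits += 1
    assert hits >= 95


def test_metric_consistency_perfect_estimate(rng):
    x = rng.random(300) + 0.1
    assert evaluate.rmse_percent(x, x) == 0.0
    assert evaluate.zero_lag_pearson(x, x) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# grid bookkeeping
# ---------------------------------------------------------------------------


def test_grid_cardinalities_match_declared_ranges():
    g = evaluate.SweepGrid()
    assert g.cardinality("MAV") == 11
    assert g.cardinality("SSC") == 6 * 21 == 126
    assert g.cardinality("ZC") == 126 and g.cardinality("WA") == 126
    assert g.cardinality("FR") == 11 * 15 == 165
    assert g.windows_for("MAV") == tuple(range(50, 1051, 100))
    assert g.windows_for("SSC") == tuple(range(50, 551, 100))
    assert g.thresholds_for("SSC")[:3] == (0.0, 0.2, 0.4)
    assert g.thresholds_for("FR") == tuple(range(85, 100))


def test_best_per_algorithm_tie_breaks():
    df = pd.DataFrame(
        [
            {"segment_id": "s", "algorithm": "MAV", "window_ms": 450.0, "threshold": np.nan,
             "rmse_percent": 10.0, "pearson_r": 0.9},
            {"segment_id": "s", "algorithm": "MAV", "window_ms": 150.0, "threshold": np.nan,
             "rmse_percent": 10.0, "pearson_r": 0.8},
            {"segment_id": "s", "algorithm": "MAV", "window_ms": 250.0, "threshold": np.nan,
             "rmse_percent": 12.0, "pearson_r": 0.95},
            {"segment_id": "s", "algorithm": "SSC", "window_ms": 50.0, "threshold": 0.4,
             "rmse_percent": 8.0, "pearson_r": 0.9},
            {"segment_id": "s", "algorithm": "SSC", "window_ms": 50.0, "threshold": 0.2,
             "rmse_percent": 8.0, "pearson_r": 0.9},
            {"segment_id": "s", "algorithm": "SSC", "window_ms": 50.0, "threshold": 1.0,
             "rmse_percent": np.nan, "pearson_r": np.nan},
        ]
    )
    best = evaluate.best_per_algorithm(df)
    mav = best[best.algorithm == "MAV"].iloc[0]
    assert mav.window_ms == 150.0  # smaller window wins the tie
    ssc_row = best[best.algorithm == "SSC"].iloc[0]
    assert ssc_row.threshold == 0.2  # then smaller threshold


def test_summarize_order_statistics():
    df = pd.DataFrame(
        {
            "algorithm": ["FR"] * 5,
            "rmse_percent": [10.0, 13.0, 17.8, 26.0, 30.0],
            "pearson_r": [0.8] * 5,
        }
    )
    s = evaluate.summarize(df).iloc[0]
    assert s.rmse_percent_median == pytest.approx(17.8)
    assert s.rmse_percent_q1 == pytest.approx(13.0)
    assert s.rmse_percent_q3 == pytest.approx(26.0)


def test_summarize_excludes_poor_segments():
    df = pd.DataFrame(
        {
            "algorithm": ["MAV", "MAV", "MAV"],
            "quality": ["good", "poor", "good"],
            "rmse_percent": [10.0, 90.0, 20.0],
            "pearson_r": [0.9, 0.1, 0.8],
        }
    )
    s = evaluate.summarize(df).iloc[0]
    assert s.n == 2
    assert s.rmse_percent_median == pytest.approx(15.0)


def test_run_sweep_row_counts_single_algorithm(proportional_segment):
    session, seg, _ = proportional_segment
    a, b = session.movement_slices[seg.movement]
    pos, _ = preprocess.split_force_phases(session.force[0, a:b])
    seg.force = pos
    df = evaluate.run_sweep([seg], algorithms=("MAV",), increment_ms=50.0)
    assert len(df) == 11
    assert df.rmse_percent.notna().all()


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def test_lilliefors_calibration_small():
    r = np.random.default_rng(0)
    _, p_norm = evaluate.lilliefors_normality(r.standard_normal(500))
    _, p_unif = evaluate.lilliefors_normality(r.random(500))
    assert p_norm > 0.05
    assert p_unif < 0.05
    with pytest.raises(ValueError):
        evaluate.lilliefors_normality(np.full(100, 2.0))
    with pytest.raises(ValueError):
        evaluate.lilliefors_normality([1.0, 2.0])


def test_friedman_statistic_matches_textbook_formula():
    # hand-computable tie-free 3x3 block design
    X = np.array([[1.0, 2.0, 3.0], [1.5, 2.5, 3.5], [1.2, 2.2, 3.2]])
    n, k = X.shape
    ranks = stats.rankdata(X, axis=1)
    rbar = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2.0) ** 2)
    table = evaluate.friedman_bonferroni(X)
    assert table.statistic == pytest.approx(chi2)
    np.testing.assert_allclose(table.mean_ranks, rbar)


def test_friedman_identical_columns_flag_nothing():
    X = np.tile(np.arange(10.0)[:, None], (1, 4))
    table = evaluate.friedman_bonferroni(X)
    assert table.p_omnibus == pytest.approx(1.0)
    assert not table.significant.any()


def test_friedman_dominant_column_flagged_against_all():
    r = np.random.default_rng(1)
    X = r.standard_normal((96, 14))
    X[:, 3] -= 10.0  # stochastically dominated column
    names = tuple(features.ALGORITHMS)
    table = evaluate.friedman_bonferroni(X, algorithms=names)
    flagged = set(table.flagged_pairs())
    dominated = names[3]
    for other in names:
        if other != dominated:
            pair = tuple(sorted((dominated, other), key=names.index))
            assert (pair[0], pair[1]) in flagged


def test_friedman_two_columns_agrees_with_sign_test():
    # k=2: the Friedman flag should agree with an exact binomial sign test
    r = np.random.default_rng(2)
    base = r.standard_normal(10)
    clear = np.column_stack([base, base + 1.0])  # 10/10 wins
    t_clear = evaluate.friedman_bonferroni(clear, require_omnibus=True)
    assert stats.binomtest(10, 10, 0.5).pvalue < 0.05
    assert t_clear.significant[0, 1]
    mixed = clear.copy()
    mixed[:3, 1] = base[:3] - 1.0  # 7/10 wins: binomial not significant
    t_mixed = evaluate.friedman_bonferroni(mixed)
    assert stats.binomtest(7, 10, 0.5).pvalue > 0.05
    assert not t_mixed.significant[0, 1]


def test_bonferroni_flags_subset_of_uncorrected():
    r = np.random.default_rng(3)
    X = r.standard_normal((30, 6))
    X[:, 0] -= 0.8
    X[:, 1] += 0.4
    table = evaluate.friedman_bonferroni(X, require_omnibus=False)
    k = X.shape[1]
    se = np.sqrt(k * (k + 1) / (6.0 * X.shape[0]))
    ranks = stats.rankdata(X, axis=1)
    rbar = ranks.mean(axis=0)
    z = np.abs(rbar[:, None] - rbar[None, :]) / se
    p_raw = 2 * stats.norm.sf(z)
    uncorrected = p_raw < 0.05
    assert np.all(~table.significant | uncorrected)


def test_friedman_input_validation():
    with pytest.raises(ValueError):
        evaluate.friedman_bonferroni(np.ones((2, 3)))
    bad = np.ones((5, 3))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        evaluate.friedman_bonferroni(bad)
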