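"""Data generation, metric computations and the study runners."""

import math

import numpy as np
import pytest

from medfx.conditions import (
    bayes_study_conditions,
    single_mediator_grid,
    two_mediator_grid,
)
from medfx.model import SimulationCondition
from medfx.simulate import (
    bradley_assess,
    generate_dataset,
    interval_metrics,
    point_metrics,
    run_bayes_study,
    run_interval_study,
    run_point_study,
    true_effect_sizes,
)

MEDIUM = {"a": 0.39, "b": 0.39, "c_prime": 0.39}


def test_generation_deterministic_given_seed():
    cond = SimulationCondition(n=50, paths=MEDIUM)
    d1, d2 = generate_dataset(cond, 9), generate_dataset(cond, 9)
    np.testing.assert_array_equal(d1.x, d2.x)
    np.testing.assert_array_equal(d1.y, d2.y)


def test_generated_variance_matches_closed_form():
    cond = SimulationCondition(n=1_000_000, paths=MEDIUM)
    data = generate_dataset(cond, 13)
    var_y = np.var(data.y, ddof=1)
    assert var_y == pytest.approx(0.5421**2 + 0.1521 + 1.0, rel=0.01)


def test_null_condition_has_no_structure():
    cond = SimulationCondition(n=10_000, paths={"a": 0.0, "b": 0.0, "c_prime": 0.0})
    data = generate_dataset(cond, 14)
    n = cond.n
    for u, v in [(data.x, data.mediators[0]), (data.x, data.y), (data.mediators[0], data.y)]:
        assert abs(np.corrcoef(u, v)[0, 1]) < 4 / math.sqrt(n)


def test_binary_x_is_zero_one():
    cond = SimulationCondition(n=200, paths=MEDIUM, x_type="binary")
    data = generate_dataset(cond, 15)
    assert set(np.unique(data.x)) <= {0.0, 1.0}


def test_true_effect_sizes_all_zero_paths():
    es = true_effect_sizes(SimulationCondition(n=50, paths={"a": 0, "b": 0, "c_prime": 0}))
    assert es.ab_ps == 0 and es.ab_fs == 0
    assert math.isnan(es.proportion) and math.isnan(es.ratio)


def test_true_proportion_is_one_under_complete_mediation():
    es = true_effect_sizes(SimulationCondition(n=50, paths={"a": 0.39, "b": 0.39, "c_prime": 0.0}))
    assert es.proportion == 1.0
    assert math.isnan(es.ratio)


def test_true_ab_ps_medium_paths():
    es = true_effect_sizes(SimulationCondition(n=50, paths=MEDIUM))
    assert es.ab_ps == pytest.approx(0.12649, abs=1e-5)


def test_point_metrics_arithmetic():
    m = point_metrics([0.11, 0.11, 0.11], truth=0.10)
    assert m["bias"] == pytest.approx(0.01)
    assert m["relative_bias"] == pytest.approx(0.10)
    assert m["sd"] == 0.0
    assert math.isnan(m["standardized_bias"])
    m2 = point_metrics([1.0, 2.0, 3.0], truth=0.0)
    assert math.isnan(m2["relative_bias"])  # undefined at truth 0
    m3 = point_metrics([np.nan, np.nan], truth=1.0)
    assert m3["reps_used"] == 0 and math.isnan(m3["bias"])


def test_interval_metrics_all_cover():
    lo, hi = np.full(50, 4.0), np.full(50, 6.0)
    m = interval_metrics(lo, hi, truth=5.0)
    assert m["coverage"] == 1.0 and m["width_mean"] == 2.0 and m["imbalance"] == 0.0
    assert m["rate_kind"] == "power" and m["rate_excl_zero"] == 1.0


def test_interval_metrics_all_miss_above_truth():
    lo, hi = np.full(20, 1.0), np.full(20, 2.0)
    m = interval_metrics(lo, hi, truth=0.0)
    assert m["rate_kind"] == "type1" and m["rate_excl_zero"] == 1.0
    # truth 0 sits left of every interval [1, 2]: all misses are on the
    # low side, so the right-minus-left disparity is -1
    assert m["coverage"] == 0.0 and m["imbalance"] == -1.0


def test_interval_metrics_undefined_truth():
    m = interval_metrics([1.0], [2.0], truth=math.nan)
    assert math.isnan(m["coverage"]) and m["rate_kind"] == "n/a"
    assert m["rate_excl_zero"] == 1.0


def test_coverage_and_misses_sum_to_one():
    rng = np.random.default_rng(2)
    lo = rng.standard_normal(200)
    hi = lo + rng.gamma(1, 1, 200)
    m = interval_metrics(lo, hi, truth=0.3)
    miss_left = np.mean(0.3 < lo)
    miss_right = np.mean(0.3 > hi)
    assert m["coverage"] + miss_left + miss_right == pytest.approx(1.0)
    assert m["imbalance"] == pytest.approx(miss_right - miss_left)


@pytest.mark.parametrize(
    "rate,kind,expected",
    [
        (0.05, "type1", "within"),
        (0.08, "type1", "above"),
        (0.02, "type1", "below"),
        (0.025, "type1", "within"),
        (0.924, "coverage", "below"),
        (0.95, "coverage", "within"),
        (0.976, "coverage", "above"),
    ],
)
def test_bradley_classification(rate, kind, expected):
    assert bradley_assess(rate, kind) == expected


def test_point_study_shape_and_determinism():
    grid = [
        SimulationCondition(n=20, paths=MEDIUM),
        SimulationCondition(n=20, paths={"a": 0.14, "b": 0.14, "c_prime": 0.0}),
    ]
    t1 = run_point_study(grid, reps=5, seed=3)
    t2 = run_point_study(grid, reps=5, seed=3)
    assert len(t1) == len(grid) * 4
    assert t1.equals(t2)


def test_point_study_relative_bias_small_at_large_n():
    cond = SimulationCondition(n=500, paths=MEDIUM)
    table = run_point_study([cond], reps=1000, seed=4)
    rel = table.set_index("estimator").loc["ab_ps", "relative_bias"]
    assert abs(rel) < 0.05


def test_interval_study_smoke_records():
    grid = [SimulationCondition(n=30, paths=MEDIUM, x_type="binary")]
    t = run_interval_study(grid, reps=2, B=100, seed=5)
    assert len(t) == 8  # 4 measures x 2 methods
    assert set(t["method"]) == {"percentile", "bias_corrected"}
    assert (t["reps_used"] + t["reps_undefined"] == 2).all()


def test_bias_corrected_type1_at_least_percentile_on_matched_seeds():
    """The bias-corrected bootstrap never has lower Type I error than the
    percentile bootstrap on the same replications at a null cell."""
    cond = SimulationCondition(n=50, paths={"a": 0.0, "b": 0.0, "c_prime": 0.14})
    t = run_interval_study([cond], reps=200, B=500, seed=6)
    by = t.set_index(["estimator", "method"])
    for m in ("ab_ps", "ab_fs"):
        assert (
            by.loc[(m, "bias_corrected"), "rate_excl_zero"]
            >= by.loc[(m, "percentile"), "rate_excl_zero"]
        )


def test_bayes_study_smoke_and_summary_columns():
    conds = bayes_study_conditions("single", "continuous")[:1]
    t = run_bayes_study(conds, reps=2, seed=7, n_iter=300, burn_in=100)
    assert len(t) == 4
    for col in ("relative_bias_mean", "relative_bias_median", "coverage_equal_tail",
                "coverage_hpd", "width_hpd"):
        assert col in t.columns
    assert (t["width_hpd"] <= t["width_equal_tail"] + 1e-12).all()


def test_posterior_median_less_biased_than_mean_for_ratio():
    """At a problematic n = 50 cell the posterior median of the ratio mediated
    has smaller relative bias magnitude than the posterior mean."""
    conds = [SimulationCondition(n=50, paths={"a": 0.14, "b": 0.59, "c_prime": 0.39})]
    t = run_bayes_study(conds, reps=30, seed=8, n_iter=1000, burn_in=200)
    row = t.set_index("estimator").loc["ratio"]
    assert abs(row["relative_bias_median"]) <= abs(row["relative_bias_mean"])


def test_grid_sizes():
    assert len(single_mediator_grid()) == 320
    assert len(two_mediator_grid()) == 256
    assert len(bayes_study_conditions("single")) == 17
    assert len(bayes_study_conditions("two")) == 21


def test_binary_small_n_regeneration_counted():
    # with n = 10 and p = 0.5 a constant-X draw happens ~0.2% of the time;
    # the study must regenerate rather than fail, and the table stays complete
    cond = SimulationCondition(n=10, paths=MEDIUM, x_type="binary")
    t = run_point_study([cond], reps=300, seed=9)
    assert (t["reps_used"] + t["reps_undefined"] == 300).all()
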