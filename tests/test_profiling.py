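"""Segment profiles and the global/pairwise statistical battery."""

import numpy as np
import pytest
from scipy import stats

from popsegment import (
    adjusted_alpha,
    cost_population_ratio,
    population_weighted_mean,
    profile_segments,
    run_test_battery,
    two_proportion_ztest,
    variable_test_plan,
)
from popsegment.profiling import ProfilingError

from conftest import make_cohort


def _profiled_cohort(rng, n=400):
    util = rng.integers(0, 6, size=(n, 7))
    return make_cohort(
        util,
        age=rng.normal(45, 15, n).clip(0),
        risk_score=rng.beta(2, 10, n),
        ltc_count=rng.poisson(1.5, n).astype(float),
        smoker=rng.integers(0, 2, n),
        deprived_q12=rng.integers(0, 2, n),
        frail_mod_severe=rng.integers(0, 2, n),
        cost_gbp=rng.gamma(2.0, 300.0, n),
    )


# ---------------------------- profiles ----------------------------

def test_segment_means_and_weighted_population_mean():
    cohort = make_cohort(np.zeros((4, 7), dtype=int) + np.arange(4)[:, None],
                         age=[30.0, 40.0, 50.0, 60.0])
    report = profile_segments(cohort, [1, 1, 2, 2])
    t = report.table
    assert t.loc[1, "age_mean"] == pytest.approx(35.0)
    assert t.loc[2, "age_mean"] == pytest.approx(55.0)
    assert t.loc["population", "age_mean"] == pytest.approx(45.0)
    assert t.loc[1, "n"] + t.loc[2, "n"] == cohort.n


def test_population_mean_is_weighted_mean_of_segment_means(rng):
    cohort = _profiled_cohort(rng)
    assignment = rng.integers(1, 5, cohort.n)
    report = profile_segments(cohort, assignment)
    seg = report.segments
    for var in ("age_mean", "gp_visits_mean", "risk_score_mean", "ltc_count_mean"):
        weighted = population_weighted_mean(seg["n"], seg[var])
        assert weighted == pytest.approx(
            report.table.loc["population", var], rel=1e-9)


def test_single_segment_row_equals_population_row(rng):
    cohort = _profiled_cohort(rng, n=50)
    report = profile_segments(cohort, np.ones(50, dtype=int))
    seg_row = report.table.loc[1].drop(["population_share", "cost_population_ratio"])
    pop_row = report.table.loc["population"].drop(
        ["population_share", "cost_population_ratio"])
    np.testing.assert_allclose(seg_row.to_numpy(float), pop_row.to_numpy(float))


def test_cost_shares_and_ratio(rng):
    cohort = _profiled_cohort(rng)
    assignment = rng.integers(1, 4, cohort.n)
    report = profile_segments(cohort, assignment)
    seg = report.segments
    assert seg["cost_share"].sum() == pytest.approx(1.0)
    for s in seg.index:
        assert seg.loc[s, "cost_population_ratio"] == pytest.approx(
            seg.loc[s, "cost_share"] / seg.loc[s, "population_share"])


def test_cost_population_ratio_hand_example():
    # 10% of cost on 1% of people -> ratio 10
    assert cost_population_ratio(0.10, 0.01) == pytest.approx(10.0)


def test_unassigned_patients_are_an_error(rng):
    cohort = _profiled_cohort(rng, n=10)
    with pytest.raises(ProfilingError):
        profile_segments(cohort, np.ones(5, dtype=int))   # assignment too short


def test_missing_profiling_values_pairwise_deleted(rng):
    cohort = _profiled_cohort(rng, n=60)
    cohort.df.loc[:9, "age"] = np.nan
    report = profile_segments(cohort, np.ones(60, dtype=int))
    expected = cohort.df["age"].dropna().mean()
    assert report.table.loc[1, "age_mean"] == pytest.approx(expected)


# ---------------------------- test plan ----------------------------

@pytest.mark.parametrize("var,expected", [
    ("gp_visits", ("kruskal-wallis", "mann-whitney")),
    ("ltc_count", ("kruskal-wallis", "mann-whitney")),
    ("age", ("anova", "t-test")),
    ("risk_score", ("anova", "t-test")),
    ("smoker", ("chi-square", "z-test")),
    ("ltc_asthma", ("chi-square", "z-test")),
])
def test_variable_test_plan(var, expected):
    assert variable_test_plan(var) == expected


def test_unknown_variable_rejected():
    with pytest.raises(ProfilingError):
        variable_test_plan("shoe_size")


# ---------------------------- battery ----------------------------

def test_adjusted_alpha_matches_published_level():
    assert round(adjusted_alpha(0.05, 10), 4) == 0.0056


def test_identical_multisets_give_zero_kruskal_statistic(rng):
    cohort = make_cohort(np.tile([[0, 1, 2, 0, 1, 2]], (7, 1)).T)
    battery = run_test_battery(cohort, [1, 1, 1, 2, 2, 2], alpha=0.05)
    row = battery.global_tests.set_index("variable").loc["gp_visits"]
    assert row["statistic"] == pytest.approx(0.0, abs=1e-9)
    assert row["p"] > 0.05


def test_two_proportion_z_matches_brute_force_and_chi_square():
    x1, n1, x2, n2 = 20, 100, 40, 100
    z, p = two_proportion_ztest(x1, n1, x2, n2)
    pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z_hand = (x1 / n1 - x2 / n2) / se
    assert z == pytest.approx(z_hand, rel=1e-9)
    chi2 = stats.chi2_contingency(
        [[x1, n1 - x1], [x2, n2 - x2]], correction=False).statistic
    assert z ** 2 == pytest.approx(chi2, rel=1e-9)
    assert p == pytest.approx(2 * stats.norm.sf(abs(z_hand)), rel=1e-9)


def test_pairwise_symmetry_and_flags(rng):
    cohort = _profiled_cohort(rng)
    assignment = rng.integers(1, 5, cohort.n)
    battery = run_test_battery(cohort, assignment, alpha=0.05)
    assert battery.adjusted_alpha == pytest.approx(0.05 / 3)
    for var in ("gp_visits", "age", "smoker"):
        for a in range(1, 5):
            for b in range(a + 1, 5):
                assert battery.pairwise_p(var, a, b) == battery.pairwise_p(var, b, a)
    assert (battery.annotations["differs_from"] <= battery.k - 1).all()


def test_small_segment_pairwise_reported_missing(rng):
    cohort = _profiled_cohort(rng, n=41)
    assignment = np.r_[np.ones(40, int), [2]]          # segment 2 has n=1
    battery = run_test_battery(cohort, assignment, alpha=0.05)
    p = battery.pairwise_p("age", 1, 2)
    assert np.isnan(p)


def test_planted_difference_is_detected(rng):
    n = 300
    util = rng.integers(0, 4, size=(n, 7))
    assignment = np.r_[np.ones(n // 2, int), np.full(n - n // 2, 2, int)]
    util[assignment == 2, 4] += 6                      # strong gp_visits shift
    cohort = make_cohort(util, age=rng.normal(45, 10, n))
    battery = run_test_battery(cohort, assignment, alpha=0.05)
    row = battery.global_tests.set_index("variable").loc["gp_visits"]
    assert row["p"] < 1e-6
    assert battery.pairwise_p("gp_visits", 1, 2) < 1e-6
    ann = battery.annotations.set_index(["variable", "segment"])
    assert ann.loc[("gp_visits", 1), "differs_from"] == 1
    assert ann.loc[("gp_visits", 1), "tier"] == "x"    # differs from all others
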