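"""Per-segment descriptive profiles and the multi-group test battery.

Profiles summarise each segment (and the whole population) on the
utilisation variables, demographics, morbidity, frailty, bed days and
cost, including each segment's share of total cost and its
cost-to-population ratio (cost share / population share).

The statistical battery follows the variable-type plan:

=================================  ============  ==================
variable class                     global test   pairwise test
=================================  ============  ==================
utilisation counts, LTC count      Kruskal-Wallis  Mann-Whitney U
age, emergency-admission risk      one-way ANOVA   t-test (Welch)
boolean proportions (incl. LTCs)   chi-square      two-proportion z
=================================  ============  ==================

Pairwise tests are two-sided and flagged at the Bonferroni-adjusted
level alpha/(k-1) — each segment is compared against the k-1 others, so
at k = 10 and alpha = 0.05 the adjusted level is 0.05/9 = 0.0056.  For
each variable and segment the report counts how many other segments
differ significantly and assigns the conventional annotation tier
(x: all k-1 others, y: k-2, z: k-3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .cohort import BOOL_COLS, CohortTable, UTIL_COLS


class ProfilingError(Exception):
    pass


RANK_VARS = UTIL_COLS + ("ltc_count",)
NORMAL_VARS = ("age", "risk_score")
MEAN_SD_VARS = RANK_VARS + NORMAL_VARS
BED_VARS = ("bed_days_elective", "bed_days_nonelective", "bed_days_maternity")


def adjusted_alpha(alpha: float, k: int, divisor: int | None = None) -> float:
    """Bonferroni-adjusted pairwise level: alpha / (k - 1) by default.

    The divisor counts comparisons of one segment against each other
    segment (not the unordered pairs); it can be overridden.
    """
    d = divisor if divisor is not None else k - 1
    if d < 1:
        raise ProfilingError("Bonferroni divisor must be >= 1")
    return alpha / d


def population_weighted_mean(ns, means) -> float:
    """Population mean reconstructed from segment sizes and segment means."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    return float((ns * means).sum() / ns.sum())


def cost_population_ratio(cost_share: float, population_share: float) -> float:
    """Segment cost share divided by its population share (>1: disproportionate)."""
    if population_share <= 0:
        raise ProfilingError("population share must be positive")
    return cost_share / population_share


def variable_test_plan(variable: str) -> tuple[str, str]:
    """(global test, pairwise test) for a schema variable."""
    if variable in RANK_VARS:
        return ("kruskal-wallis", "mann-whitney")
    if variable in NORMAL_VARS:
        return ("anova", "t-test")
    if variable in BOOL_COLS:
        return ("chi-square", "z-test")
    raise ProfilingError(f"no test plan for variable {variable!r}")


# --------------------------------------------------------------------------
# Descriptive profiles
# --------------------------------------------------------------------------

@dataclass
class SegmentProfileReport:
    """Per-segment summary table plus a population row.

    ``table`` is indexed by segment id (plus a ``"population"`` row) with
    columns ``n``, ``population_share``, ``<var>_mean`` / ``<var>_sd`` for
    the mean-type variables, ``<flag>_prop`` for booleans,
    ``bed_days_*_mean``, ``cost_total``, ``cost_per_head``, ``cost_share``
    and ``cost_population_ratio``.
    """

    table: pd.DataFrame

    @property
    def segments(self) -> pd.DataFrame:
        return self.table.drop(index="population")


def profile_segments(cohort: CohortTable, assignment) -> SegmentProfileReport:
    """Summarise each segment and the whole cohort.

    Means/SDs are sample statistics (SD denominator n-1); proportions are
    computed over non-missing values (pairwise deletion).  An empty
    segment is an error.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != cohort.n:
        raise ProfilingError("every patient must be assigned a segment")
    df = cohort.df
    seg_ids = np.unique(assignment)

    def summarise(sub: pd.DataFrame) -> dict:
        out: dict[str, float] = {"n": len(sub)}
        for var in MEAN_SD_VARS:
            if var in sub.columns:
                vals = sub[var].dropna()
                out[f"{var}_mean"] = float(vals.mean()) if len(vals) else np.nan
                out[f"{var}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        for var in BOOL_COLS:
            if var in sub.columns:
                vals = sub[var].dropna()
                out[f"{var}_prop"] = float(vals.mean()) if len(vals) else np.nan
        for var in BED_VARS:
            if var in sub.columns:
                vals = sub[var].dropna()
                out[f"{var}_mean"] = float(vals.mean()) if len(vals) else np.nan
        if "cost_gbp" in sub.columns:
            out["cost_total"] = float(sub["cost_gbp"].sum())
        return out

    rows = {}
    for seg in seg_ids:
        sub = df[assignment == seg]
        if len(sub) == 0:
            raise ProfilingError(f"empty segment {seg}")
        rows[int(seg)] = summarise(sub)
    rows["population"] = summarise(df)

    table = pd.DataFrame.from_dict(rows, orient="index")
    table["population_share"] = table["n"] / cohort.n
    table.loc["population", "population_share"] = 1.0
    if "cost_total" in table.columns:
        total_cost = table.loc["population", "cost_total"]
        table["cost_per_head"] = table["cost_total"] / table["n"]
        if total_cost > 0:
            table["cost_share"] = table["cost_total"] / total_cost
            table["cost_population_ratio"] = (
                table["cost_share"] / table["population_share"])
    return SegmentProfileReport(table=table)


# --------------------------------------------------------------------------
# Test battery
# --------------------------------------------------------------------------

@dataclass
class TestBatteryReport:
    """Global and Bonferroni-adjusted pairwise test results.

    ``global_tests``: one row per variable (test, statistic, p).
    ``pairwise``: one row per (variable, segment a, segment b) with the
    test, statistic, p-value and significance flag at ``adjusted_alpha``;
    stored for a < b but symmetric by construction.
    ``annotations``: per (variable, segment) the number of other segments
    that differ significantly and the x/y/z annotation tier.
    """

    global_tests: pd.DataFrame
    pairwise: pd.DataFrame
    annotations: pd.DataFrame
    alpha: float
    adjusted_alpha: float
    k: int

    def pairwise_p(self, variable: str, a: int, b: int) -> float:
        if a == b:
            raise ProfilingError("pairwise test needs two distinct segments")
        lo, hi = min(a, b), max(a, b)
        sel = self.pairwise[(self.pairwise["variable"] == variable)
                            & (self.pairwise["segment_a"] == lo)
                            & (self.pairwise["segment_b"] == hi)]
        if sel.empty:
            raise ProfilingError(f"no pairwise test for {variable!r} {a} vs {b}")
        return float(sel["p"].iloc[0])


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided pooled-variance two-proportion z-test (no continuity corr.)."""
    stat, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(stat), float(p)


def _battery_variables(df: pd.DataFrame) -> list[str]:
    cols = [v for v in RANK_VARS if v in df.columns]
    cols += [v for v in NORMAL_VARS if v in df.columns]
    cols += [v for v in BOOL_COLS if v in df.columns]
    return cols


def run_test_battery(cohort: CohortTable, assignment, alpha: float = 0.05,
                     welch: bool = True,
                     bonferroni_divisor: int | None = None) -> TestBatteryReport:
    """Run the full global + pairwise battery over all profiled variables.

    Mann-Whitney uses the tie-corrected large-sample normal approximation
    without continuity correction; the pairwise t-test is Welch by
    default (``welch=False`` for pooled variance); the global chi-square
    is the k x 2 contingency test without continuity correction.  A
    segment with fewer than 2 usable observations on a continuous
    variable leaves its pairwise tests missing (NaN).
    """
    assignment = np.asarray(assignment)
    df = cohort.df
    seg_ids = [int(s) for s in np.unique(assignment)]
    k = len(seg_ids)
    if k < 2:
        raise ProfilingError("test battery needs at least 2 segments")
    adj = adjusted_alpha(alpha, k, bonferroni_divisor)
    variables = _battery_variables(df)

    glob_rows, pair_rows = [], []
    for var in variables:
        g_test, p_test = variable_test_plan(var)
        groups = {s: df.loc[assignment == s, var].dropna().to_numpy(dtype=float)
                  for s in seg_ids}

        # global test
        stat, p = np.nan, np.nan
        try:
            if g_test == "kruskal-wallis":
                stat, p = stats.kruskal(*groups.values())
            elif g_test == "anova":
                stat, p = stats.f_oneway(*groups.values())
            else:  # chi-square on the k x 2 table of flag counts
                table = np.array([[g.sum(), len(g) - g.sum()]
                                  for g in groups.values()])
                if (table.sum(axis=0) > 0).all():
                    res = stats.chi2_contingency(table, correction=False)
                    stat, p = res.statistic, res.pvalue
        except ValueError:
            pass
        glob_rows.append({"variable": var, "test": g_test,
                          "statistic": float(stat), "p": float(p)})

        # pairwise tests
        for a, b in itertools.combinations(seg_ids, 2):
            ga, gb = groups[a], groups[b]
            s_ab, p_ab = np.nan, np.nan
            if p_test == "mann-whitney":
                if len(ga) >= 2 and len(gb) >= 2:
                    s_ab, p_ab = stats.mannwhitneyu(
                        ga, gb, alternative="two-sided", method="asymptotic",
                        use_continuity=False)
            elif p_test == "t-test":
                if len(ga) >= 2 and len(gb) >= 2:
                    s_ab, p_ab = stats.ttest_ind(ga, gb, equal_var=not welch)
            else:  # z-test on proportions
                if len(ga) >= 1 and len(gb) >= 1:
                    x1, x2 = int(ga.sum()), int(gb.sum())
                    if 0 < x1 + x2 < len(ga) + len(gb):
                        s_ab, p_ab = two_proportion_ztest(x1, len(ga), x2, len(gb))
                    elif x1 + x2 in (0, len(ga) + len(gb)):
                        s_ab, p_ab = 0.0, 1.0  # identical degenerate proportions
            sig = bool(np.isfinite(p_ab) and p_ab < adj)
            pair_rows.append({"variable": var, "test": p_test,
                              "segment_a": a, "segment_b": b,
                              "statistic": float(s_ab), "p": float(p_ab),
                              "significant": sig})

    pairwise = pd.DataFrame(pair_rows)
    ann_rows = []
    for var in variables:
        sub = pairwise[pairwise["variable"] == var]
        for s in seg_ids:
            mask = (sub["segment_a"] == s) | (sub["segment_b"] == s)
            differs = int(sub.loc[mask, "significant"].sum())
            tier = {k - 1: "x", k - 2: "y", k - 3: "z"}.get(differs, "")
            ann_rows.append({"variable": var, "segment": s,
                             "differs_from": differs, "tier": tier})

    return TestBatteryReport(
        global_tests=pd.DataFrame(glob_rows),
        pairwise=pairwise,
        annotations=pd.DataFrame(ann_rows),
        alpha=alpha, adjusted_alpha=adj, k=k)
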