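"""Seeded synthetic cohorts with planted segment structure.

The study data (a linked primary/secondary-care extract for ~80,000
GP-registered patients in the South Wales Valleys) are not publicly
deposited, so this module generates cohorts with the same shape: a finite
mixture of utilisation segments with zero-inflated, overdispersed annual
counts, a dominant (~50%) low-utilisation segment, rare (~1%) very-high
utilisation segments, and segment-specific demographic, morbidity, risk
and cost distributions.  The default mixture is parameterised directly
from the published per-segment summary table (``REFERENCE_SEGMENTS``),
so every downstream stage is testable without any data download.

Only first moments (and, via the negative-binomial dispersion, a crude
second moment) are matched; the generator makes no attempt to reproduce
printed SDs exactly, condition co-occurrence, or the study's cost
attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    BOOL_COLS,
    CohortTable,
    ID_COL,
    LTC_CONDITIONS,
    SEX_COL,
    TRUTH_COL,
    UTIL_COLS,
    validate_cohort,
)


class ParameterError(ValueError):
    """A generator parameter is infeasible (e.g. beta moment matching)."""


# --------------------------------------------------------------------------
# Published per-segment summary table
# --------------------------------------------------------------------------
# One row per segment, population row separate.  Utilisation means are in
# canonical UTIL_COLS order: non-elective admissions, elective admissions,
# outpatient first, outpatient follow-up, GP visits, distinct drugs, A&E.

_SEGMENT_ROWS = [
    # n, util means (7), age (m, sd), deprived %, smoker %, risk (m, sd),
    # ltc mean, frailty %, bed days (elective, non-elective, maternity),
    # total cost GBP millions, published characterisation
    (39821, (0.01, 0.00, 0.00, 0.14, 0.11, 1.78, 0.00), (36.2, 21.5), 84.2, 20.3,
     (0.07, 0.05), 0.58, 0.4, (0.00, 0.00, 0.01), 3.2, "Low Need, Low Complex"),
    (4720, (0.17, 1.22, 0.87, 2.02, 1.34, 8.11, 0.48), (53.6, 20.5), 85.7, 23.1,
     (0.27, 0.13), 2.55, 12.9, (0.64, 0.35, 0.01), 10.0, "High Need, Low Complex"),
    (4274, (1.27, 0.03, 0.39, 1.17, 1.30, 6.65, 1.52), (38.2, 27.9), 87.6, 22.3,
     (0.23, 0.14), 2.08, 9.5, (0.02, 3.21, 0.04), 8.7, "Low Need, Low Complex"),
    (739, (3.27, 0.36, 1.79, 4.22, 4.94, 15.90, 5.13), (47.5, 27.3), 88.6, 27.2,
     (0.45, 0.19), 5.27, 28.3, (0.21, 1.10, 0.14), 5.1, "High Need, High Complex"),
    (8899, (0.02, 0.00, 1.23, 1.17, 0.93, 4.31, 0.28), (42.9, 23.0), 85.0, 22.1,
     (0.20, 0.10), 1.22, 4.0, (0.00, 0.07, 0.05), 4.2, "Low Need, Low Complex"),
    (2950, (0.34, 0.14, 1.89, 3.66, 4.60, 15.00, 1.13), (59.3, 21.4), 85.2, 22.1,
     (0.38, 0.15), 3.75, 32.3, (0.10, 2.00, 0.01), 6.4, "High Need, High Complex"),
    (851, (0.35, 0.10, 1.26, 20.53, 1.55, 8.28, 0.69), (42.1, 20.3), 86.5, 28.0,
     (0.36, 0.16), 2.31, 11.8, (0.07, 1.76, 1.26), 2.0, "High Need, Low Complex"),
    (8836, (0.02, 0.00, 0.17, 0.79, 0.71, 12.35, 0.14), (60.4, 18.5), 86.1, 25.9,
     (0.24, 0.12), 2.89, 20.9, (0.00, 0.06, 0.01), 6.8, "Low Need, Low Complex"),
    (423, (1.25, 0.14, 0.92, 2.26, 7.55, 20.64, 2.04), (82.1, 11.1), 78.5, 12.8,
     (0.50, 0.17), 6.46, 66.0, (0.46, 11.90, 0.00), 2.3, "High Need, High Complex"),
    (8094, (0.00, 0.00, 0.09, 0.26, 0.81, 2.61, 1.46), (29.8, 20.0), 85.6, 20.6,
     (0.12, 0.08), 0.64, 1.0, (0.00, 0.00, 0.01), 2.3, "Low Need, Low Complex"),
]

# Per-condition prevalence (%) by segment, rows in LTC_CONDITIONS order.
_LTC_PREVALENCE_PCT = {
    "armd":                    (0.2, 1.6, 0.9, 1.9, 0.7, 2.8, 2.2, 1.9, 9.0, 0.2),
    "arthritis":               (0.2, 1.2, 1.2, 2.6, 0.8, 5.0, 1.2, 2.4, 5.7, 0.3),
    "asthma":                  (7.1, 15.7, 13.6, 24.6, 10.3, 21.3, 16.2, 21.9, 11.8, 9.6),
    "bipolar_disorder":        (0.1, 0.4, 0.5, 2.7, 0.4, 1.3, 2.5, 0.8, 1.4, 0.1),
    "chf":                     (0.1, 1.8, 2.1, 8.4, 0.5, 4.8, 2.2, 2.6, 14.9, 0.1),
    "copd":                    (0.7, 7.1, 6.3, 20.6, 2.0, 12.9, 6.5, 12.2, 30.7, 0.5),
    "crf":                     (1.1, 6.7, 5.7, 15.7, 3.2, 13.1, 5.6, 10.8, 31.0, 0.8),
    "depression":              (6.8, 15.4, 13.5, 28.7, 11.9, 17.7, 17.2, 16.8, 22.0, 8.5),
    "diabetes":                (2.1, 11.7, 8.2, 21.7, 5.3, 25.4, 13.3, 24.9, 24.8, 1.9),
    "glaucoma":                (0.5, 3.4, 1.5, 2.8, 1.3, 4.5, 2.0, 3.2, 9.5, 0.3),
    "hypertension":            (9.5, 33.4, 22.8, 39.2, 17.8, 46.6, 21.0, 49.5, 68.1, 7.2),
    "hyperthyroidism":         (1.8, 7.4, 4.9, 11.1, 4.1, 11.7, 5.2, 11.5, 17.5, 1.6),
    "ischaemic_heart_disease": (0.6, 7.6, 6.8, 19.8, 2.6, 17.5, 5.1, 11.7, 30.0, 0.8),
    "low_back_pain":           (1.1, 5.1, 3.6, 8.8, 2.2, 5.8, 2.8, 4.4, 5.4, 2.0),
    "osteoporosis":            (0.0, 0.8, 1.4, 5.8, 0.3, 2.1, 0.7, 0.4, 7.1, 0.0),
    "parkinsons":              (0.0, 0.1, 0.4, 1.1, 0.3, 1.1, 0.2, 0.5, 5.0, 0.0),
    "schizophrenia":           (0.4, 0.8, 1.6, 4.6, 0.9, 2.3, 10.7, 1.3, 4.5, 0.3),
    "seizure_disorder":        (0.8, 2.1, 4.0, 10.4, 1.2, 3.4, 2.2, 3.0, 4.7, 1.3),
}

#: Study population size.
REFERENCE_POPULATION_N = 79_607

#: Whole-population utilisation means in UTIL_COLS order.
REFERENCE_POPULATION_UTIL_MEANS = (0.14, 0.08, 0.34, 0.91, 0.74, 4.75, 0.41)


def _build_reference_table() -> pd.DataFrame:
    rows = []
    for i, (n, util, age, depr, smok, risk, ltc_mean, frail, beds, cost,
            label) in enumerate(_SEGMENT_ROWS, start=1):
        row = {"segment": i, "n": n,
               "age_mean": age[0], "age_sd": age[1],
               "deprived_pct": depr, "smoker_pct": smok,
               "risk_mean": risk[0], "risk_sd": risk[1],
               "ltc_count_mean": ltc_mean, "frail_pct": frail,
               "bed_days_elective": beds[0], "bed_days_nonelective": beds[1],
               "bed_days_maternity": beds[2],
               "total_cost_gbp_m": cost, "characterisation": label}
        for col, m in zip(UTIL_COLS, util):
            row[f"{col}_mean"] = m
        for cond in LTC_CONDITIONS:
            row[f"ltc_{cond}_pct"] = _LTC_PREVALENCE_PCT[cond][i - 1]
        rows.append(row)
    return pd.DataFrame(rows).set_index("segment")


#: Published per-segment summary table used to parameterise the default
#: generator and for worked-example arithmetic.
REFERENCE_SEGMENTS: pd.DataFrame = _build_reference_table()


# --------------------------------------------------------------------------
# Generator configuration
# --------------------------------------------------------------------------

#: Invented but plausible unit prices (GBP per unit of activity) used to
#: synthesise annual cost; configurable, and deliberately not calibrated
#: to reproduce the published per-head costs.
DEFAULT_UNIT_PRICES = (2000.0, 1500.0, 200.0, 150.0, 30.0, 80.0, 160.0)


@dataclass
class SegmentSpec:
    """Distributional parameters of one mixture component.

    Counts are negative-binomial with the given mean and dispersion
    (variance = m + m^2 / dispersion), degenerate at zero when the mean is
    zero.  Age is normal truncated to [0, 105]; flags are Bernoulli; the
    emergency-admission risk score is beta with matched moments; cost is
    unit price x activity plus half-normal noise.
    """

    weight: float
    util_means: tuple[float, ...]
    util_dispersion: float = 1.0
    age_mean: float = 40.0
    age_sd: float = 20.0
    smoker_p: float = 0.2
    deprived_p: float = 0.5
    frail_p: float = 0.05
    ltc_prevalence: dict[str, float] = field(default_factory=dict)
    ltc_count_mean: float = 1.0
    risk_mean: float = 0.15
    risk_sd: float = 0.10
    bed_day_means: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cost_unit_prices: tuple[float, ...] = DEFAULT_UNIT_PRICES
    cost_noise_sd: float = 50.0

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ParameterError("weight must be in [0, 1]")
        if len(self.util_means) != len(UTIL_COLS):
            raise ParameterError("util_means must have one entry per utilisation variable")
        if any(m < 0 for m in self.util_means):
            raise ParameterError("util_means must be non-negative")
        if self.util_dispersion <= 0:
            raise ParameterError("util_dispersion must be positive")
        for name in ("smoker_p", "deprived_p", "frail_p"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ParameterError(f"{name} must be a probability")
        for cond, p in self.ltc_prevalence.items():
            if not 0 <= p <= 1:
                raise ParameterError(f"ltc_prevalence[{cond!r}] must be a probability")


@dataclass
class GeneratorConfig:
    segments: list[SegmentSpec]
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if len(self.segments) < 1:
            raise ParameterError("at least one segment required")
        total = sum(s.weight for s in self.segments)
        if total <= 0:
            raise ParameterError("segment weights must sum to a positive value")
        # normalise so weights sum to 1 exactly
        for s in self.segments:
            s.weight = s.weight / total

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.segments])


def default_generator_config(n: int, seed: int = 0,
                             util_dispersion: float = 1.0) -> GeneratorConfig:
    """Mixture of ten segments parameterised from the published summaries.

    Segment weights are the published population counts divided by 79,607;
    utilisation, age, risk, morbidity and frailty parameters are the
    printed per-segment values.
    """
    segments = []
    for seg, row in REFERENCE_SEGMENTS.iterrows():
        segments.append(SegmentSpec(
            weight=row["n"] / REFERENCE_POPULATION_N,
            util_means=tuple(row[f"{c}_mean"] for c in UTIL_COLS),
            util_dispersion=util_dispersion,
            age_mean=row["age_mean"], age_sd=row["age_sd"],
            smoker_p=row["smoker_pct"] / 100.0,
            deprived_p=row["deprived_pct"] / 100.0,
            frail_p=row["frail_pct"] / 100.0,
            ltc_prevalence={c: row[f"ltc_{c}_pct"] / 100.0 for c in LTC_CONDITIONS},
            ltc_count_mean=row["ltc_count_mean"],
            risk_mean=row["risk_mean"], risk_sd=row["risk_sd"],
            bed_day_means=(row["bed_days_elective"], row["bed_days_nonelective"],
                           row["bed_days_maternity"]),
        ))
    return GeneratorConfig(segments=segments, n=n, seed=seed)


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------

def _neg_binomial(rng: np.random.Generator, mean: float, dispersion: float,
                  size: int) -> np.ndarray:
    """Negative-binomial counts with the given mean; degenerate at 0."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def _beta_moment_matched(rng: np.random.Generator, mean: float, sd: float,
                         size: int) -> np.ndarray:
    """Beta draws with the given mean and SD; ParameterError if infeasible."""
    var = sd * sd
    if var <= 0:
        return np.full(size, mean)
    if var >= mean * (1 - mean):
        raise ParameterError(
            f"risk_sd {sd} too large for mean {mean}: beta moment matching infeasible")
    nu = mean * (1 - mean) / var - 1.0
    a, b = mean * nu, (1 - mean) * nu
    return np.clip(rng.beta(a, b, size=size), 0.0, 1.0)


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a cohort from the mixture; bit-identical for identical configs.

    The true mixture component of each patient is emitted in a
    ``true_segment`` column (1-based, in config order) so recovery tests
    can compare recovered and planted partitions; segmentation itself only
    ever reads the seven utilisation columns.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    labels = rng.choice(len(config.segments), size=n, p=config.weights)

    df = pd.DataFrame({ID_COL: [f"p{i:07d}" for i in range(n)]})
    df[TRUTH_COL] = labels + 1
    for col in UTIL_COLS:
        df[col] = np.zeros(n, dtype=np.int64)
    for col in ("age", "risk_score", "ltc_count", "cost_gbp",
                "bed_days_elective", "bed_days_nonelective", "bed_days_maternity"):
        df[col] = np.zeros(n, dtype=float)
    for col in BOOL_COLS:
        df[col] = np.zeros(n, dtype=np.int64)
    df[SEX_COL] = np.where(rng.random(n) < 0.501, "F", "M")

    bed_cols = ("bed_days_elective", "bed_days_nonelective", "bed_days_maternity")
    for si, spec in enumerate(config.segments):
        idx = np.flatnonzero(labels == si)
        m = idx.size
        if m == 0:
            continue
        counts = np.column_stack([
            _neg_binomial(rng, mu, spec.util_dispersion, m) for mu in spec.util_means])
        for j, col in enumerate(UTIL_COLS):
            df.loc[idx, col] = counts[:, j]
        lo, hi = (0 - spec.age_mean) / spec.age_sd, (105 - spec.age_mean) / spec.age_sd
        df.loc[idx, "age"] = stats.truncnorm.rvs(
            lo, hi, loc=spec.age_mean, scale=spec.age_sd, size=m, random_state=rng)
        df.loc[idx, "smoker"] = (rng.random(m) < spec.smoker_p).astype(np.int64)
        df.loc[idx, "deprived_q12"] = (rng.random(m) < spec.deprived_p).astype(np.int64)
        df.loc[idx, "frail_mod_severe"] = (rng.random(m) < spec.frail_p).astype(np.int64)
        for cond in LTC_CONDITIONS:
            p = spec.ltc_prevalence.get(cond, 0.0)
            df.loc[idx, f"ltc_{cond}"] = (rng.random(m) < p).astype(np.int64)
        df.loc[idx, "ltc_count"] = _neg_binomial(
            rng, spec.ltc_count_mean, spec.util_dispersion, m).astype(float)
        df.loc[idx, "risk_score"] = _beta_moment_matched(
            rng, spec.risk_mean, spec.risk_sd, m)
        for j, col in enumerate(bed_cols):
            df.loc[idx, col] = _neg_binomial(
                rng, spec.bed_day_means[j], spec.util_dispersion, m).astype(float)
        prices = np.asarray(spec.cost_unit_prices, dtype=float)
        noise = np.abs(rng.normal(0.0, spec.cost_noise_sd, size=m))
        df.loc[idx, "cost_gbp"] = counts @ prices + noise

    out = validate_cohort(df)
    assert out.n_dropped == 0
    return out


def generate_planted_gaussians(k: int, n: int, separation: float,
                               seed: int = 0) -> tuple[CohortTable, np.ndarray]:
    """k spherical clusters in the 7-dimensional utilisation space.

    Centroids are drawn with pairwise spacing at least ``separation``
    within-cluster SDs (unit within-cluster SD); values are shifted and
    rounded to non-negative integers so they are valid utilisation counts.
    Returns the cohort and the planted labels (1..k).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > 1 and separation <= 0:
        raise ParameterError("separation must be positive")
    rng = np.random.default_rng(seed)
    d = len(UTIL_COLS)
    for _ in range(1000):
        centroids = rng.normal(0.0, max(1.5 * separation, 1.0), size=(k, d))
        if k == 1:
            break
        dists = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
        if dists[np.triu_indices(k, 1)].min() >= separation:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise ParameterError("could not place centroids at requested separation")

    labels = rng.integers(0, k, size=n)
    x = centroids[labels] + rng.normal(0.0, 1.0, size=(n, d))
    x = np.maximum(np.round(x - x.min()), 0.0).astype(np.int64)

    df = pd.DataFrame({ID_COL: [f"p{i:07d}" for i in range(n)]})
    for j, col in enumerate(UTIL_COLS):
        df[col] = x[:, j]
    df[TRUTH_COL] = labels + 1
    return validate_cohort(df), labels + 1
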