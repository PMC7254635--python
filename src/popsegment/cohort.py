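"""Cohort schema, validation, file I/O and run configuration.

A cohort is one row per registered patient.  Seven annual utilisation
counts drive the clustering; the remaining columns (demographics,
long-term-condition flags, emergency-admission risk, cost, bed days)
are profiling attributes and may be absent or partially missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

#: The seven utilisation variables the segmentation is computed on, in
#: canonical order (one "care setting" each).
UTIL_COLS: tuple[str, ...] = (
    "nonelective_adm",
    "elective_adm",
    "op_first",
    "op_followup",
    "gp_visits",
    "distinct_drugs",
    "ae_attendances",
)

#: Long-term conditions carried as per-patient boolean flags (columns are
#: prefixed ``ltc_``).  The schema accepts extra ``ltc_`` columns beyond
#: this list so local condition sets can be extended.
LTC_CONDITIONS: tuple[str, ...] = (
    "armd",
    "arthritis",
    "asthma",
    "bipolar_disorder",
    "chf",
    "copd",
    "crf",
    "depression",
    "diabetes",
    "glaucoma",
    "hypertension",
    "hyperthyroidism",
    "ischaemic_heart_disease",
    "low_back_pain",
    "osteoporosis",
    "parkinsons",
    "schizophrenia",
    "seizure_disorder",
)

LTC_FLAG_COLS: tuple[str, ...] = tuple(f"ltc_{c}" for c in LTC_CONDITIONS)

#: Boolean profiling attributes (encoded 0/1 on disk and in memory).
BOOL_COLS: tuple[str, ...] = ("deprived_q12", "smoker", "frail_mod_severe") + LTC_FLAG_COLS

#: Continuous / count profiling attributes.
PROFILE_NUMERIC_COLS: tuple[str, ...] = (
    "age",
    "risk_score",
    "ltc_count",
    "cost_gbp",
    "bed_days_elective",
    "bed_days_nonelective",
    "bed_days_maternity",
)

ID_COL = "patient_id"
SEX_COL = "sex"
TRUTH_COL = "true_segment"  # emitted by the synthetic generator only

REQUIRED_COLS: tuple[str, ...] = (ID_COL,) + UTIL_COLS


class CohortError(Exception):
    """Base class for cohort-level failures."""


class SchemaError(CohortError):
    """A required column is missing or mis-typed."""


class ValidationError(CohortError):
    """A record violates a schema invariant."""


class ConfigError(CohortError):
    """A run-configuration value is out of range."""


@dataclass
class CohortTable:
    """A validated patient-level cohort.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per patient.  Contains at least ``patient_id`` and the
        seven utilisation columns; utilisation values are non-negative
        integers with no missing entries.
    n_dropped : int
        Records discarded during non-strict reading (0 otherwise).
    """

    df: pd.DataFrame
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.df)

    def utilisation(self) -> np.ndarray:
        """The n x 7 utilisation count matrix in canonical column order."""
        return self.df.loc[:, list(UTIL_COLS)].to_numpy(dtype=float)


def validate_cohort(df: pd.DataFrame, strict: bool = True) -> CohortTable:
    """Validate a raw cohort frame against the schema.

    Utilisation columns must be complete non-negative integers: clustering
    distance is undefined on missing coordinates, so offending records are
    fatal in strict mode and dropped (with a count) otherwise.  Profiling
    columns may contain missing values; they are range-checked only where
    present.
    """
    for col in REQUIRED_COLS:
        if col not in df.columns:
            raise SchemaError(f"required column missing: {col!r}")
    df = df.copy()

    if df[ID_COL].duplicated().any():
        dup = df[ID_COL][df[ID_COL].duplicated()].iloc[0]
        raise ValidationError(f"duplicate patient_id: {dup!r}")

    bad = pd.Series(False, index=df.index)
    for col in UTIL_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        missing = vals.isna()
        negative = vals < 0
        noninteger = ~missing & (vals != np.floor(vals))
        col_bad = missing | negative | noninteger
        if strict and col_bad.any():
            row = int(np.flatnonzero(col_bad.to_numpy())[0])
            if missing.iloc[np.flatnonzero(col_bad.to_numpy())[0]]:
                raise ValidationError(f"missing value in {col!r} at row {row}")
            if bool(negative.fillna(False).iloc[np.flatnonzero(col_bad.to_numpy())[0]]):
                raise ValidationError(f"negative count in {col!r} at row {row}")
            raise ValidationError(f"non-integer count in {col!r} at row {row}")
        bad |= col_bad.fillna(True)
        df[col] = vals

    if bad.any():
        df = df.loc[~bad]
    n_dropped = int(bad.sum())
    df = df.reset_index(drop=True)
    for col in UTIL_COLS:
        df[col] = df[col].astype(np.int64)

    # profiling attributes: range checks where present, missing allowed
    if "age" in df.columns:
        age = pd.to_numeric(df["age"], errors="coerce")
        if (age.dropna() < 0).any():
            row = int(age.index[age < 0][0])
            raise ValidationError(f"negative age at row {row}")
        df["age"] = age
    if "risk_score" in df.columns:
        r = pd.to_numeric(df["risk_score"], errors="coerce")
        out = (r.dropna() < 0) | (r.dropna() > 1)
        if out.any():
            raise ValidationError("risk_score outside [0, 1]")
        df["risk_score"] = r
    for col in ("cost_gbp", "ltc_count", "bed_days_elective",
                "bed_days_nonelective", "bed_days_maternity"):
        if col in df.columns:
            v = pd.to_numeric(df[col], errors="coerce")
            if (v.dropna() < 0).any():
                raise ValidationError(f"negative value in {col!r}")
            df[col] = v
    for col in BOOL_COLS:
        if col in df.columns:
            v = pd.to_numeric(df[col], errors="coerce")
            ok = v.dropna().isin((0, 1)).all()
            if not ok:
                raise ValidationError(f"non-boolean value in {col!r} (expect 0/1)")
            df[col] = v

    return CohortTable(df=df, n_dropped=n_dropped)


def read_cohort(path: str | Path, strict: bool = True,
                aliases: Mapping[str, str] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path : str or Path
        Delimited text table with a header row naming at least
        ``patient_id`` and the seven utilisation columns.
    strict : bool
        If True (default), any missing, negative or non-integer
        utilisation value raises :class:`ValidationError`.  If False,
        offending records are dropped and counted in
        :attr:`CohortTable.n_dropped`.
    aliases : mapping, optional
        Maps file header names onto schema column names.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"cohort file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if aliases:
        df = df.rename(columns=dict(aliases))
    return validate_cohort(df, strict=strict)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a validated cohort to CSV (UTF-8, header row, booleans 0/1).

    ``read_cohort(write_cohort(x))`` reproduces the table field-for-field.
    """
    df = cohort.df.copy()
    for col in BOOL_COLS:
        if col in df.columns and df[col].notna().all():
            df[col] = df[col].astype(np.int64)
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class KMeansOptions:
    init: str = "k-means++"          # or "random"
    restarts: int = 10
    tol: float = 1e-6                # relative objective change
    max_iter: int = 300


@dataclass
class RunConfig:
    """Tunable parameters of the full segmentation run.

    Defaults follow the study design: 10 random subsets of 3,000 patients,
    candidate cluster counts 2-20, a final k of 10, Ward linkage, and the
    need/complexity rule thresholds (more than 100% above the population
    mean in any setting; more than 20% above in >= 4 settings; above the
    mean in >= 4 settings for complexity) with pairwise significance
    Bonferroni-adjusted from alpha = 0.05.
    """

    k_final: int = 10
    n_subsets: int = 10
    subset_size: int = 3000
    k_range: tuple[int, int] = (2, 20)
    seed: int = 0
    need_any_setting_ratio: float = 2.0
    need_multi_setting_ratio: float = 1.2
    need_multi_setting_min: int = 4
    complexity_ratio: float = 1.0
    complexity_min_settings: int = 4
    alpha: float = 0.05
    linkage: str = "ward"
    #: minimum fall in pseudo-T-squared from g-1 to g for the stopping rule
    #: to flag g as a candidate cluster count
    t2_drop_ratio: float = 3.0
    kmeans: KMeansOptions = field(default_factory=KMeansOptions)
    welch: bool = True               # Welch pairwise t-test (False: pooled)

    def __post_init__(self) -> None:
        if self.k_final < 1:
            raise ConfigError("k_final must be positive")
        if self.n_subsets < 1 or self.subset_size < 1:
            raise ConfigError("n_subsets and subset_size must be positive")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ConfigError("k_range lower bound must be >= 2 and <= upper bound")
        for name in ("need_any_setting_ratio", "need_multi_setting_ratio",
                     "complexity_ratio", "t2_drop_ratio"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.linkage not in ("ward", "average", "complete"):
            raise ConfigError(f"unsupported linkage: {self.linkage!r}")
        if self.kmeans.restarts < 1 or self.kmeans.max_iter < 1 or self.kmeans.tol < 0:
            raise ConfigError("invalid k-means options")


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, object] | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file.

    Unspecified keys take the defaults; a ``kmeans:`` section maps onto
    :class:`KMeansOptions`.  ``overrides`` (e.g. CLI flags) win over file
    values.  Out-of-range values raise :class:`ConfigError`.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must be a mapping")
        data.update(raw)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "k_range" in data:
        kr = data["k_range"]
        if not (isinstance(kr, Sequence) and len(kr) == 2):
            raise ConfigError("k_range must be a [low, high] pair")
        data["k_range"] = (int(kr[0]), int(kr[1]))
    if "kmeans" in data:
        km = data["kmeans"]
        if not isinstance(km, Mapping):
            raise ConfigError("kmeans section must be a mapping")
        bad = set(km) - {f.name for f in dataclasses.fields(KMeansOptions)}
        if bad:
            raise ConfigError(f"unknown kmeans keys: {sorted(bad)}")
        data["kmeans"] = KMeansOptions(**km)
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
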