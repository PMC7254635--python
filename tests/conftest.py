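"""Shared fixtures and independent brute-force oracles.

The oracles here recompute sums of squares, pseudo-F values and optimal
k-means partitions from first principles (direct summation, exhaustive
enumeration) so they stay independent of the library code paths they
check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from popsegment import CohortTable, UTIL_COLS
from popsegment.cohort import ID_COL, validate_cohort


# --------------------------------------------------------------------------
# Brute-force oracles
# --------------------------------------------------------------------------

def brute_within_ss(points: np.ndarray, labels: np.ndarray) -> float:
    """Total within-group SS by direct per-point summation."""
    x = np.asarray(points, dtype=float)
    total = 0.0
    for lab in set(labels.tolist()):
        grp = x[labels == lab]
        mean = grp.sum(axis=0) / len(grp)
        for row in grp:
            total += float(((row - mean) ** 2).sum())
    return total


def brute_between_ss(points: np.ndarray, labels: np.ndarray) -> float:
    x = np.asarray(points, dtype=float)
    grand = x.sum(axis=0) / len(x)
    total = 0.0
    for lab in set(labels.tolist()):
        grp = x[labels == lab]
        mean = grp.sum(axis=0) / len(grp)
        total += len(grp) * float(((mean - grand) ** 2).sum())
    return total


def brute_pseudo_f(points: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    k = len(set(labels.tolist()))
    b = brute_between_ss(points, labels)
    w = brute_within_ss(points, labels)
    if b == 0:
        return 0.0
    if w == 0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def set_partitions(items: list[int], k: int):
    """All partitions of ``items`` into exactly k non-empty blocks."""
    if k == 1:
        yield [list(items)]
        return
    if len(items) == k:
        yield [[i] for i in items]
        return
    head, rest = items[0], items[1:]
    for part in set_partitions(rest, k):          # head joins an existing block
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
    for part in set_partitions(rest, k - 1):      # head is its own block
        yield [[head]] + part


def exhaustive_kmeans_optimum(points: np.ndarray, k: int) -> float:
    """Global minimum within-SS over all partitions into <= k blocks."""
    x = np.asarray(points, dtype=float)
    idx = list(range(len(x)))
    best = np.inf
    for kk in range(1, k + 1):
        for part in set_partitions(idx, kk):
            labels = np.empty(len(x), dtype=int)
            for j, block in enumerate(part):
                labels[block] = j
            best = min(best, brute_within_ss(x, labels))
    return best


def pair_agreement_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected pairwise partition agreement (adjusted Rand)."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

def make_cohort(util: np.ndarray, **extra_cols) -> CohortTable:
    """CohortTable straight from an n x 7 utilisation count matrix."""
    util = np.asarray(util)
    df = pd.DataFrame({ID_COL: [f"p{i:05d}" for i in range(len(util))]})
    for j, col in enumerate(UTIL_COLS):
        df[col] = util[:, j].astype(np.int64)
    for name, vals in extra_cols.items():
        df[name] = vals
    return validate_cohort(df)


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Three patients with hand-enterable utilisation and profiling values."""
    rng = np.random.default_rng(5)
    util = rng.integers(0, 5, size=(3, 7))
    return make_cohort(
        util,
        age=[30.0, 40.0, 50.0],
        sex=["F", "M", "F"],
        smoker=[0, 1, 0],
        deprived_q12=[1, 1, 0],
        risk_score=[0.1, 0.2, 0.3],
        ltc_count=[0.0, 2.0, 1.0],
        frail_mod_severe=[0, 0, 1],
        cost_gbp=[100.0, 250.0, 75.0],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
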