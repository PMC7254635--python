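"""Standardisation, cluster-number selection and k-means segmentation.

The method runs in three steps on the seven utilisation variables:

1. z-score standardisation (subtract the mean, divide by the sample SD)
   so every variable carries equal weight in the Euclidean distance;
2. agglomerative (Ward by default) clustering on random subsets, scoring
   each candidate cluster count with the Calinski-Harabasz pseudo-F and
   the Duda-Hart Je(2)/Je(1) index with its companion pseudo-T-squared,
   and pooling a consensus cluster count across subsets;
3. Lloyd's k-means with Euclidean distance on the full cohort at the
   chosen k, with segments renumbered by decreasing size.

The Duda-Hart record at g describes the split undone when moving from g
to g+1 groups: Je(1) is the within-SS of the parent cluster, Je(2) the
summed within-SS of its two children, and
pseudo-T2 = (Je(1) - Je(2)) / (Je(2) / (n1 + n2 - 2)).  A split beyond
the real structure barely reduces within-SS (index near 1, small T2); a
split that separates genuinely distinct groups slashes it (index near 0,
huge T2).  The stopping rule therefore looks for the sharp *fall* in
pseudo-T-squared: g is flagged when T2(g-1)/T2(g) >= ``t2_drop_ratio``
and the index rises at g, and each subset suggests the flagged g with the
largest fall (ties to the smallest g).  The consensus over subsets is the
median suggestion (ties resolved toward the modal suggestion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .cohort import CohortTable, RunConfig


class SegmentationError(Exception):
    pass


class SelectionError(SegmentationError):
    """No subset produced a usable cluster-count suggestion."""


def stage_rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    """Deterministic per-stage RNG.

    All randomness flows from one top-level seed through
    ``SeedSequence(seed).spawn``: stage 0 is cohort synthesis, stage 1 the
    k-selection subsets (one child per subset index), stage 2 k-means.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(stage + 1)
    return np.random.default_rng(children[stage].spawn(index + 1)[index])


# --------------------------------------------------------------------------
# Standardisation
# --------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-variable z-scoring (sample SD, denominator n-1)."""

    mu: np.ndarray
    sigma: np.ndarray
    columns: tuple[str, ...]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mu) / self.sigma

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sigma + self.mu


def fit_standardizer(cohort: CohortTable) -> Standardizer:
    """Fit per-variable means and sample SDs on the utilisation matrix.

    A zero-variance variable would receive infinite weight in the
    standardised distance, so it is an error and is named.
    """
    x = cohort.utilisation()
    if x.shape[0] < 2:
        raise SegmentationError("need at least 2 records to standardise")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    from .cohort import UTIL_COLS
    zero = np.flatnonzero(sigma == 0)
    if zero.size:
        raise SegmentationError(
            f"zero-variance utilisation variable: {UTIL_COLS[zero[0]]!r}")
    return Standardizer(mu=mu, sigma=sigma, columns=UTIL_COLS)


def transform(standardizer: Standardizer, cohort: CohortTable) -> np.ndarray:
    return standardizer.transform(cohort.utilisation())


# --------------------------------------------------------------------------
# Hierarchical tree with per-node within-group sums of squares
# --------------------------------------------------------------------------

@dataclass
class HierarchicalTree:
    """Agglomerative merge history over a point set.

    ``z`` is the merge matrix (one row per merge, children in columns 0-1);
    ``node_n`` / ``node_ss`` give, for every leaf and internal node, the
    member count and the within-group sum of squared Euclidean distances
    to the group mean.  Node ids follow the usual convention: leaves are
    0..n-1, the i-th merge creates node n+i.
    """

    z: np.ndarray
    n: int
    node_n: np.ndarray
    node_ss: np.ndarray
    linkage: str

    def cut(self, g: int) -> np.ndarray:
        """Partition into g groups (labels 1..g)."""
        if not 1 <= g <= self.n:
            raise SegmentationError(f"cannot cut {self.n} points into {g} groups")
        return fcluster(self.z, t=g, criterion="maxclust")

    def split_children(self, g: int) -> tuple[int, int]:
        """Node ids of the two children of the split undone at g -> g+1."""
        if not 1 <= g <= self.n - 1:
            raise SegmentationError(f"no split from {g} to {g + 1} groups")
        row = self.n - 1 - g
        return int(self.z[row, 0]), int(self.z[row, 1])


def build_tree(points: np.ndarray, linkage: str = "ward") -> HierarchicalTree:
    """Agglomerative clustering with per-node within-SS bookkeeping.

    For Ward linkage every merge minimises the increase in total
    within-group SS.  Whatever the linkage, node within-SS is computed
    exactly from running per-node sums and sums of squares.
    """
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise SegmentationError("need at least 2 points")
    z = scipy_linkage(x, method=linkage)

    node_n = np.zeros(2 * n - 1)
    node_sum = np.zeros((2 * n - 1, x.shape[1]))
    node_sq = np.zeros(2 * n - 1)
    node_n[:n] = 1.0
    node_sum[:n] = x
    node_sq[:n] = (x ** 2).sum(axis=1)
    node_ss = np.zeros(2 * n - 1)
    for i in range(n - 1):
        a, b = int(z[i, 0]), int(z[i, 1])
        j = n + i
        node_n[j] = node_n[a] + node_n[b]
        node_sum[j] = node_sum[a] + node_sum[b]
        node_sq[j] = node_sq[a] + node_sq[b]
        ss = node_sq[j] - (node_sum[j] ** 2).sum() / node_n[j]
        node_ss[j] = max(ss, 0.0)  # guard tiny negative round-off
    return HierarchicalTree(z=z, n=n, node_n=node_n, node_ss=node_ss,
                            linkage=linkage)


# --------------------------------------------------------------------------
# Stopping indices
# --------------------------------------------------------------------------

def _group_ss(points: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(within, between, total) sums of squares about group/grand means."""
    x = np.asarray(points, dtype=float)
    grand = x.mean(axis=0)
    total = float(((x - grand) ** 2).sum())
    within = 0.0
    for lab in np.unique(labels):
        grp = x[labels == lab]
        within += float(((grp - grp.mean(axis=0)) ** 2).sum())
    return within, total - within, total


def ch_pseudo_f(points: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz pseudo F: [B/(k-1)] / [W/(n-k)].

    B is the between-group SS about the grand mean, W the total
    within-group SS about group means; B + W equals the total SS.  W = 0
    (all groups internally identical) is reported as +inf.
    """
    labels = np.asarray(labels)
    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    k = uniq.size
    if not 2 <= k <= n - 1:
        raise SegmentationError(f"pseudo-F defined only for 2 <= k <= n-1, got k={k}")
    if (counts == 0).any():
        raise SegmentationError("empty group")
    within, between, _total = _group_ss(points, labels)
    if between <= 0:
        return 0.0
    if within == 0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


@dataclass
class DudaHartRecord:
    """Duda-Hart statistics for the split undone going from g to g+1 groups.

    ``dh_index`` is Je(2)/Je(1); ``pseudo_t2`` its companion.  Degenerate
    cases: Je(1) = 0 leaves the index undefined (NaN); Je(2) = 0 sends the
    pseudo-T-squared to +inf; n1 + n2 <= 2 leaves it undefined (NaN).
    """

    g: int
    je1: float
    je2: float
    dh_index: float
    pseudo_t2: float
    n1: int
    n2: int


def duda_hart(tree: HierarchicalTree, g: int) -> DudaHartRecord:
    a, b = tree.split_children(g)
    parent = tree.n + (tree.n - 1 - g)
    je1 = float(tree.node_ss[parent])
    je2 = float(tree.node_ss[a] + tree.node_ss[b])
    n1, n2 = int(tree.node_n[a]), int(tree.node_n[b])
    if je1 <= 0:
        dh = float("nan")
    else:
        dh = je2 / je1
    if n1 + n2 <= 2:
        t2 = float("nan")
    elif je2 <= 0:
        t2 = float("inf")
    else:
        t2 = (je1 - je2) / (je2 / (n1 + n2 - 2))
    return DudaHartRecord(g=g, je1=je1, je2=je2, dh_index=dh, pseudo_t2=t2,
                          n1=n1, n2=n2)


# --------------------------------------------------------------------------
# Cluster-number selection on random subsets
# --------------------------------------------------------------------------

@dataclass
class KSelectionTrace:
    """Full per-subset stopping-rule trace plus the consensus decision.

    ``table`` is tidy: one row per (subset, g) with the pseudo-F of the
    g-group hierarchical cut, the Duda-Hart index and pseudo-T-squared of
    the g -> g+1 split, the T2 drop ratio from g-1, and the candidate
    flag.  The trace is always emitted in full so a human can override
    the automated decision.
    """

    table: pd.DataFrame
    suggestions: list[int | None]
    chosen_k: int
    k_range: tuple[int, int]

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def _consensus(suggestions: list[int]) -> int:
    """Median of subset suggestions; a half-integer median resolves toward
    the modal suggestion (then toward the smaller candidate)."""
    arr = np.sort(np.asarray(suggestions))
    med = float(np.median(arr))
    if med == int(med):
        return int(med)
    lo, hi = int(np.floor(med)), int(np.ceil(med))
    counts = {v: int((arr == v).sum()) for v in (lo, hi)}
    if counts[lo] != counts[hi]:
        return lo if counts[lo] > counts[hi] else hi
    return lo


def select_k(cohort: CohortTable, config: RunConfig) -> KSelectionTrace:
    """Consensus cluster count from subsampled hierarchical clustering.

    Draws ``n_subsets`` random subsets of ``subset_size`` patients
    (without replacement within a subset; subsets independent), builds the
    hierarchical tree on the standardised utilisation matrix of each,
    records the Calinski-Harabasz pseudo-F and Duda-Hart statistics for
    every candidate count in ``k_range``, applies the T2-drop stopping
    rule per subset, and pools suggestions by median.  A subset with no
    flagged candidate abstains; if every subset abstains a
    :class:`SelectionError` advises choosing k manually.
    """
    if config.subset_size > cohort.n:
        raise SegmentationError("subset_size exceeds cohort size")
    std = fit_standardizer(cohort)
    z = transform(std, cohort)
    k_lo, k_hi = config.k_range

    rows = []
    suggestions: list[int | None] = []
    for s in range(config.n_subsets):
        rng = stage_rng(config.seed, stage=1, index=s)
        idx = rng.choice(cohort.n, size=config.subset_size, replace=False)
        tree = build_tree(z[idx], linkage=config.linkage)
        g_max = min(k_hi + 1, tree.n - 1)
        recs = {g: duda_hart(tree, g) for g in range(max(k_lo - 1, 1), g_max + 1)}

        best_g, best_ratio = None, 0.0
        for g in range(k_lo, k_hi + 1):
            rec = recs.get(g)
            prev = recs.get(g - 1)
            pf = ch_pseudo_f(z[idx], tree.cut(g)) if g <= tree.n - 1 else float("nan")
            ratio = float("nan")
            flagged = False
            if rec is not None and prev is not None:
                t2, t2p = rec.pseudo_t2, prev.pseudo_t2
                if np.isfinite(t2) and t2 > 0 and not np.isnan(t2p):
                    ratio = t2p / t2  # inf t2p -> inf ratio
                elif t2 == 0:
                    ratio = float("inf")
                dh_rises = (not np.isnan(rec.dh_index) and not np.isnan(prev.dh_index)
                            and rec.dh_index > prev.dh_index)
                flagged = bool(ratio >= config.t2_drop_ratio and dh_rises)
                if flagged and ratio > best_ratio:
                    best_g, best_ratio = g, ratio
            rows.append({
                "subset": s, "g": g, "pseudo_f": pf,
                "dh_index": rec.dh_index if rec else float("nan"),
                "pseudo_t2": rec.pseudo_t2 if rec else float("nan"),
                "t2_drop_ratio": ratio, "flagged": flagged,
            })
        suggestions.append(best_g)

    usable = [s for s in suggestions if s is not None]
    if not usable:
        raise SelectionError(
            "no subset flagged a candidate cluster count; inspect the trace "
            "and choose k manually")
    chosen = _consensus(usable)
    return KSelectionTrace(table=pd.DataFrame(rows), suggestions=suggestions,
                           chosen_k=chosen, k_range=config.k_range)


# --------------------------------------------------------------------------
# k-means (Lloyd's algorithm)
# --------------------------------------------------------------------------

@dataclass
class SegmentModel:
    """Fitted k-means model in the standardised utilisation space."""

    k: int
    centroids: np.ndarray
    assignment: np.ndarray          # segment ids 1..k
    objective: float                # total within-cluster SS
    iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    d2 = ((x - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = x[rng.integers(n)]
            continue
        centroids[j] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((x - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _assign(x: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels (ties -> lowest centroid index) and distances."""
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return labels, d2[np.arange(len(x)), labels]


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator, init: str,
           tol: float, max_iter: int) -> SegmentModel:
    n = x.shape[0]
    if init == "k-means++":
        centroids = _kmeans_pp_init(x, k, rng)
    elif init == "random":
        centroids = x[rng.choice(n, size=k, replace=False)]
    else:
        raise SegmentationError(f"unknown k-means init: {init!r}")

    prev_obj = np.inf
    trace: list[float] = []
    converged = False
    labels = np.zeros(n, dtype=int)
    for it in range(1, max_iter + 1):
        labels, d2 = _assign(x, centroids)
        # empty cluster: re-seed with the point farthest from its centroid
        for j in range(k):
            if not (labels == j).any():
                far = int(d2.argmax())
                centroids[j] = x[far]
                labels, d2 = _assign(x, centroids)
        obj = float(d2.sum())
        trace.append(obj)
        for j in range(k):
            centroids[j] = x[labels == j].mean(axis=0)
        if prev_obj < np.inf:
            denom = prev_obj if prev_obj > 0 else 1.0
            if (prev_obj - obj) / denom < tol:
                converged = True
                break
        prev_obj = obj
    # final consistent state: assignment to the final centroids
    labels, d2 = _assign(x, centroids)
    obj = float(d2.sum())
    return SegmentModel(k=k, centroids=centroids, assignment=labels + 1,
                        objective=obj, iterations=len(trace),
                        converged=converged, objective_trace=trace)


def kmeans_fit(points: np.ndarray, k: int, *, rng: np.random.Generator | None = None,
               seed: int | None = None, init: str = "k-means++",
               restarts: int = 10, tol: float = 1e-6,
               max_iter: int = 300) -> SegmentModel:
    """Lloyd's k-means with Euclidean distance.

    Runs ``restarts`` seeded initialisations (k-means++ by default) and
    keeps the solution with the lowest total within-cluster SS.  Each
    point ends up assigned to its nearest final centroid (ties broken by
    the lowest segment id) and every centroid is the mean of its points.
    """
    x = np.asarray(points, dtype=float)
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise SegmentationError(
            f"k={k} exceeds the number of distinct points ({n_distinct})")
    if rng is None:
        rng = np.random.default_rng(seed)
    best: SegmentModel | None = None
    for _ in range(restarts):
        model = _lloyd(x, k, rng, init, tol, max_iter)
        if best is None or model.objective < best.objective:
            best = model
    assert best is not None
    return best


def relabel_by_size(model: SegmentModel) -> SegmentModel:
    """Renumber segments 1..k by decreasing population (ties keep original order)."""
    sizes = np.array([(model.assignment == j + 1).sum() for j in range(model.k)])
    order = np.argsort(-sizes, kind="stable")       # old index per new id
    new_of_old = np.empty(model.k, dtype=int)
    new_of_old[order] = np.arange(model.k)
    return SegmentModel(
        k=model.k,
        centroids=model.centroids[order],
        assignment=new_of_old[model.assignment - 1] + 1,
        objective=model.objective,
        iterations=model.iterations,
        converged=model.converged,
        objective_trace=list(model.objective_trace),
    )
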