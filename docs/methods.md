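# Methods

This note documents the models, rules and numerical choices behind
`popsegment`: what is computed, what is assumed, and where the design was
genuinely open.

## The segmentation model

The unit of analysis is a GP-registered patient-year. Seven annual
utilisation counts — non-elective admissions, elective admissions,
outpatient first attendances, outpatient follow-up attendances, GP
practice visits, distinct drugs prescribed, A&E attendances — define a
point in ℝ⁷ per patient. Each variable is z-scored with the sample SD
(denominator n−1; the choice of denominator is immaterial at cohort
sizes but is fixed for reproducibility), giving every care setting equal
weight in the Euclidean metric. Clustering this space groups patients by
*pattern of care use*, not by diagnosis; all clinical attributes enter
only post hoc, in profiling.

Segmentation itself is plain k-means (Lloyd's algorithm). The
substantive modelling question is the number of clusters, handled by the
subsampled hierarchical procedure below.

## Cluster-count selection

Agglomerative clustering with Ward linkage is run on `n_subsets` random
subsets of `subset_size` patients (defaults 10 × 3,000; subsets are drawn
without replacement within a subset and independently across subsets).
Ward is the default because both stopping indices are within-SS based;
average and complete linkage are available by configuration, since the
linkage behind the original analysis is not documented anywhere we could
follow.

For each candidate count g in `k_range` (default 2–20) the trace records:

* the Calinski–Harabasz pseudo-F of the g-group cut,
  `F(g) = [B/(g−1)] / [W/(n−g)]`, where B + W equals the total SS about
  the grand mean (an identity the tests verify);
* the Duda–Hart record of the split undone when moving from g to g+1
  groups: Je(1) = within-SS of the parent cluster, Je(2) = summed
  within-SS of its two children, index Je(2)/Je(1), and
  pseudo-T² = (Je(1) − Je(2)) / (Je(2)/(n₁+n₂−2)). The algebraic
  identity index = 1/(1 + T²/(n₁+n₂−2)) holds on every split and is
  enforced by tests. Degenerate cases: Je(1)=0 leaves the index
  undefined (NaN); Je(2)=0 sends T² to +∞; n₁+n₂ ≤ 2 leaves T²
  undefined.

**Decision rule.** The qualitative guidance for these indices — a high
Duda–Hart with a low pseudo-T² next to high T² values — needs a concrete
operationalisation. Flagging strict local extrema of the two sequences
turns out to be the wrong formalisation: on cleanly clustered data, once
g passes the true count Ward undoes pure-cluster splits in decreasing
ΔSS order, so the pseudo-T² sequence declines gently and the true count
is never a strict interior minimum (empirically, T² falls from thousands
to ~50 at the true k and then drifts downward). What *is* diagnostic is
the fall itself. The rule used here:

* flag g when `T²(g−1)/T²(g) ≥ t2_drop_ratio` (default 3.0) **and** the
  Duda–Hart index rises from g−1 to g;
* each subset suggests the flagged g with the largest drop ratio (ties
  to the smallest g); a subset with no flag abstains;
* the consensus k is the median of suggestions; a half-integer median
  resolves toward the modal suggestion, then toward the smaller value.
  If every subset abstains the procedure raises and asks for a manual
  choice — on structureless data that is the correct answer.

The drop factor 3.0 says "the split at g is at least three times less
significant than the one before it"; on planted well-separated structure
the observed drop at the true count is ~70–80×, and on homogeneous noise
ratios hover near 1, so the default sits far from both regimes. The
full per-subset trace (pseudo-F, index, T², drop ratio, flags) is always
emitted so a human can override the automated choice, which is the
spirit in which these stopping rules are meant to be used.

## k-means

Lloyd's algorithm with squared-Euclidean assignment (ties to the lowest
centroid index), k-means++ initialisation, 10 restarts keeping the
lowest objective, relative-objective tolerance 1e-6, max 300 iterations.
An empty cluster during iteration is re-seeded with the point farthest
from its centroid. On instances small enough to enumerate every
partition (n ≤ 8) the implementation attains the global optimum in ≥95%
of seeded runs, and its objective matches scikit-learn's `KMeans` (used
in the tests only, as an independent cross-check). Segments are
renumbered 1..k by decreasing population for cross-run comparability.

## Need/complexity classification

Per segment, mean utilisation is divided by the population mean per
setting (settings with zero population mean are excluded from
counting). *High need*: some ratio > `need_any_setting_ratio` (default
2.0, i.e. more than 100% above the mean), or ratios >
`need_multi_setting_ratio` (1.2) in at least `need_multi_setting_min`
(4) settings. *High complexity*: ratios > 1 in at least 4 settings.
All inequalities are strict ("more than"), and all thresholds are
configurable so alternative readings of "care setting" or baseline can
be run.

Applied verbatim to the published per-segment means, this rule
contradicts the published characterisation for six of ten segments
(2, 3, 5, 7, 8 and 10): e.g. a segment with distinct-drugs ratio
12.35/4.75 = 2.6 is "high need" under the any-setting criterion yet was
published as low-need, and two segments published as low-complexity
exceed the population mean in all seven settings. The comparator
actually used for the published labels (possibly a different baseline or
a subset of settings) is not recoverable, so the classifier never
adjusts its output to match; `discrepancy_report` surfaces every
disagreement for human review.

## Profiling and the test battery

Per-segment summaries use sample SDs and pairwise deletion of missing
profiling values (the seven clustering variables are required complete —
distance is undefined on missing coordinates, so validation either
rejects or, in non-strict mode, drops such records with a count).
Cost-to-population ratio = (segment share of total cost)/(segment share
of patients).

Tests by variable type: utilisation counts and LTC count —
Kruskal–Wallis globally, Mann–Whitney pairwise (tie-corrected normal
approximation, no continuity correction; these are large samples); age
and emergency-admission risk — one-way ANOVA globally, t-test pairwise
(Welch by default, pooled by configuration); boolean proportions — k×2
chi-square without continuity correction globally, pooled two-proportion
z pairwise (z² equals the uncorrected 2×2 chi-square, verified in
tests). The Bonferroni divisor is k−1 — each segment against the k−1
others, giving 0.05/9 = 0.0056 at k = 10 — not the 45 unordered pairs;
it is configurable. P-values are stored at full precision; annotation
tiers (x/y/z for differing from k−1/k−2/k−3 other segments) are derived
from the significance flags.

## Synthetic cohorts

`default_generator_config` encodes the published ten-segment summary
profile: weights are the published segment sizes over 79,607;
utilisation, age, deprivation, smoking, risk, LTC prevalence, LTC count,
frailty and bed-day parameters are the printed per-segment values.
Distributional forms are stand-ins with matched first moments, since no
distributions were published:

* counts (utilisation, LTC count, bed days): negative binomial with
  variance m + m²/φ, dispersion φ = 1 by default — chosen because the
  printed SDs exceed the means for most variables — degenerate at zero
  when the mean is zero;
* age: normal truncated to [0, 105]; flags: independent Bernoulli
  (condition co-occurrence is not modelled; nothing was published about
  it); risk score: beta with moments matched to the printed mean/SD
  (infeasible combinations raise a parameter error);
* cost: Σ unit-price × activity plus half-normal noise. Unit prices are
  invented plausible values (£2000 non-elective admission, £1500
  elective, £200/£150 outpatient first/follow-up, £30 GP visit, £80 per
  distinct drug, £160 A&E); cost is deliberately *not* calibrated to the
  published per-head costs, which are checked as printed-table
  arithmetic instead.

The planted-cluster generator (`generate_planted_gaussians`) emits k
spherical unit-SD clusters with centroid spacing ≥ the requested number
of within-cluster SDs, shifted and rounded to non-negative integers so
they are valid counts. True labels always travel in a separate
`true_segment` column that clustering never reads.

What passing tests on these cohorts do and do not show: moment
identities, seeding contracts, cluster-count recovery and classifier
behaviour are fully exercised; but real utilisation data have
correlation structure across settings, longitudinal dependence and
coding artefacts that independent negative-binomial draws do not
emulate, so recovery results here bound method behaviour under the
stated mixture, not under any particular health system's data. One
visible consequence: k-means on the default mixture merges the
overlapping lowest-utilisation components, so the dominant fitted
segment holds somewhat more than its planted 50% weight (~68% at
n = 20,000).

## Problem sizes and determinism

Cluster-count recovery is exercised at 30,000 patients (10 subsets of
3,000, candidate counts 2–20), matching the study design; moment checks
use cohorts of 20,000–50,000; the null-calibration study uses 500
simulated cohorts of 120 patients. All randomness flows from a single
seed through `SeedSequence.spawn` with a fixed stage order (synthesis,
selection subsets, k-means), so identical configurations reproduce
outputs bit-identically and partial re-runs reproduce their stage.

## Known limitations

* The selection rule's drop factor is a heuristic constant; data with
  genuinely hierarchical structure at several scales may legitimately
  flag several counts, which is why the trace is always emitted.
* Printed-rounding inconsistencies in the published summaries (e.g. a
  cost-to-population ratio of 11.11 where the rounded printed costs give
  10.77) mean those ratios are checked as arithmetic on the given
  inputs, not as exact reproduction targets.
* The generator's independence assumptions (across settings and
  conditions) understate real-world clustering of morbidity and use.
* No alternative cluster-count criteria (gap statistic, silhouette) and
  no model-based clustering are provided; the scope is this method,
  done carefully.
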