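"""Standardisation, stopping indices, k-selection and k-means."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popsegment import (
    RunConfig,
    build_tree,
    ch_pseudo_f,
    duda_hart,
    fit_standardizer,
    generate_planted_gaussians,
    kmeans_fit,
    relabel_by_size,
    select_k,
    transform,
)
from popsegment.segmentation import SegmentationError, SegmentModel, _consensus

from conftest import (
    brute_between_ss,
    brute_pseudo_f,
    brute_within_ss,
    exhaustive_kmeans_optimum,
    make_cohort,
    pair_agreement_index,
)


def _col(values, col=0):
    """Embed 1-D values into the 7-column utilisation space (other cols 0)."""
    x = np.zeros((len(values), 7))
    x[:, col] = values
    return x


# ---------------------------- standardiser ----------------------------

def test_standardizer_hand_values():
    cohort = make_cohort(np.tile([[0], [1], [2]], (1, 7)))
    std = fit_standardizer(cohort)
    np.testing.assert_allclose(std.mu, np.ones(7))
    np.testing.assert_allclose(std.sigma, np.ones(7))   # sample SD, n-1


def test_standardizer_zero_variance_names_variable():
    util = np.tile([[1, 2, 3]], (7, 1)).T.copy()
    util[:, 4] = 5                                       # gp_visits constant
    with pytest.raises(SegmentationError, match="gp_visits"):
        fit_standardizer(make_cohort(util))


def test_transform_definition_and_roundtrip(rng):
    cohort = make_cohort(rng.integers(0, 9, size=(40, 7)))
    std = fit_standardizer(cohort)
    z = transform(std, cohort)
    np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-9)
    np.testing.assert_allclose(std.transform(std.mu), np.zeros(7), atol=1e-12)
    np.testing.assert_allclose(std.transform(std.mu + std.sigma), np.ones(7))
    np.testing.assert_allclose(std.inverse_transform(z), cohort.utilisation(),
                               atol=1e-12)


def test_standardisation_scale_equivariance(rng):
    """Scaling a raw column leaves the standardised matrix unchanged."""
    util = rng.integers(0, 7, size=(60, 7)) + 1
    a = make_cohort(util)
    scaled = util.copy()
    scaled[:, 3] *= 13
    b = make_cohort(scaled)
    za = transform(fit_standardizer(a), a)
    zb = transform(fit_standardizer(b), b)
    np.testing.assert_allclose(za, zb, atol=1e-9)


# ---------------------------- hierarchy ----------------------------

def test_ward_first_merge_joins_closest_points():
    tree = build_tree(_col([0.0, 1.0, 10.0]))
    assert set(tree.z[0, :2].astype(int)) == {0, 1}


def test_identical_points_merge_at_height_zero():
    tree = build_tree(np.zeros((2, 7)))
    assert tree.z[0, 2] == 0.0
    assert tree.node_ss[2] == 0.0


def test_cut_into_n_singletons_has_zero_within_ss():
    x = _col([0.0, 2.0, 5.0, 9.0])
    tree = build_tree(x)
    labels = tree.cut(4)
    assert len(set(labels)) == 4
    assert brute_within_ss(x, labels) == 0.0


# ---------------------------- pseudo-F ----------------------------

def test_pseudo_f_hand_example():
    x = _col([0.0, 1.0, 10.0, 11.0])
    labels = np.array([1, 1, 2, 2])
    assert ch_pseudo_f(x, labels) == pytest.approx(200.0)
    assert brute_within_ss(x, labels) == pytest.approx(1.0)
    assert brute_between_ss(x, labels) == pytest.approx(100.0)


def test_pseudo_f_degenerate_cases():
    x = np.zeros((4, 7))
    assert ch_pseudo_f(x, np.array([1, 1, 2, 2])) == 0.0          # B = 0
    y = _col([0.0, 0.0, 5.0, 5.0])
    assert ch_pseudo_f(y, np.array([1, 1, 2, 2])) == np.inf       # W = 0, B > 0
    with pytest.raises(SegmentationError):
        ch_pseudo_f(y, np.array([1, 1, 1, 1]))                    # k < 2


def test_pseudo_f_matches_brute_force_oracle_and_sklearn(rng):
    from sklearn.metrics import calinski_harabasz_score

    for _ in range(100):
        n = int(rng.integers(6, 31))
        k = int(rng.integers(2, 6))
        x = rng.normal(size=(n, 7))
        labels = np.r_[np.arange(k), rng.integers(0, k, n - k)]
        rng.shuffle(labels)
        ours = ch_pseudo_f(x, labels)
        assert ours == pytest.approx(brute_pseudo_f(x, labels), rel=1e-9)
        assert ours == pytest.approx(calinski_harabasz_score(x, labels), rel=1e-9)


def test_ss_decomposition_property(rng):
    for _ in range(25):
        n = int(rng.integers(5, 40))
        x = rng.normal(size=(n, 7))
        labels = rng.integers(0, 4, n)
        w, b = brute_within_ss(x, labels), brute_between_ss(x, labels)
        total = float(((x - x.mean(axis=0)) ** 2).sum())
        assert w + b == pytest.approx(total, rel=1e-9)


# ---------------------------- Duda-Hart ----------------------------

def test_duda_hart_hand_example():
    tree = build_tree(_col([0.0, 1.0, 10.0, 11.0]))
    rec = duda_hart(tree, 1)
    assert rec.je1 == pytest.approx(101.0)
    assert rec.je2 == pytest.approx(1.0)
    assert rec.dh_index == pytest.approx(1 / 101)
    assert rec.pseudo_t2 == pytest.approx(200.0)
    # algebraic identity
    assert rec.dh_index == pytest.approx(
        1.0 / (1.0 + rec.pseudo_t2 / (rec.n1 + rec.n2 - 2)))


def test_duda_hart_identity_on_every_split(rng):
    for _ in range(10):
        x = rng.normal(size=(int(rng.integers(8, 25)), 7))
        tree = build_tree(x)
        for g in range(1, tree.n - 1):
            rec = duda_hart(tree, g)
            if rec.n1 + rec.n2 > 2 and rec.je2 > 0 and rec.je1 > 0:
                assert rec.dh_index == pytest.approx(
                    1.0 / (1.0 + rec.pseudo_t2 / (rec.n1 + rec.n2 - 2)), abs=1e-9)
            assert 0.0 <= rec.dh_index <= 1.0 + 1e-12 or np.isnan(rec.dh_index)


def test_duda_hart_pure_children_limit():
    tree = build_tree(_col([0.0, 0.0, 5.0, 5.0]))
    rec = duda_hart(tree, 1)
    assert rec.je2 == 0.0
    assert rec.dh_index == 0.0
    assert rec.pseudo_t2 == np.inf


# ---------------------------- k-means ----------------------------

def test_kmeans_k1_closed_form(rng):
    x = rng.normal(size=(30, 7))
    model = kmeans_fit(x, 1, seed=0)
    np.testing.assert_allclose(model.centroids[0], x.mean(axis=0))
    assert model.objective == pytest.approx(float(((x - x.mean(0)) ** 2).sum()))


def test_kmeans_two_cluster_hand_example():
    x = _col([0.0, 1.0, 10.0, 11.0])
    model = kmeans_fit(x, 2, seed=0)
    assert model.objective == pytest.approx(1.0)
    assert len(set(model.assignment[:2])) == 1
    assert len(set(model.assignment[2:])) == 1


def test_kmeans_objective_trace_non_increasing(rng):
    x = rng.normal(size=(200, 7))
    model = kmeans_fit(x, 5, seed=1, restarts=1)
    trace = np.array(model.objective_trace)
    assert (np.diff(trace) <= 1e-9).all()


def test_kmeans_attains_exhaustive_optimum_on_tiny_instances(rng):
    hits = 0
    for i in range(100):
        n = int(rng.integers(5, 9))
        k = int(rng.integers(2, 4))
        x = rng.normal(size=(n, 2))
        model = kmeans_fit(x, k, seed=i, restarts=10)
        best = exhaustive_kmeans_optimum(x, k)
        hits += model.objective <= best + 1e-9
    assert hits >= 95


def test_kmeans_matches_sklearn_objective(rng):
    from sklearn.cluster import KMeans

    x = rng.normal(size=(300, 7)) + 4 * rng.integers(0, 3, 300)[:, None]
    ours = kmeans_fit(x, 3, seed=0, restarts=10)
    ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(x)
    assert ours.objective == pytest.approx(ref.inertia_, rel=1e-6)


def test_kmeans_rejects_k_above_distinct_points():
    x = np.zeros((5, 7))
    with pytest.raises(SegmentationError):
        kmeans_fit(x, 2, seed=0)


def test_kmeans_centroids_are_assigned_means(rng):
    x = rng.normal(size=(120, 7))
    model = kmeans_fit(x, 4, seed=2)
    for j in range(4):
        members = x[model.assignment == j + 1]
        np.testing.assert_allclose(model.centroids[j], members.mean(axis=0),
                                   atol=1e-9)


def test_relabel_by_size_orders_ties_and_is_idempotent():
    model = SegmentModel(
        k=3, centroids=np.arange(21, dtype=float).reshape(3, 7),
        assignment=np.array([1] * 5 + [2] * 100 + [3] * 20),
        objective=1.0, iterations=1, converged=True)
    rel = relabel_by_size(model)
    assert (rel.assignment[:5] == 3).all()
    assert (rel.assignment[5:105] == 1).all()
    assert (rel.assignment[105:] == 2).all()
    np.testing.assert_allclose(rel.centroids[0], model.centroids[1])
    again = relabel_by_size(rel)
    np.testing.assert_array_equal(again.assignment, rel.assignment)

    equal = SegmentModel(
        k=2, centroids=np.zeros((2, 7)),
        assignment=np.array([1, 2, 1, 2]), objective=0.0, iterations=1,
        converged=True)
    np.testing.assert_array_equal(relabel_by_size(equal).assignment,
                                  equal.assignment)


# ---------------------------- selection ----------------------------

def test_select_k_recovers_two_planted_clusters():
    cohort, _ = generate_planted_gaussians(2, 400, separation=12.0, seed=5)
    cfg = RunConfig(seed=2, n_subsets=4, subset_size=150, k_range=(2, 8))
    trace = select_k(cohort, cfg)
    assert trace.chosen_k == 2
    assert set(trace.table.columns) >= {"subset", "g", "pseudo_f", "dh_index",
                                        "pseudo_t2", "flagged"}


def test_select_k_trace_shape_and_bounds():
    cohort, _ = generate_planted_gaussians(3, 300, separation=9.0, seed=7)
    cfg = RunConfig(seed=1, n_subsets=3, subset_size=100, k_range=(2, 6))
    trace = select_k(cohort, cfg)
    assert len(trace.table) == 3 * 5
    assert 2 <= trace.chosen_k <= 6
    assert len(trace.suggestions) == 3


def test_consensus_median_resolves_toward_mode():
    assert _consensus([10, 10, 10, 12]) == 10
    assert _consensus([9, 10, 10, 11]) == 10
    assert _consensus([2, 2, 3, 3]) == 2        # tie -> smaller
    assert _consensus([4]) == 4


def test_label_recovery_on_separated_mixture():
    cohort, truth = generate_planted_gaussians(4, 2000, separation=6.0, seed=9)
    z = transform(fit_standardizer(cohort), cohort)
    model = kmeans_fit(z, 4, seed=0)
    assert pair_agreement_index(truth, model.assignment) > 0.9


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(1, 10_000))
def test_clustering_scale_invariance_property(mult):
    """Scaling any raw column by a positive constant leaves clustering output
    unchanged (standardisation equivariance)."""
    rng = np.random.default_rng(77)
    util = rng.integers(0, 6, size=(50, 7)) + 1
    scaled = util.copy()
    scaled[:, 1] *= mult
    a, b = make_cohort(util), make_cohort(scaled)
    za = transform(fit_standardizer(a), a)
    zb = transform(fit_standardizer(b), b)
    ma = kmeans_fit(za, 3, seed=4)
    mb = kmeans_fit(zb, 3, seed=4)
    np.testing.assert_array_equal(ma.assignment, mb.assignment)
    assert ma.objective == pytest.approx(mb.objective, rel=1e-9)
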