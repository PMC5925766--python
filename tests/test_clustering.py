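import numpy as np
import pytest

from interheat import (DataMatrix, agglomerate, compute_distance, cut_tree,
                       find_k, mean_silhouette)
from interheat.clustering import ClusteringError, DistanceMatrix
from interheat.datasets import planted_clusters

from conftest import brute_silhouette, mst_edge_weights, random_matrix


# -- distances ---------------------------------------------------------------

def test_euclidean_three_four_five():
    m = DataMatrix(np.array([[0.0, 0.0], [3.0, 4.0]]), ["a", "b"], ["x", "y"])
    assert compute_distance(m).d[0, 1] == pytest.approx(5.0)


def test_identical_rows_zero_distance():
    m = DataMatrix(np.array([[1.0, 2.0], [1.0, 2.0]]), ["a", "b"], ["x", "y"])
    assert compute_distance(m, "manhattan").d[0, 1] == 0.0


def test_pearson_dissimilarity_of_collinear_rows():
    m = DataMatrix(np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]),
                   ["a", "b"], ["x", "y", "z"])
    assert compute_distance(m, "pearson").d[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_maximum_metric_is_chebyshev():
    m = DataMatrix(np.array([[0.0, 0.0], [3.0, 4.0]]), ["a", "b"], ["x", "y"])
    assert compute_distance(m, "maximum").d[0, 1] == 4.0


def test_missing_values_pairwise_complete_rescaling():
    # joint columns: 2 of 3 -> squared sum rescaled by 3/2
    m = DataMatrix(np.array([[0.0, 0.0, np.nan], [3.0, 4.0, 7.0]]),
                   ["a", "b"], ["x", "y", "z"])
    assert compute_distance(m).d[0, 1] == pytest.approx(np.sqrt(25 * 3 / 2))
    assert compute_distance(m, "manhattan").d[0, 1] == pytest.approx(7 * 3 / 2)


def test_no_joint_observation_names_pair():
    m = DataMatrix(np.array([[1.0, np.nan], [np.nan, 2.0]]), ["a", "b"], ["x", "y"])
    with pytest.raises(ClusteringError, match="'a'.*'b'"):
        compute_distance(m)


def test_unknown_metric_rejected():
    m = DataMatrix(np.ones((2, 2)), ["a", "b"], ["x", "y"])
    with pytest.raises(ClusteringError):
        compute_distance(m, "cosine")


# -- agglomeration -----------------------------------------------------------

def test_upgma_heights_on_line(line_matrix):
    t = agglomerate(compute_distance(line_matrix), "average")
    # {0,1} merge at 1; then distance to {5} = (5+4)/2 = 4.5
    np.testing.assert_allclose(t.heights, [1.0, 4.5])


def test_two_leaves_single_merge():
    m = DataMatrix(np.array([[0.0], [3.0]]), ["a", "b"], ["v"])
    t = agglomerate(compute_distance(m), "single")
    assert t.heights.tolist() == [3.0]


@pytest.mark.parametrize("seed", range(10))
def test_single_linkage_equals_mst(seed):
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, int(rng.integers(4, 13)), 3)
    d = compute_distance(m)
    t = agglomerate(d, "single")
    np.testing.assert_allclose(sorted(t.heights), mst_edge_weights(d.d))


@pytest.mark.parametrize("linkage", ["single", "complete", "average", "ward"])
def test_merge_heights_monotone(linkage):
    rng = np.random.default_rng(42)
    m = random_matrix(rng, 12, 4)
    t = agglomerate(compute_distance(m), linkage)
    assert (np.diff(t.heights) >= -1e-12).all()


def test_unknown_linkage_rejected(line_matrix):
    with pytest.raises(ClusteringError):
        agglomerate(compute_distance(line_matrix), "median")


# -- tree cutting ------------------------------------------------------------

def test_cut_extremes(line_matrix):
    t = agglomerate(compute_distance(line_matrix), "average")
    assert cut_tree(t, 3).labels_by_leaf.tolist() != [0, 0, 0]
    assert len(set(cut_tree(t, 3).labels_by_leaf)) == 3
    assert set(cut_tree(t, 1).labels_by_leaf) == {0}


def test_cut_line_k2_groups_near_points(line_matrix):
    t = agglomerate(compute_distance(line_matrix), "average")
    lab = cut_tree(t, 2).labels_by_leaf
    assert lab[0] == lab[1] != lab[2]


def test_cut_labels_numbered_by_leaf_order(line_matrix):
    t = agglomerate(compute_distance(line_matrix), "average")
    lab = cut_tree(t, 2).labels_by_leaf
    # walking the display order, cluster ids must appear as 0 then 1
    seen = list(dict.fromkeys(lab[i] for i in t.leaf_order))
    assert seen == [0, 1]


def test_cut_out_of_range(line_matrix):
    t = agglomerate(compute_distance(line_matrix), "average")
    with pytest.raises(ClusteringError):
        cut_tree(t, 4)


@pytest.mark.parametrize("linkage", ["single", "complete", "average", "ward"])
@pytest.mark.parametrize("k", [2, 3, 5])
def test_cut_partitions_all_leaves(linkage, k):
    rng = np.random.default_rng(1)
    m = random_matrix(rng, 9, 3)
    t = agglomerate(compute_distance(m), linkage)
    a = cut_tree(t, k)
    assert len(a.labels_by_leaf) == 9
    assert len(set(a.labels_by_leaf)) == k


# -- silhouette --------------------------------------------------------------

def test_silhouette_two_pairs(four_point_matrix):
    d = compute_distance(four_point_matrix)
    t = agglomerate(d, "average")
    a = cut_tree(t, 2)
    # outer points: (10.5-1)/10.5; inner points: (9.5-1)/9.5
    expected = (2 * 9.5 / 10.5 + 2 * 8.5 / 9.5) / 4
    assert mean_silhouette(d, a) == pytest.approx(expected, abs=1e-12)
    assert mean_silhouette(d, a) == pytest.approx(0.8997493734335840, abs=1e-12)


def test_silhouette_coincident_clusters_is_one():
    m = DataMatrix(np.array([[0.0], [0.0], [9.0], [9.0]]), list("abcd"), ["v"])
    d = compute_distance(m)
    a = cut_tree(agglomerate(d, "average"), 2)
    assert mean_silhouette(d, a) == 1.0


def test_singleton_contributes_zero():
    # two coincident points + one singleton: singleton s=0, others s=1
    m = DataMatrix(np.array([[0.0], [0.0], [9.0]]), list("abc"), ["v"])
    d = compute_distance(m)
    a = cut_tree(agglomerate(d, "average"), 2)
    assert mean_silhouette(d, a) == pytest.approx(2 / 3)


def test_silhouette_requires_k_at_least_two(line_matrix):
    d = compute_distance(line_matrix)
    a = cut_tree(agglomerate(d, "average"), 1)
    with pytest.raises(ClusteringError):
        mean_silhouette(d, a)


@pytest.mark.parametrize("seed", range(8))
def test_silhouette_matches_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(5, 31))
    m = random_matrix(rng, n, 3)
    d = compute_distance(m)
    t = agglomerate(d, "average")
    for k in range(2, min(8, n)):
        a = cut_tree(t, k)
        assert mean_silhouette(d, a) == pytest.approx(
            brute_silhouette(d.d, a.labels_by_leaf), abs=1e-9)


def test_silhouette_matches_sklearn(four_point_matrix):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    d = compute_distance(four_point_matrix)
    a = cut_tree(agglomerate(d, "average"), 2)
    ref = sklearn_metrics.silhouette_score(d.d, a.labels_by_leaf,
                                           metric="precomputed")
    assert mean_silhouette(d, a) == pytest.approx(ref, abs=1e-12)


# -- find_k ------------------------------------------------------------------

def test_find_k_recovers_planted_three_groups():
    m = planted_clusters(3, 5, 4, separation=10.0, noise_sd=0.1, seed=1)
    d = compute_distance(m)
    t = agglomerate(d, "average")
    a = find_k(d, t)
    assert a.k == 3
    # independent argmax over the whole curve
    scores = {k: brute_silhouette(d.d, cut_tree(t, k).labels_by_leaf)
              for k in range(2, 11)}
    assert a.k == min(k for k, s in scores.items() if s == max(scores.values()))


def test_find_k_perfect_separation():
    m = DataMatrix(np.array([[0.0], [0.0], [50.0], [50.0]]), list("abcd"), ["v"])
    d = compute_distance(m)
    a = find_k(d, agglomerate(d, "average"))
    assert a.k == 2 and a.mean_silhouette == 1.0


def test_find_k_tie_breaks_to_smallest_k():
    # regular simplex: every partition scores 0, so all k tie -> pick 2
    d = DistanceMatrix(np.ones((5, 5)) - np.eye(5), list("abcde"), "euclidean")
    t = agglomerate(d, "average")
    a = find_k(d, t)
    assert a.k == 2 and a.mean_silhouette == 0.0


def test_find_k_needs_three_leaves():
    m = DataMatrix(np.array([[0.0], [1.0]]), ["a", "b"], ["v"])
    d = compute_distance(m)
    with pytest.raises(ClusteringError):
        find_k(d, agglomerate(d, "average"))


@pytest.mark.parametrize("seed", range(5))
def test_find_k_is_independent_argmax(seed):
    rng = np.random.default_rng(500 + seed)
    m = random_matrix(rng, int(rng.integers(6, 20)), 4)
    d = compute_distance(m)
    t = agglomerate(d, "average")
    a = find_k(d, t)
    k_max = min(10, d.n - 1)
    scores = {k: brute_silhouette(d.d, cut_tree(t, k).labels_by_leaf)
              for k in range(2, k_max + 1)}
    best = max(scores.values())
    assert a.mean_silhouette == pytest.approx(best, abs=1e-9)
    assert a.k == min(k for k, s in scores.items()
                      if s >= best - 1e-12)
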