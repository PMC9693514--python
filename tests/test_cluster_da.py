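"""Ward agglomeration, tree cutting and discriminant validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from epibrom.benchmarks import adjusted_rand_index, ward_bruteforce_agreement
from epibrom.cluster_da import (GroupModel, brute_force_ward, cut_tree,
                                fit_discriminant, mahalanobis_matrix,
                                two_way_cluster, ward_linkage)


def partition_sets(mapping):
    groups = {}
    for k, v in mapping.items():
        groups.setdefault(v, set()).add(k)
    return sorted(map(frozenset, groups.values()), key=sorted)


# ---------------------------------------------------------------------------
# Ward linkage

def test_two_points_merge_at_half_squared_distance():
    X = np.array([[0.0, 0.0], [3.0, 4.0]])
    tree = ward_linkage(X)
    assert len(tree.merges) == 1
    a, b, h = tree.merges[0]
    assert (a, b) == ((0,), (1,))
    assert h == pytest.approx(25.0 / 2)          # dSSE convention


def test_matches_brute_force_on_planar_configuration():
    X = np.array([[0, 0], [0.1, 0], [4, 4], [4.1, 4], [8, 0], [8, 0.2]],
                 dtype=float)
    fast, slow = ward_linkage(X), brute_force_ward(X)
    for (a1, b1, h1), (a2, b2, h2) in zip(fast.merges, slow.merges):
        assert (a1, b1) == (a2, b2)
        assert h1 == pytest.approx(h2, abs=1e-9)


def test_duplicated_points_merge_first_at_zero_height():
    rng = np.random.default_rng(0)
    P = rng.normal(size=(4, 3))
    X = np.vstack([P, P])
    tree = ward_linkage(X)
    first = tree.merges[:4]
    assert all(h == pytest.approx(0.0) for _, _, h in first)
    merged_pairs = {frozenset(a + b) for a, b, _ in first}
    assert merged_pairs == {frozenset({i, i + 4}) for i in range(4)}


def test_heights_monotone_nondecreasing():
    rng = np.random.default_rng(5)
    for _ in range(5):
        tree = ward_linkage(rng.normal(size=(14, 4)))
        h = tree.heights()
        assert all(h[i] <= h[i + 1] + 1e-12 for i in range(len(h) - 1))


def test_brute_force_equivalence_random_instances():
    # property over random small instances (oracle agreement must be total)
    assert ward_bruteforce_agreement(n_trials=60, seed=2) == 1.0


def test_nan_rejected():
    with pytest.raises(ValueError, match="NaN"):
        ward_linkage(np.array([[0.0], [np.nan]]))


def test_merge_order_agrees_with_scipy_partition():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(18, 5))
    mine = cut_tree(ward_linkage(X), 4)
    sc = fcluster(linkage(X, method="ward"), 4, criterion="maxclust")
    other = {str(i): c for i, c in enumerate(sc)}
    assert partition_sets(mine) == partition_sets(other)


# ---------------------------------------------------------------------------
# Two-way clustering

def test_symmetric_matrix_gives_identical_trees():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(6, 6))
    S = (A + A.T) / 2
    df = pd.DataFrame(S, index=list("abcdef"), columns=list("abcdef"))
    row_tree, col_tree, _ = two_way_cluster(df)
    assert row_tree.merges == col_tree.merges


def test_block_diagonal_top_split_separates_blocks():
    blocks = np.zeros((6, 6))
    blocks[:3, :3] = 5.0
    blocks[3:, 3:] = 5.0
    df = pd.DataFrame(blocks,
                      index=[f"r{i}" for i in range(6)],
                      columns=[f"c{i}" for i in range(6)])
    row_tree, col_tree, ordered = two_way_cluster(df)
    top_a, top_b, _ = row_tree.merges[-1]
    assert {frozenset(top_a), frozenset(top_b)} == \
        {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
    top_a, top_b, _ = col_tree.merges[-1]
    assert {frozenset(top_a), frozenset(top_b)} == \
        {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
    assert set(ordered.index[:3]) in ({"r0", "r1", "r2"}, {"r3", "r4", "r5"})


def test_single_column_trait_tree_degenerate():
    df = pd.DataFrame({"only": [1.0, 2.0, 3.0]}, index=list("abc"))
    _, col_tree, _ = two_way_cluster(df)
    assert col_tree.merges == []


# ---------------------------------------------------------------------------
# Tree cutting

def test_cut_extremes_and_nesting():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 3))
    tree = ward_linkage(X)
    assert set(cut_tree(tree, 1).values()) == {0}
    assert len(set(cut_tree(tree, 10).values())) == 10
    with pytest.raises(ValueError):
        cut_tree(tree, 0)
    with pytest.raises(ValueError):
        cut_tree(tree, 11)
    # k-partition refines the (k-1)-partition
    for k in range(2, 10):
        fine = cut_tree(tree, k)
        coarse = cut_tree(tree, k - 1)
        for cs in partition_sets(fine):
            assert any(cs <= bigger for bigger in partition_sets(coarse))


def test_cut_recovers_generator_archetypes():
    from epibrom.benchmarks import label_recovery
    from epibrom.synthetic import SyntheticConfig
    metrics = label_recovery(SyntheticConfig(seed=0), k=5)
    assert metrics["ward_ari"] >= 0.9


# ---------------------------------------------------------------------------
# Discriminant analysis

def test_identity_covariance_reduces_to_euclidean():
    rng = np.random.default_rng(11)
    # two groups with isotropic unit covariance by construction
    base = rng.normal(size=(40, 2))
    base = (base - base.mean(0)) @ np.linalg.inv(
        np.linalg.cholesky(np.cov(base.T, bias=False))).T
    X = pd.DataFrame(np.vstack([base, base + [5.0, 0.0]]),
                     columns=["u", "v"])
    y = pd.Series(["a"] * 40 + ["b"] * 40, index=X.index)
    model = fit_discriminant(X, y, shrinkage=0.0)
    d2 = mahalanobis_matrix(model).at["a", "b"]
    centro = model.centroids
    eucl2 = ((centro.loc["a"] - centro.loc["b"]) ** 2).sum()
    assert d2 == pytest.approx(eucl2, rel=1e-9)


def test_two_group_two_dim_hand_computation():
    X = pd.DataFrame({"x": [0.0, 2.0, 4.0, 10.0, 12.0, 14.0],
                      "y": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]})
    y = pd.Series(["a", "a", "a", "b", "b", "b"], index=X.index)
    model = fit_discriminant(X, y, shrinkage=0.0)
    # pooled covariance: within-group scatter / (n - g) = 16/4 for x, 0 y
    # hand: scatter_x = (2-0)^2*... each group {0,2,4}: dev {-2,0,2} -> 8
    # two groups -> 16; pooled = 16/4 = 4.  y constant within groups.
    # regularisation floor keeps y invertible; x-distance dominates:
    # d2 >= (12-2)^2/4 = 25
    d2 = mahalanobis_matrix(model).at["a", "b"]
    assert d2 >= 25.0 - 1e-9
    # 1-D check without the degenerate dimension
    model1 = fit_discriminant(X[["x"]], y, shrinkage=0.0)
    d1 = mahalanobis_matrix(model1).at["a", "b"]
    assert d1 == pytest.approx((12.0 - 2.0) ** 2 / 4.0, rel=1e-9)


def test_identical_centroids_zero_distance():
    X = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
    y = pd.Series(["a", "a", "b", "b"], index=X.index)
    d = mahalanobis_matrix(fit_discriminant(X, y, shrinkage=0.0))
    assert d.at["a", "b"] == pytest.approx(0.0)
    assert d.at["a", "a"] == 0.0


def test_mahalanobis_affine_invariance():
    rng = np.random.default_rng(21)
    X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("xyz"))
    y = pd.Series(rng.choice(["a", "b", "c"], size=60), index=X.index)
    A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    shift = rng.normal(size=3)
    X2 = pd.DataFrame(X.to_numpy() @ A.T + shift, columns=list("xyz"))
    d1 = mahalanobis_matrix(fit_discriminant(X, y, shrinkage=0.0))
    d2 = mahalanobis_matrix(fit_discriminant(X2, y, shrinkage=0.0))
    np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), rtol=1e-8)
    assert np.allclose(d1.to_numpy(), d1.to_numpy().T)
    assert np.allclose(np.diag(d1.to_numpy()), 0.0)


def test_training_classification_on_separated_groups(default_dataset):
    table, tree, labels, _ = default_dataset
    full = table.values.dropna()
    from epibrom.preprocess import transform
    matrix = transform(table.subset_species(list(full.index)))
    truth = labels.loc[matrix.index]
    model = fit_discriminant(matrix, truth)
    agreement = float((model.classify(matrix) == truth).mean())
    assert agreement >= 0.95


def test_small_groups_rejected():
    X = pd.DataFrame({"x": [0.0, 1.0, 5.0]})
    y = pd.Series(["a", "a", "b"], index=X.index)
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_discriminant(X, y)
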