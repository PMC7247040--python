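"""Fidelity, agreement, overlap, symmetry, contiguity and graph metrics."""

import math

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_mutual_info_score

import conparc as cp
from conparc.core import DenseConnectome, Partition


def random_connectome(rng, K):
    w = np.triu(rng.random((K, K)), 1)
    return DenseConnectome(w + w.T)


# ---------------------------------------------------------------------------
# piecewise-constant approximation and KL divergence
# ---------------------------------------------------------------------------


def test_piecewise_constant_singletons_identity(rng):
    w = random_connectome(rng, 6)
    gamma = cp.piecewise_constant(w, Partition(np.arange(6)))
    assert np.allclose(gamma, w.weights)


def test_piecewise_constant_fixed_point_on_block_constant():
    labels = np.array([0, 0, 1, 1])
    w = np.where(labels[:, None] == labels[None, :], 0.0, 2.0)
    np.fill_diagonal(w, 0.0)
    conn = DenseConnectome(w)
    gamma = cp.piecewise_constant(conn, Partition(labels))
    # off-diagonal blocks of a block-constant matrix are reproduced exactly
    assert np.allclose(gamma[:2, 2:], 2.0)


def test_piecewise_constant_explicit_block_means():
    w = np.array(
        [
            [0.0, 1.0, 2.0, 3.0],
            [1.0, 0.0, 4.0, 5.0],
            [2.0, 4.0, 0.0, 6.0],
            [3.0, 5.0, 6.0, 0.0],
        ]
    )
    gamma = cp.piecewise_constant(DenseConnectome(w), Partition(np.array([0, 0, 1, 1])))
    assert gamma[0, 2] == pytest.approx((2 + 3 + 4 + 5) / 4)  # brute-force block mean
    assert gamma[0, 0] == pytest.approx(2 / 4)
    assert gamma[2, 3] == pytest.approx(12 / 4)


def test_kl_zero_iff_block_constant(rng):
    labels = np.array([0, 0, 0, 1, 1, 1])
    w = np.where(labels[:, None] == labels[None, :], 3.0, 1.0)
    np.fill_diagonal(w, 0.0)
    conn = DenseConnectome(w)
    gamma = cp.piecewise_constant(conn, Partition(labels))
    # within-block off-diagonal pairs all share a weight, so KL vanishes only
    # after the diagonal-cell dilution is absent; compare against singletons
    assert cp.kl_divergence(conn, conn.weights) == pytest.approx(0.0, abs=1e-12)
    assert cp.kl_divergence(conn, gamma) >= 0.0
    w2 = random_connectome(rng, 8)
    g2 = cp.piecewise_constant(w2, Partition(np.array([0, 0, 1, 1, 2, 2, 3, 3])))
    assert cp.kl_divergence(w2, g2) >= 0.0  # Gibbs' inequality


def test_kl_refinement_monotonicity(small_cohort):
    """KL is non-increasing along nested refinement levels."""
    for i in range(3):
        w = small_cohort.connectomes[i]
        hp = cp.hierarchical_parcellation(w, cp.ParcellationConfig(random_seed=i))
        kls = [cp.kl_divergence(w, cp.piecewise_constant(w, lvl)) for lvl in hp.levels]
        for coarse, fine in zip(kls, kls[1:]):
            assert fine <= coarse + 1e-9


def test_kl_rejects_zero_support_violation():
    w = np.array([[0.0, 1.0], [1.0, 0.0]])
    gamma = np.zeros((2, 2))
    with pytest.raises(ValueError):
        cp.kl_divergence(DenseConnectome(w), gamma)


# ---------------------------------------------------------------------------
# mutual information, expected MI, AMI
# ---------------------------------------------------------------------------


def test_mi_of_identical_partitions_is_entropy():
    p = Partition(np.array([0, 0, 0, 1, 1, 2]))
    mi, hx, hy, _ = cp.mutual_information(p, p)
    assert mi == pytest.approx(hx)
    assert hx == pytest.approx(hy)


def test_mi_against_single_cluster_is_zero(rng):
    x = Partition(rng.integers(0, 3, size=20))
    y = Partition(np.zeros(20, dtype=int))
    mi, *_ = cp.mutual_information(x, y)
    assert mi == pytest.approx(0.0, abs=1e-12)


def test_mi_hand_summation_oracle():
    # contingency [[2,1],[1,2]], K=6
    x = Partition(np.array([0, 0, 0, 1, 1, 1]))
    y = Partition(np.array([0, 0, 1, 0, 1, 1]))
    mi, hx, hy, t = cp.mutual_information(x, y)
    assert t.counts.tolist() == [[2, 1], [1, 2]]
    expected = (2 / 3) * math.log(4 / 3) + (1 / 3) * math.log(2 / 3)
    assert mi == pytest.approx(expected)


def test_expected_mi_single_row_cluster_is_zero():
    assert cp.expected_mi([6], [3, 3], 6) == pytest.approx(0.0, abs=1e-12)


def test_expected_mi_against_monte_carlo():
    """Hypergeometric E[MI] agrees with permutation sampling within 3 SE."""
    rng = np.random.default_rng(99)
    x = np.array([0, 0, 0, 1, 1, 1])
    y = np.array([0, 0, 1, 0, 1, 1])
    n_draws = 100_000
    mis = np.empty(n_draws)
    for i in range(n_draws):
        mis[i] = cp.mutual_information(Partition(x), Partition(rng.permutation(y)))[0]
    emi = cp.expected_mi([3, 3], [3, 3], 6)
    se = mis.std(ddof=1) / math.sqrt(n_draws)
    assert abs(emi - mis.mean()) <= 3 * se


@pytest.mark.parametrize("k", [6, 9, 12])
def test_expected_mi_bounded_by_entropies(k, rng):
    x = rng.integers(0, 3, size=k)
    y = rng.integers(0, 4, size=k)
    _, hx, hy, t = cp.mutual_information(Partition(x), Partition(y))
    emi = cp.expected_mi(t.row_marginals, t.col_marginals, k)
    assert emi <= min(hx, hy) + 1e-12
    assert emi >= 0.0


def test_ami_is_one_for_relabeled_partitions(rng):
    x = Partition(rng.integers(0, 5, size=40))
    perm = rng.permutation(10)
    y = Partition(perm[x.labels])
    assert cp.ami(x, y) == 1.0


def test_ami_near_zero_for_independent_partitions():
    rng = np.random.default_rng(7)
    x = Partition(rng.integers(0, 10, size=1000))
    y = Partition(rng.integers(0, 10, size=1000))
    assert abs(cp.ami(x, y)) <= 0.05


def test_ami_matches_sklearn_oracle(rng):
    """Independent cross-check: sklearn's AMImax on random label pairs."""
    for _ in range(25):
        K = int(rng.integers(8, 40))
        x = rng.integers(0, 5, size=K)
        y = rng.integers(0, 4, size=K)
        ours = cp.ami(Partition(x), Partition(y))
        ref = adjusted_mutual_info_score(x, y, average_method="max")
        assert ours == pytest.approx(ref, abs=1e-10)


def test_ami_symmetry_and_composition(rng):
    x = Partition(rng.integers(0, 3, size=30))
    y = Partition(rng.integers(0, 3, size=30))
    assert cp.ami(x, y) == pytest.approx(cp.ami(y, x))
    mi, hx, hy, t = cp.mutual_information(x, y)
    emi = cp.expected_mi(t.row_marginals, t.col_marginals, 30)
    assert cp.ami(x, y) == pytest.approx((mi - emi) / (max(hx, hy) - emi))


# ---------------------------------------------------------------------------
# minimal-cover Dice
# ---------------------------------------------------------------------------


def test_dice_exact_region_match():
    y = Partition(np.array([0, 0, 0, 1, 1]))
    assert cp.dice_min_cover([0, 1, 2], y) == 1.0


def test_dice_split_region():
    # |X| = 10 split 6/4 across two y-regions of size 10 each
    y = Partition(np.repeat([0, 1, 2], [10, 10, 10]))
    x = list(range(4, 10)) + list(range(10, 14))
    assert cp.dice_min_cover(x, y) == pytest.approx(2 / 3)


def test_dice_single_region_cover_closed_form():
    K = 25
    y = Partition(np.zeros(K, dtype=int))
    x = list(range(7))
    assert cp.dice_min_cover(x, y) == pytest.approx(2 * 7 / (7 + K))


def test_dice_rejects_empty_region():
    with pytest.raises(ValueError):
        cp.dice_min_cover([], Partition(np.array([0, 1])))


# ---------------------------------------------------------------------------
# symmetry and contiguity
# ---------------------------------------------------------------------------


def test_symmetry_of_mirrored_labeling(mesh1):
    part = cp.planted_parcellation(mesh1, 6, seed=0, mirrored=True)
    assert cp.hemispheric_symmetry(part, mesh1) == 1.0


def test_symmetry_of_randomized_right_hemisphere(mesh1):
    rng = np.random.default_rng(3)
    part = cp.planted_parcellation(mesh1, 6, seed=0, mirrored=True)
    labels = part.labels.copy()
    right = mesh1.vertices_of(cp.RIGHT)
    labels[right] = rng.integers(10, 14, size=right.size)
    assert abs(cp.hemispheric_symmetry(Partition(labels), mesh1)) <= 0.15


def test_contiguity_one_label_per_hemisphere(mesh1):
    assert cp.contiguity(Partition(mesh1.hemisphere.astype(int)), mesh1) == 1.0


def test_contiguity_island_fraction_matches_component_oracle(mesh1):
    """A parcel with a detached island scores the exact oracle fraction."""
    K = mesh1.vertex_count
    labels = mesh1.hemisphere.astype(int).copy()
    # move a connected 5-vertex patch of the right hemisphere into label 0
    right0 = int(mesh1.vertices_of(cp.RIGHT)[0])
    adj = mesh1.adjacency
    patch = [right0] + list(adj.indices[adj.indptr[right0] : adj.indptr[right0 + 1]][:4])
    labels[patch] = 0
    part = Partition(labels)
    # independent oracle: networkx connected components per label
    G = nx.from_scipy_sparse_array(adj)
    good = 0
    for lab in np.unique(labels):
        nodes = np.flatnonzero(labels == lab)
        if nx.number_connected_components(G.subgraph(nodes.tolist())) == 1:
            good += nodes.size
    assert cp.contiguity(part, mesh1) == pytest.approx(good / K)
    assert cp.contiguity(part, mesh1) < 1.0


def test_contiguity_relabeling_invariant(mesh1, rng):
    part = cp.planted_parcellation(mesh1, 8, seed=2)
    shifted = Partition(part.labels + 5)
    assert cp.contiguity(part, mesh1) == cp.contiguity(shifted, mesh1)


# ---------------------------------------------------------------------------
# coarse-graph characteristics
# ---------------------------------------------------------------------------


def test_complete_graph_characteristics():
    K5 = np.ones((5, 5)) - np.eye(5)
    cc, apl = cp.graph_characteristics(cp.CoarseConnectome(K5, np.ones(5, dtype=int)))
    assert cc == pytest.approx(1.0)
    assert apl == pytest.approx(1.0)


def test_path_graph_characteristics():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    cc, apl = cp.graph_characteristics(cp.CoarseConnectome(w, np.ones(3, dtype=int)))
    assert cc == pytest.approx(0.0)
    assert apl == pytest.approx((1 + 1 + 2) / 3)


def test_characteristics_weight_scaling():
    rng = np.random.default_rng(1)
    w = np.triu(rng.random((6, 6)) + 0.1, 1)
    w = w + w.T
    sizes = np.ones(6, dtype=int)
    cc1, apl1 = cp.graph_characteristics(cp.CoarseConnectome(w, sizes))
    cc2, apl2 = cp.graph_characteristics(cp.CoarseConnectome(3.0 * w, sizes))
    assert cc2 == pytest.approx(cc1)  # max-rescaled: scale-invariant
    assert apl2 == pytest.approx(apl1 / 3.0)  # lengths 1/weight


def test_characteristics_need_three_nodes():
    with pytest.raises(ValueError):
        cp.graph_characteristics(cp.CoarseConnectome(np.zeros((2, 2)), np.ones(2, dtype=int)))


# ---------------------------------------------------------------------------
# ensemble goodness
# ---------------------------------------------------------------------------


def test_goodness_of_self_cohort():
    c = Partition(np.array([0, 0, 1, 1, 2]))
    assert cp.ensemble_goodness(c, [c] * 5) == 1.0


def test_goodness_bounded_and_he_competitive(mesh1):
    truth = cp.planted_parcellation(mesh1, 6, seed=4)
    rngs = [np.random.default_rng(s) for s in range(8)]
    cohort = [cp.noisy_partition(truth, mesh1, 0.15, r) for r in rngs]
    he = cp.hard_ensemble(cohort)
    g_he = cp.ensemble_goodness(he, cohort)
    assert g_he <= 1.0
    for c in cohort:
        assert g_he >= cp.ensemble_goodness(c, cohort) - 0.05
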