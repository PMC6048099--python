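"""Weighted graph metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longscn import metrics as gm

from conftest import random_weight_matrix
from oracles import exhaustive_best_modularity, floyd_warshall, onnela_clustering


def test_strengths_row_sums(triangle_weights, k4_half):
    s, mean = gm.nodal_strengths(triangle_weights)
    np.testing.assert_allclose(s, [1.4, 1.0, 0.8])
    assert mean == pytest.approx(1.0666666666666667)
    s4, _ = gm.nodal_strengths(k4_half)
    np.testing.assert_allclose(s4, 1.5)
    s0, _ = gm.nodal_strengths(np.zeros((3, 3)))
    np.testing.assert_array_equal(s0, 0.0)


def test_clustering_closed_forms(triangle_weights):
    # equal-weight triangle: fully connected neighbourhoods
    tri = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    np.testing.assert_allclose(gm.clustering_coefficients(tri)[0], 1.0)
    # star: no closed triangles
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 0.7
    np.testing.assert_allclose(gm.clustering_coefficients(star)[0], 0.0)
    # worked triangle: C = (1 * 0.75 * 0.25)^(1/3) for every node
    expected = (1.0 * 0.75 * 0.25) ** (1 / 3)
    np.testing.assert_allclose(
        gm.clustering_coefficients(triangle_weights)[0], expected, atol=1e-12
    )


@pytest.mark.parametrize("seed", range(10))
def test_clustering_matches_direct_onnela_sum(seed):
    rng = np.random.default_rng(seed)
    w = random_weight_matrix(8, rng, density=0.7)
    c, _ = gm.clustering_coefficients(w)
    np.testing.assert_allclose(c, onnela_clustering(w), atol=1e-10)


def test_path_lengths_worked_triangle(triangle_weights):
    l = gm.path_length_matrix(triangle_weights)
    # B-C detour through A (1.25 + 1.6667) beats the direct edge (5.0)
    np.testing.assert_allclose(l[0, 1], 1.25)
    np.testing.assert_allclose(l[0, 2], 5 / 3)
    np.testing.assert_allclose(l[1, 2], 1.25 + 5 / 3)
    assert gm.characteristic_path_length(l) == pytest.approx((1.25 + 5 / 3 + 35 / 12) / 3)
    assert gm.global_efficiency(l) == pytest.approx((0.8 + 0.6 + 12 / 35) / 3)


def test_path_length_edge_cases(k4_half):
    # chain with unit weights: lengths add
    chain = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    l = gm.path_length_matrix(chain)
    assert l[0, 2] == pytest.approx(2.0)
    # isolated pair: infinite distance, zero efficiency, L undefined
    iso = np.zeros((2, 2))
    liso = gm.path_length_matrix(iso)
    assert np.isinf(liso[0, 1])
    assert gm.global_efficiency(liso) == 0.0
    with pytest.raises(ValueError, match="disconnected"):
        gm.characteristic_path_length(liso)
    # K4 at weight 0.5: every shortest path is the direct edge, length 2
    l4 = gm.path_length_matrix(k4_half)
    assert gm.characteristic_path_length(l4) == pytest.approx(2.0)
    assert gm.global_efficiency(l4) == pytest.approx(0.5)
    ones = np.ones((5, 5)) - np.eye(5)
    assert gm.characteristic_path_length(gm.path_length_matrix(ones)) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(20))
def test_dijkstra_equals_floyd_warshall(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    w = random_weight_matrix(n, rng, density=float(rng.uniform(0.4, 1.0)))
    np.testing.assert_allclose(
        gm.path_length_matrix(w), floyd_warshall(w), atol=1e-10
    )


def test_local_efficiency_closed_forms(triangle_weights):
    # A's neighbours {B, C} are joined only by the BC edge (w=0.2, l=5)
    el, mean = gm.local_efficiencies(triangle_weights)
    np.testing.assert_allclose(el, [0.2, 0.6, 0.8])
    assert mean == pytest.approx(0.5333333333333333)
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 0.7
    np.testing.assert_allclose(gm.local_efficiencies(star)[0], 0.0)
    ones = np.ones((5, 5)) - np.eye(5)
    np.testing.assert_allclose(gm.local_efficiencies(ones)[0], 1.0)


def test_modularity_two_cliques_and_null():
    two_cliques = np.kron(np.eye(2), np.ones((3, 3)) - np.eye(3))
    q, part = gm.modularity_coefficient(two_cliques, seed=1, restarts=20)
    assert q == pytest.approx(0.5)
    assert sorted(sorted(c) for c in part) == [[0, 1, 2], [3, 4, 5]]
    # exhaustive enumeration agrees this is the global optimum
    q_best, _ = exhaustive_best_modularity(two_cliques)
    assert q == pytest.approx(q_best, abs=1e-12)
    # equal-weight complete graph has no module structure
    k5 = np.ones((5, 5)) - np.eye(5)
    q_null, _ = gm.modularity_coefficient(k5, seed=1, restarts=20)
    assert q_null >= 0.0
    assert q_null <= exhaustive_best_modularity(k5)[0] + 1e-12
    with pytest.raises(ValueError):
        gm.modularity_coefficient(np.zeros((4, 4)), seed=0)


@pytest.mark.parametrize("seed", range(8))
def test_louvain_near_exhaustive_optimum(seed):
    rng = np.random.default_rng(seed)
    w = random_weight_matrix(int(rng.integers(5, 9)), rng, density=0.6)
    if w.sum() == 0:
        pytest.skip("empty graph drawn")
    q, _ = gm.modularity_coefficient(w, seed=seed, restarts=50)
    q_best, _ = exhaustive_best_modularity(w)
    assert q >= q_best - 0.02
    assert q <= q_best + 1e-10


def test_modularity_beats_random_partitions_on_equicorrelation():
    rng = np.random.default_rng(7)
    import networkx as nx

    x = rng.multivariate_normal(
        np.zeros(10), np.full((10, 10), 0.5) + 0.5 * np.eye(10), size=30
    )
    w = np.abs(np.corrcoef(x, rowvar=False))
    np.fill_diagonal(w, 0.0)
    q, _ = gm.modularity_coefficient(w, seed=3, restarts=20)
    g = nx.from_numpy_array(w)
    for _ in range(100):
        labels = rng.integers(0, 3, size=10)
        part = [set(np.flatnonzero(labels == k)) for k in range(3)]
        part = [p for p in part if p]
        assert q >= nx.community.modularity(g, part, weight="weight") - 1e-12


def test_summarize_network_composition(triangle_weights, k4_half):
    ms = gm.summarize_network(k4_half, seed=0, restarts=20)
    assert ms.network_level() == pytest.approx(
        {
            "mean_strength": 1.5,
            "mean_clustering": 1.0,
            "char_path_length": 2.0,
            "global_efficiency": 0.5,
            # neighbour subgraphs of K4 at weight 0.5 have all l_jh = 2,
            # so the literal subgraph formula gives 0.5 (it equals 1 only
            # at unit weights)
            "local_efficiency": 0.5,
            "modularity": 0.0,
        },
        abs=1e-10,
    )
    ms_tri = gm.summarize_network(triangle_weights, seed=0, restarts=20)
    assert ms_tri.mean_strength == pytest.approx(1.0666666666666667)
    assert ms_tri.mean_clustering == pytest.approx((0.1875) ** (1 / 3))
    assert ms_tri.char_path_length == pytest.approx(1.9444444444444446)
    assert ms_tri.global_efficiency == pytest.approx(0.580952380952381)
    assert ms_tri.local_efficiency == pytest.approx(0.5333333333333333)
    assert set(ms_tri.network_level()) == set(gm.METRIC_NAMES)
    assert set(ms_tri.nodal()) == {"strength", "clustering", "local_efficiency"}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), c=st.floats(0.1, 3.0))
def test_scale_behaviour(seed, c):
    """Scaling all weights by c: strength and E_glob scale by c, L by 1/c,
    Onnela clustering and modularity are invariant."""
    rng = np.random.default_rng(seed)
    w = random_weight_matrix(7, rng)
    l1 = gm.path_length_matrix(w)
    l2 = gm.path_length_matrix(c * w)
    np.testing.assert_allclose(
        gm.nodal_strengths(c * w)[0], c * gm.nodal_strengths(w)[0], rtol=1e-10
    )
    assert gm.characteristic_path_length(l2) == pytest.approx(
        gm.characteristic_path_length(l1) / c
    )
    assert gm.global_efficiency(l2) == pytest.approx(c * gm.global_efficiency(l1))
    np.testing.assert_allclose(
        gm.clustering_coefficients(c * w)[0],
        gm.clustering_coefficients(w)[0],
        rtol=1e-10,
    )
    q1, _ = gm.modularity_coefficient(w, seed=0, restarts=5)
    q2, _ = gm.modularity_coefficient(c * w, seed=0, restarts=5)
    assert q1 == pytest.approx(q2, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_weight_increase_monotonicity_and_jensen(seed):
    """Raising one weight never lengthens any shortest path or lowers
    E_glob; and E_glob >= 1/L on every connected network (Jensen)."""
    rng = np.random.default_rng(seed)
    w = random_weight_matrix(6, rng)
    l1 = gm.path_length_matrix(w)
    assert gm.global_efficiency(l1) >= 1.0 / gm.characteristic_path_length(l1) - 1e-12
    i, j = rng.integers(0, 6, size=2)
    while i == j:
        j = rng.integers(0, 6)
    w2 = w.copy()
    w2[i, j] = w2[j, i] = min(1.0, w[i, j] + rng.uniform(0.05, 0.5))
    l2 = gm.path_length_matrix(w2)
    assert (l2 <= l1 + 1e-12).all()
    assert gm.global_efficiency(l2) >= gm.global_efficiency(l1) - 1e-12


def test_binary_clustering_flag():
    # binary form on a weighted triangle-plus-leaf
    w = np.array(
        [
            [0, 0.9, 0.4, 0.2],
            [0.9, 0, 0.7, 0],
            [0.4, 0.7, 0, 0],
            [0.2, 0, 0, 0],
        ]
    )
    c, _ = gm.clustering_coefficients(w, weighted=False)
    # node 0 has neighbours {1,2,3}: of 6 ordered pairs only (1,2),(2,1) close
    np.testing.assert_allclose(c, [2 / 6, 1.0, 1.0, 0.0])
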