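"""Structural indices: closed-form fixtures, brute-force oracles, invariants.

Oracles are independent of the implementation: networkx for traversal-based
quantities, Floyd-Warshall for distances, exhaustive geodesic enumeration
for betweenness, dense eigendecomposition for the Perron vector.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from herdnet import (
    ValidationError,
    betweenness_centrality,
    closeness_centrality,
    clustering_coefficient,
    count_components,
    degree_centrality,
    density,
    eigenvector_centrality,
    local_clustering,
)

from conftest import network_from_edges, random_network

PATH3 = [(0, 1), (1, 2)]
PATH4 = [(0, 1), (1, 2), (2, 3)]
TRIANGLE = [(0, 1), (1, 2), (0, 2)]
STAR3 = [(0, 1), (0, 2), (0, 3)]  # center 0
K4 = list(itertools.combinations(range(4), 2))
K4_MINUS_EDGE = [e for e in K4 if e != (0, 1)]
K5 = list(itertools.combinations(range(5), 2))


# ---------------------------------------------------------------------------
# Closed-form fixtures


@pytest.mark.parametrize(
    "n,edges,expected",
    [
        (4, K4, 1.0),
        (91, [], 0.0),
        (3, PATH3, 2 * 2 / 6),  # path on 3 vertices: 4/(9-3)
    ],
)
def test_density_closed_forms(n, edges, expected):
    assert density(network_from_edges(n, edges)) == pytest.approx(expected)


def test_density_undefined_below_two_vertices():
    with pytest.raises(ValidationError):
        density(network_from_edges(1, []))


@pytest.mark.parametrize(
    "n,edges,expected",
    [
        (91, [], 91),
        (5, [(0, 1), (2, 3)], 3),
        (4, PATH4, 1),
    ],
)
def test_component_counts(n, edges, expected):
    assert count_components(network_from_edges(n, edges)) == expected


@pytest.mark.parametrize(
    "n,edges,expected",
    [
        (3, TRIANGLE, 1.0),
        (4, STAR3, 0.0),
        (4, K4_MINUS_EDGE, (1 + 1 + 2 / 3 + 2 / 3) / 4),
    ],
)
def test_clustering_closed_forms(n, edges, expected):
    assert clustering_coefficient(network_from_edges(n, edges)) == pytest.approx(
        expected
    )


def test_clustering_low_degree_exclusion_switch():
    # path on 3: middle vertex has degree 2 and CC=0; endpoints excluded
    net = network_from_edges(3, PATH3)
    assert clustering_coefficient(net, include_low_degree=False) == 0.0
    tri_plus_isolate = network_from_edges(4, TRIANGLE)
    assert clustering_coefficient(tri_plus_isolate) == pytest.approx(3 / 4)
    assert clustering_coefficient(
        tri_plus_isolate, include_low_degree=False
    ) == pytest.approx(1.0)


def test_degree_star_and_isolate():
    deg = degree_centrality(network_from_edges(5, [(0, i) for i in range(1, 5)]))
    assert deg.tolist() == [4, 1, 1, 1, 1]


@pytest.mark.parametrize(
    "n,edges,vertex,expected",
    [
        (3, PATH3, 1, 1 / 2),  # middle of path: distances 1+1
        (3, PATH3, 0, 1 / 3),  # endpoint: 1+2
        (4, PATH4, 0, 1 / 6),  # endpoint of P4: 1+2+3
    ],
)
def test_closeness_closed_forms(n, edges, vertex, expected):
    assert closeness_centrality(network_from_edges(n, edges))[vertex] == pytest.approx(
        expected
    )


def test_closeness_empty_network_is_zero():
    assert closeness_centrality(network_from_edges(6, [])).tolist() == [0.0] * 6


@pytest.mark.parametrize(
    "n,edges,vertex,expected",
    [
        (4, PATH4, 1, 2.0),  # pairs {0,2}, {0,3}
        (4, STAR3, 0, 3.0),  # all three leaf pairs
        (5, K5, 0, 0.0),  # complete graph: all geodesics direct
    ],
)
def test_betweenness_closed_forms(n, edges, vertex, expected):
    assert betweenness_centrality(network_from_edges(n, edges))[vertex] == pytest.approx(
        expected
    )


def test_eigenvector_complete_graph_uniform():
    e = eigenvector_centrality(network_from_edges(5, K5))
    assert e == pytest.approx(np.ones(5))


def test_eigenvector_star_closed_form():
    e = eigenvector_centrality(network_from_edges(4, STAR3))
    assert e[0] == pytest.approx(1.0)
    assert e[1:] == pytest.approx(np.full(3, 1 / np.sqrt(3)), abs=1e-8)


def test_eigenvector_empty_network_all_zero():
    assert eigenvector_centrality(network_from_edges(8, [])).tolist() == [0.0] * 8


def test_eigenvector_subdominant_component_exactly_zero():
    # triangle (leading eigenvalue 2) + single edge (eigenvalue 1)
    net = network_from_edges(5, TRIANGLE + [(3, 4)])
    e = eigenvector_centrality(net)
    assert e[:3] == pytest.approx(np.ones(3))
    assert e[3] == 0.0 and e[4] == 0.0


def test_eigenvector_tied_components_both_keep_mass():
    net = network_from_edges(6, TRIANGLE + [(3, 4), (4, 5), (3, 5)])
    e = eigenvector_centrality(net)
    assert e == pytest.approx(np.ones(6))


# ---------------------------------------------------------------------------
# Brute-force oracles


def oracle_distances(adj):
    """Floyd-Warshall on the binary adjacency."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def oracle_betweenness(adj):
    """Exhaustive enumeration of all geodesic paths via simple-path search."""
    n = adj.shape[0]
    g = nx.from_numpy_array(adj)
    d = oracle_distances(adj)
    bc = np.zeros(n)
    for j, k in itertools.combinations(range(n), 2):
        if not np.isfinite(d[j, k]):
            continue
        geodesics = [
            p
            for p in nx.all_simple_paths(g, j, k, cutoff=int(d[j, k]))
            if len(p) - 1 == d[j, k]
        ]
        if d[j, k] == 0 or not geodesics:
            continue
        for i in range(n):
            if i in (j, k):
                continue
            through = sum(i in p for p in geodesics)
            bc[i] += through / len(geodesics)
    return bc


def oracle_eigenvector(adj):
    """Dense eigendecomposition; Perron vector of the leading eigenvalue."""
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    active = np.flatnonzero(deg > 0)
    out = np.zeros(n)
    if active.size == 0:
        return out
    g = nx.from_numpy_array(adj)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    best = []
    for comp in comps:
        sub = adj[np.ix_(comp, comp)].astype(float)
        w, v = np.linalg.eigh(sub)
        vec = np.abs(v[:, -1])
        best.append((w[-1], comp, vec / vec.max()))
    z_max = max(z for z, _, _ in best)
    for z, comp, vec in best:
        if z >= z_max - 1e-9:
            out[comp] = vec
    return out


@pytest.mark.parametrize("trial", range(60))
def test_indices_match_oracles_on_random_small_graphs(trial):
    """All six indices agree with independent oracles on random N<=7 graphs."""
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(2, 8))
    net = random_network(rng, n, p=float(rng.uniform(0.15, 0.8)))
    adj = net.adjacency
    g = nx.from_numpy_array(adj)

    assert density(net) == pytest.approx(nx.density(g), abs=1e-12)
    assert count_components(net) == nx.number_connected_components(g)
    assert clustering_coefficient(net) == pytest.approx(
        nx.average_clustering(g), abs=1e-12
    )
    assert degree_centrality(net).tolist() == [g.degree(i) for i in range(n)]

    d = oracle_distances(adj)
    expected_closeness = [
        0.0 if not np.isfinite(s) or s == 0 else 1.0 / s
        for s in [d[i][np.isfinite(d[i])].sum() for i in range(n)]
    ]
    # a vertex alone in its component has finite 0 distance sum -> 0
    expected_closeness = [
        0.0 if g.degree(i) == 0 else c for i, c in enumerate(expected_closeness)
    ]
    assert closeness_centrality(net) == pytest.approx(
        np.array(expected_closeness), abs=1e-8
    )

    assert betweenness_centrality(net) == pytest.approx(
        oracle_betweenness(adj), abs=1e-8
    )
    assert eigenvector_centrality(net) == pytest.approx(
        oracle_eigenvector(adj), abs=1e-8
    )


# ---------------------------------------------------------------------------
# Invariants


def test_permutation_equivariance():
    rng = np.random.default_rng(77)
    net = random_network(rng, 12, p=0.3)
    perm = rng.permutation(12)
    adj_p = net.adjacency[np.ix_(perm, perm)]
    net_p = network_from_edges(
        12, list(zip(*np.nonzero(np.triu(adj_p, 1))))
    )
    assert density(net) == pytest.approx(density(net_p))
    assert count_components(net) == count_components(net_p)
    for fn in (degree_centrality, closeness_centrality, betweenness_centrality,
               eigenvector_centrality, local_clustering):
        np.testing.assert_allclose(fn(net)[perm], fn(net_p), atol=1e-8)


def test_adding_edge_monotonicity():
    rng = np.random.default_rng(3)
    for _ in range(20):
        net = random_network(rng, 8, p=0.25)
        zeros = np.argwhere(np.triu(net.adjacency == 0, 1))
        if not len(zeros):
            continue
        i, j = zeros[rng.integers(len(zeros))]
        denser = network_from_edges(
            8, list(zip(*np.nonzero(np.triu(net.adjacency, 1)))) + [(i, j)]
        )
        assert density(denser) > density(net)
        assert count_components(denser) <= count_components(net)
        assert (degree_centrality(denser) >= degree_centrality(net)).all()


def test_eigenvector_satisfies_eigen_equation_on_dominant_component():
    rng = np.random.default_rng(8)
    for _ in range(10):
        net = random_network(rng, 10, p=0.3)
        e = eigenvector_centrality(net)
        support = e > 0
        if not support.any():
            continue
        sub = net.adjacency[np.ix_(support.nonzero()[0], support.nonzero()[0])]
        v = e[support]
        z = v @ (sub @ v) / (v @ v)
        assert np.abs(sub @ v - z * v).max() < 1e-8


def test_closeness_orders_like_mean_geodesic_distance_on_connected_graph():
    rng = np.random.default_rng(12)
    net = network_from_edges(6, PATH4 + [(3, 4), (4, 5)])
    d = oracle_distances(net.adjacency)
    mean_dist = d.sum(axis=1) / (net.n_vertices - 1)
    cl = closeness_centrality(net)
    assert np.argsort(np.argsort(cl)).tolist() == np.argsort(
        np.argsort(-mean_dist)
    ).tolist()
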