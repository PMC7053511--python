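"""Global and local structural indices of binary proximity networks.

Three global indices describe each network as a whole:

* density  D = sum_ij a_ij / (N^2 - N) — the fraction of realized edges;
* number of connected components (isolated vertices count as singleton
  components, so an empty N-vertex network has N components);
* clustering coefficient  CC = (1/N) sum_i CC_i, with CC_i the fraction
  of vertex i's neighbour pairs that are themselves connected; CC_i is 0
  when deg_i < 2 and, by default, still enters the N-average.

Four vertex centralities describe individual positions:

* degree       deg_i = sum_j a_ij — direct proximity partners;
* closeness    Cl_i = 1 / sum_j d_ij, with d_ij geodesic (unweighted)
  distances; on fragmented networks the sum runs over vertices reachable
  from i, and isolated vertices get 0 (the strict formula is infinite
  across components);
* betweenness  b_i = sum over unordered pairs {j,k} (j != i != k) of the
  fraction of geodesics between j and k passing through i — Freeman's raw
  (unnormalized) sum, computed with Brandes' accumulation;
* eigenvector  e_i: the Perron-Frobenius eigenvector of the adjacency
  matrix, max-normalized to 1; vertices in components whose leading
  eigenvalue is not attained get 0 (empty network: all 0).

All computations are restricted to the non-isolated subgraph where
possible, since the activity-stratified ensemble is dominated by networks
in which most of the herd is isolated.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import NetworkEnsemble, ProximityNetwork
from .records import ValidationError

#: Ordered names of the global and local indices.
GLOBAL_INDICES = ("density", "n_components", "clustering")
LOCAL_INDICES = ("degree", "closeness", "betweenness", "eigenvector")


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration cap."""


# ---------------------------------------------------------------------------
# Global indices


def density(network: ProximityNetwork) -> float:
    """Edge density sum_ij a_ij / (N^2 - N); requires N >= 2."""
    n = network.n_vertices
    if n < 2:
        raise ValidationError("density is undefined for networks with N < 2")
    return float(network.adjacency.sum()) / (n * n - n)


def _adjacency_lists(adj: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(adj[i]) for i in range(adj.shape[0])]


def _active_components(adj: np.ndarray) -> list[list[int]]:
    """Connected components of the non-isolated subgraph (BFS), as vertex lists."""
    active = np.flatnonzero(adj.sum(axis=1) > 0)
    neighbors = {int(i): np.flatnonzero(adj[i]) for i in active}
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in active:
        start = int(start)
        if start in seen:
            continue
        comp = [start]
        queue = deque([start])
        seen.add(start)
        while queue:
            u = queue.popleft()
            for v in neighbors[u]:
                v = int(v)
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    queue.append(v)
        comps.append(comp)
    return comps


def count_components(network: ProximityNetwork) -> int:
    """Number of connected components (BFS; isolates are singletons)."""
    adj = network.adjacency
    n = adj.shape[0]
    n_isolates = n - int((adj.sum(axis=1) > 0).sum())
    return len(_active_components(adj)) + n_isolates


def local_clustering(network: ProximityNetwork) -> np.ndarray:
    """Per-vertex clustering CC_i (0 for degree < 2)."""
    adj = network.adjacency
    n = adj.shape[0]
    cc = np.zeros(n)
    deg = adj.sum(axis=1)
    for i in np.flatnonzero(deg >= 2):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        links = int(adj[np.ix_(nbrs, nbrs)].sum()) // 2
        cc[i] = 2.0 * links / (k * (k - 1))
    return cc


def clustering_coefficient(
    network: ProximityNetwork, *, include_low_degree: bool = True
) -> float:
    """Average clustering CC = (1/N) sum_i CC_i.

    With ``include_low_degree`` (default) every vertex enters the average
    and vertices with degree < 2 contribute 0, matching a plain division
    by N; with False the average runs over degree >= 2 vertices only
    (0 if there are none).
    """
    cc = local_clustering(network)
    if include_low_degree:
        return float(cc.mean()) if cc.size else 0.0
    deg = network.adjacency.sum(axis=1)
    eligible = deg >= 2
    return float(cc[eligible].mean()) if eligible.any() else 0.0


# ---------------------------------------------------------------------------
# Local centralities


def degree_centrality(network: ProximityNetwork) -> np.ndarray:
    """Row sums of the adjacency matrix, as integers."""
    return network.adjacency.sum(axis=1).astype(np.int64)


def _bfs_distances(neighbors: dict[int, np.ndarray], source: int) -> dict[int, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in neighbors[u]:
            v = int(v)
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def closeness_centrality(network: ProximityNetwork) -> np.ndarray:
    """Cl_i = 1 / sum of geodesic distances to vertices reachable from i.

    Isolated vertices (nothing reachable) get 0.
    """
    adj = network.adjacency
    n = adj.shape[0]
    out = np.zeros(n)
    active = np.flatnonzero(adj.sum(axis=1) > 0)
    neighbors = {int(i): np.flatnonzero(adj[i]) for i in active}
    for i in active:
        i = int(i)
        total = sum(_bfs_distances(neighbors, i).values())  # self contributes 0
        out[i] = 1.0 / total
    return out


def betweenness_centrality(network: ProximityNetwork) -> np.ndarray:
    """Freeman betweenness b_i over unordered pairs, endpoints excluded.

    Brandes' algorithm: one BFS + dependency accumulation per source on
    the non-isolated subgraph; the undirected double count is halved.
    No normalization is applied.
    """
    adj = network.adjacency
    n = adj.shape[0]
    bc = np.zeros(n)
    active = [int(i) for i in np.flatnonzero(adj.sum(axis=1) > 0)]
    neighbors = {i: [int(v) for v in np.flatnonzero(adj[i])] for i in active}
    for s in active:
        stack: list[int] = []
        preds: dict[int, list[int]] = {v: [] for v in active}
        sigma = {v: 0.0 for v in active}
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for v in neighbors[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = {v: 0.0 for v in active}
        while stack:
            w = stack.pop()
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


def eigenvector_centrality(
    network: ProximityNetwork,
    *,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    tie_tol: float = 1e-9,
) -> np.ndarray:
    """Perron-Frobenius eigenvector, max-normalized to 1.

    The Perron vector and leading eigenvalue are computed per connected
    component by power iteration on A + I from the all-ones vector (the
    identity shift makes the Perron eigenvalue strictly dominant within a
    component, so bipartite components — stars, chains — converge too,
    without changing the eigenvectors).  Only the component(s) attaining
    the network's largest eigenvalue carry mass: every other component is
    exactly 0, as are isolated vertices.  Components tied for the leading
    eigenvalue (within ``tie_tol`` relative) each keep their Perron
    vector, max-normalized to 1 — a deterministic convention for a case
    the strict formula leaves open.  Empty network: all zeros.
    """
    adj = network.adjacency
    n = adj.shape[0]
    out = np.zeros(n)
    solutions: list[tuple[float, list[int], np.ndarray]] = []
    for comp in _active_components(adj):
        sub = adj[np.ix_(comp, comp)].astype(float)
        x = np.ones(len(comp))
        for _ in range(max_iter):
            y = sub @ x + x  # (A + I) x
            scale = y.max()
            y /= scale
            if np.abs(y - x).max() < tol:
                x = y
                break
            x = y
        else:
            residual = float(np.abs(sub @ x + x - scale * x).max())
            raise ConvergenceError(
                f"power iteration did not converge in {max_iter} iterations "
                f"on a {len(comp)}-vertex component (residual {residual:.3e})"
            )
        z = float(x @ (sub @ x) / (x @ x))  # Rayleigh quotient on A
        solutions.append((z, comp, x))
    if not solutions:
        return out
    z_max = max(z for z, _, _ in solutions)
    for z, comp, x in solutions:
        if z >= z_max - tie_tol * max(1.0, abs(z_max)):
            out[comp] = x
    return out


# ---------------------------------------------------------------------------
# Index table over an ensemble


@dataclass(frozen=True)
class IndexTable:
    """Per-network global indices and per-(network, vertex) centralities.

    ``globals_`` has one row per network (columns: network_id, activity,
    period, density, n_components, clustering); ``locals_`` one row per
    (network, vertex) (columns: network_id, activity, period, animal_id,
    degree, closeness, betweenness, eigenvector).
    """

    globals_: pd.DataFrame
    locals_: pd.DataFrame


def compute_indices(
    network: ProximityNetwork, *, cc_include_low_degree: bool = True
) -> tuple[dict, np.ndarray]:
    """All indices of one network: (global dict, local array (N, 4))."""
    glob = {
        "density": density(network),
        "n_components": count_components(network),
        "clustering": clustering_coefficient(
            network, include_low_degree=cc_include_low_degree
        ),
    }
    loc = np.column_stack(
        [
            degree_centrality(network),
            closeness_centrality(network),
            betweenness_centrality(network),
            eigenvector_centrality(network),
        ]
    )
    return glob, loc


def compute_index_table(
    ensemble: NetworkEnsemble, *, cc_include_low_degree: bool = True
) -> IndexTable:
    """Index every network of the ensemble.

    Yields 7 x P global rows and 7 x P x N local rows (the default
    campaign: 1680 and 152,880).  Empty networks take the degenerate
    conventions (density 0, N components, clustering 0, all centralities
    0) without any traversal.
    """
    g_rows = []
    l_blocks = []
    ids = np.asarray(ensemble.vertex_ids, dtype=object)
    n = len(ids)
    for net in ensemble:
        glob, loc = compute_indices(net, cc_include_low_degree=cc_include_low_degree)
        g_rows.append(
            {
                "network_id": net.network_id,
                "activity": net.activity,
                "period": net.period_id,
                **glob,
            }
        )
        block = pd.DataFrame(loc, columns=list(LOCAL_INDICES))
        block.insert(0, "animal_id", ids)
        block.insert(0, "period", net.period_id)
        block.insert(0, "activity", net.activity)
        block.insert(0, "network_id", net.network_id)
        l_blocks.append(block)
    globals_ = pd.DataFrame(g_rows)
    locals_ = pd.concat(l_blocks, ignore_index=True)
    locals_["degree"] = locals_["degree"].astype(np.int64)
    return IndexTable(globals_=globals_, locals_=locals_)
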