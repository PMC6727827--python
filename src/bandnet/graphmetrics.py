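"""Global and nodal graph measures on binary undirected networks.

Everything here is implemented directly on the adjacency matrix — BFS hop
distances, Brandes betweenness, triangle-census clustering, Latora-Marchiori
efficiencies, and small-worldness against degree-preserving rewired
surrogates.  Cost-thresholded connectomes at low cost are routinely
disconnected, so path-based measures average over *reachable* pairs only
and the excluded fraction is reported alongside.

Nodal feature vectors are assembled per band in the fixed block order
ND (degree), BC (betweenness), NL (nodal path length), 90 ROIs each:
270 features per band, 810 when the three bands are concatenated.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from .connectome import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "NodalFeatures",
    "shortest_paths",
    "nodal_path_length",
    "nodal_degree",
    "betweenness",
    "clustering",
    "global_efficiency",
    "local_efficiency",
    "char_path_length",
    "small_worldness",
    "rewired_surrogate",
    "extract_features",
    "global_metrics",
    "GLOBAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = (
    "global_efficiency",
    "local_efficiency",
    "char_path_length",
    "avg_clustering",
    "small_worldness",
)


@dataclass(frozen=True)
class GlobalMetrics:
    global_efficiency: float
    local_efficiency: float
    char_path_length: float
    avg_clustering: float
    small_worldness: float
    excluded_pair_fraction: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in GLOBAL_METRIC_NAMES}


@dataclass(frozen=True)
class NodalFeatures:
    """Per-node degree (nd), betweenness (bc) and path length (nl)."""

    nd: np.ndarray
    bc: np.ndarray
    nl: np.ndarray

    def concatenate(self) -> np.ndarray:
        """Feature row in the fixed ND | BC | NL block order."""
        return np.concatenate([self.nd.astype(float), self.bc, self.nl])


# ---------------------------------------------------------------------------
# distances


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs hop distances by BFS level expansion; inf if unreachable."""
    a = net.adjacency.astype(np.int32)
    n = net.n_nodes
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        frontier = ((frontier.astype(np.int32) @ a) > 0) & ~reached
        dist[frontier] = d
        reached |= frontier
    return dist


def nodal_path_length(net: BinaryNetwork, dist: np.ndarray | None = None) -> np.ndarray:
    """Mean hop distance from each node to the nodes it can reach.

    An isolated node has no reachable partner; its value is 0 and a warning
    is emitted, so the convention is visible rather than silent.
    """
    if dist is None:
        dist = shortest_paths(net)
    n = dist.shape[0]
    finite = np.isfinite(dist) & ~np.eye(n, dtype=bool)
    counts = finite.sum(axis=1)
    sums = np.where(finite, dist, 0.0).sum(axis=1)
    nl = np.zeros(n)
    ok = counts > 0
    nl[ok] = sums[ok] / counts[ok]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} isolated node(s); nodal path length set to 0 there",
            stacklevel=2,
        )
    return nl


def nodal_degree(net: BinaryNetwork) -> np.ndarray:
    return net.adjacency.sum(axis=1).astype(np.int64)


def betweenness(net: BinaryNetwork) -> np.ndarray:
    """Unnormalized shortest-path betweenness over unordered pairs.

    Brandes' accumulation: one BFS per source with shortest-path counts,
    dependencies propagated back down the BFS tree.  Multiple shortest
    paths contribute fractionally.  O(n*m).
    """
    a = net.adjacency
    n = net.n_nodes
    neighbors = [np.flatnonzero(a[i]).tolist() for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1, dtype=np.int64)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair {j,m} was counted from both ends


def clustering(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Binary clustering coefficient per node and its average over all nodes."""
    a = net.adjacency.astype(np.int64)
    k = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 * triangles at i
    denom = k * (k - 1)
    c = np.zeros(a.shape[0])
    ok = denom > 0
    c[ok] = tri2[ok] / denom[ok]
    return c, float(c.mean())


def global_efficiency(net: BinaryNetwork, dist: np.ndarray | None = None) -> float:
    """Mean of 1/d(i,j) over ordered pairs, with 1/inf = 0."""
    if dist is None:
        dist = shortest_paths(net)
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(dist[off] > 0, 1.0 / dist[off], 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean over nodes of the global efficiency of each neighborhood subgraph
    (0 for nodes with fewer than 2 neighbors)."""
    a = net.adjacency
    n = net.n_nodes
    eff = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        sub = BinaryNetwork(adjacency=a[np.ix_(nb, nb)], cost=net.cost)
        eff[i] = global_efficiency(sub)
    return float(eff.mean())


def char_path_length(
    net: BinaryNetwork, dist: np.ndarray | None = None
) -> tuple[float, float]:
    """Mean hop distance over reachable unordered pairs.

    Returns ``(cpl, excluded_fraction)`` where the excluded fraction is the
    share of unordered pairs that are mutually unreachable.  Fails if no
    pair is reachable.
    """
    if dist is None:
        dist = shortest_paths(net)
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("no reachable pair: characteristic path length undefined")
    return float(d[finite].mean()), float(1.0 - finite.mean())


# ---------------------------------------------------------------------------
# small-worldness


def rewired_surrogate(net: BinaryNetwork, rng: np.random.Generator) -> BinaryNetwork:
    """Degree-preserving surrogate by double-edge swaps (10x edges attempts)."""
    a = net.adjacency.copy()
    iu = np.vstack(np.nonzero(np.triu(a, k=1))).T  # edge list (i < j)
    m = iu.shape[0]
    if m < 2:
        raise ValueError("graph has fewer than 2 edges; cannot rewire")
    edges = [tuple(e) for e in iu]
    attempts = 10 * m
    swapped = 0
    for _ in range(attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        (u, v), (x, y) = edges[e1], edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        # propose u-x, v-y
        if len({u, v, x, y}) < 4:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = (min(u, x), max(u, x))
        edges[e2] = (min(v, y), max(v, y))
        swapped += 1
    if swapped == 0:
        raise ValueError("degenerate graph: no valid degree-preserving swaps found")
    return BinaryNetwork(adjacency=a, cost=net.cost)


def small_worldness(net: BinaryNetwork, n_random: int = 100, seed: int = 0) -> float:
    """sigma = (C/C_rand) / (L/L_rand) against degree-preserving surrogates."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    _, c = clustering(net)
    l, _ = char_path_length(net)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for k in range(n_random):
        sur = rewired_surrogate(net, rng)
        _, c_rand[k] = clustering(sur)
        l_rand[k], _ = char_path_length(sur)
    c_bar, l_bar = c_rand.mean(), l_rand.mean()
    if c_bar == 0 or l_bar == 0:
        raise ValueError("degenerate surrogates: zero mean clustering or path length")
    return float((c / c_bar) / (l / l_bar))


# ---------------------------------------------------------------------------
# feature bundling


def extract_features(net: BinaryNetwork) -> NodalFeatures:
    """Nodal degree, betweenness and path length for the feature table."""
    dist = shortest_paths(net)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolated-node convention logged once upstream
        nl = nodal_path_length(net, dist)
    return NodalFeatures(nd=nodal_degree(net), bc=betweenness(net), nl=nl)


def global_metrics(
    net: BinaryNetwork,
    n_random: int = 100,
    seed: int = 0,
    include_small_world: bool = True,
) -> GlobalMetrics:
    """The five global measures bundled; small-worldness optional since it is
    the only stochastic (surrogate-based) one."""
    dist = shortest_paths(net)
    cpl, excl = char_path_length(net, dist)
    _, avg_c = clustering(net)
    sw = small_worldness(net, n_random=n_random, seed=seed) if include_small_world else float("nan")
    return GlobalMetrics(
        global_efficiency=global_efficiency(net, dist),
        local_efficiency=local_efficiency(net),
        char_path_length=cpl,
        avg_clustering=avg_c,
        small_worldness=sw,
        excluded_pair_fraction=excl,
    )
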