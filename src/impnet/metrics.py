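"""Weighted graph-theoretic topology metrics with null-model normalization.

Global measures: clustering coefficient Cp (segregation), characteristic path
length Lp (integration), global and local efficiency, and small-worldness.
Cp and Lp are normalized against the means of an ensemble of degree-matched
random networks (default 100), giving gamma = Cp/Cp_rand and
lambda = Lp/Lp_rand; sigma = gamma/lambda > 1 indicates small-world
architecture (high clustering at near-random path length).

Nodal measures: degree centrality (strength or binary) and betweenness
centrality, each mean-normalized across nodes; hubs are nodes exceeding the
network mean by more than one standard deviation.

Edge weights are converted to distances by d = 1/W (stronger connections are
shorter), the standard convention for structural connectomes.  Weighted
clustering uses the geometric-mean triangle formulation on weights rescaled
by the network maximum, which keeps per-node values in [0, 1] and reduces to
binary clustering on unit-weight graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network import WeightedNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "NullEnsemble",
    "weight_to_distance",
    "shortest_path_matrix",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "degree_centrality",
    "betweenness_centrality",
    "normalize_nodal",
    "identify_hubs",
    "generate_matched_nulls",
    "small_worldness",
    "global_metrics",
    "nodal_metrics",
]


@dataclass
class GlobalMetrics:
    Cp: float
    Lp: float
    E_glob: float
    E_loc: float
    gamma: float
    lambda_: float
    sigma: float
    Cp_rand: float
    Lp_rand: float
    n_unreachable_pairs: int


@dataclass
class NodalMetrics:
    degree: np.ndarray
    betweenness: np.ndarray
    degree_norm: np.ndarray
    betweenness_norm: np.ndarray
    hubs_degree: set[int] = field(default_factory=set)
    hubs_betweenness: set[int] = field(default_factory=set)


@dataclass
class NullEnsemble:
    """Degree-matched randomized surrogates of a source network."""

    networks: list[np.ndarray]
    generator_seed: int
    rewires_per_edge: int


def _as_weights(net) -> np.ndarray:
    if isinstance(net, WeightedNetwork):
        return net.weights
    W = np.asarray(net, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("expected a square weight matrix")
    return W


def weight_to_distance(net) -> np.ndarray:
    """Map weights to path distances: d = 1/W, absent edges -> inf, diag 0."""
    W = _as_weights(net)
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(D, 0.0)
    return D


def shortest_path_matrix(net) -> np.ndarray:
    """All-pairs shortest-path distances under d = 1/W (inf if unreachable)."""
    W = _as_weights(net)
    n = W.shape[0]
    iu, ju = np.nonzero(W)
    with np.errstate(divide="ignore"):
        data = 1.0 / W[iu, ju]
    graph = csr_matrix((data, (iu, ju)), shape=(n, n))
    return dijkstra(graph, directed=False)


def clustering_coefficient(net) -> tuple[float, np.ndarray]:
    """Weighted clustering: geometric mean of triangle weights, max-rescaled.

    Per node i with binary degree k_i >= 2:
        C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3)
    with w' = W / max(W).  Nodes with fewer than two neighbors get 0.
    Returns (mean over all nodes, per-node vector).
    """
    W = _as_weights(net)
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty network")
    wmax = W.max()
    if wmax == 0:
        return 0.0, np.zeros(n)
    cw = np.cbrt(W / wmax)
    k = np.count_nonzero(W, axis=1).astype(float)
    triangles = np.diag(cw @ cw @ cw)  # 2x the triangle intensity per node
    denom = k * (k - 1)
    per_node = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return float(per_node.mean()), per_node


def characteristic_path_length(net) -> tuple[float, int]:
    """Mean shortest-path distance over reachable ordered pairs.

    Returns (Lp, number of unreachable ordered pairs).  Unreachable pairs are
    excluded from the average but counted; a network with no finite path at
    all raises.
    """
    D = shortest_path_matrix(net)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_unreachable = int(off.sum() - finite.sum())
    if not finite.any():
        raise ValueError("no finite paths: network has no edges")
    return float(D[finite].mean()), n_unreachable


def global_efficiency(net) -> float:
    """Mean inverse shortest-path distance over all ordered pairs.

    E_glob = (1/(n(n-1))) * sum_{i != j} 1/d_ij, with 1/inf = 0, so
    disconnection lowers efficiency instead of breaking the average.
    """
    D = shortest_path_matrix(net)
    n = D.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency(net) -> tuple[float, np.ndarray]:
    """Efficiency of each node's neighbor-induced subgraph (weights retained).

    Nodal E_loc(i) is the global efficiency of the subgraph on i's neighbors;
    it measures fault tolerance to removal of node i.  Nodes with fewer than
    two neighbors get 0.  Returns (mean over nodes, per-node vector).
    """
    W = _as_weights(net)
    n = W.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nb = np.nonzero(W[i])[0]
        if nb.size < 2:
            continue
        per_node[i] = global_efficiency(W[np.ix_(nb, nb)])
    return float(per_node.mean()), per_node


def degree_centrality(net, mode: str = "strength") -> np.ndarray:
    """Per-node degree: weight row sums ("strength") or neighbor counts ("binary")."""
    W = _as_weights(net)
    if mode == "strength":
        return W.sum(axis=1)
    if mode == "binary":
        return np.count_nonzero(W, axis=1).astype(float)
    raise ValueError(f"unknown degree mode {mode!r}")


def betweenness_centrality(net) -> np.ndarray:
    """Weighted betweenness: shortest paths under d = 1/W through each node.

    Path multiplicity is shared fractionally among equal-length shortest
    paths; endpoints are excluded.  Unnormalized pair counts are returned
    (each unordered pair counted once); downstream mean-normalization cancels
    any constant factor.
    """
    W = _as_weights(net)
    G = nx.from_numpy_array(W)
    for _, _, d in G.edges(data=True):
        d["dist"] = 1.0 / d["weight"]
    bc = nx.betweenness_centrality(G, normalized=False, weight="dist")
    return np.array([bc[i] for i in range(W.shape[0])])


def normalize_nodal(values) -> np.ndarray:
    """Divide nodal values by their mean so that the normalized mean is 1."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m <= 0:
        raise ValueError("cannot mean-normalize: nodal values have nonpositive mean")
    return v / m


def identify_hubs(values) -> set[int]:
    """Nodes whose value exceeds mean + 1 sample standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("hub detection needs at least 2 nodes")
    thresh = v.mean() + v.std(ddof=1)
    return set(np.nonzero(v > thresh)[0].tolist())


def _swap_edges(
    edges: list[tuple[int, int]], rng: np.random.Generator, n_swaps: int
) -> tuple[list[tuple[int, int]], int]:
    """Degree-preserving double-edge swaps on an undirected edge list."""
    edge_set = {frozenset(e) for e in edges}
    m = len(edges)
    done = 0
    attempts = 0
    max_attempts = max(100 * n_swaps, 1000)
    # draw randomness in blocks; each attempt uses 2 edge picks + 1 coin
    while done < n_swaps and attempts < max_attempts:
        block = min(4096, max_attempts - attempts)
        picks = rng.integers(0, m, size=(block, 2))
        coins = rng.integers(0, 2, size=block)
        for (e1, e2), coin in zip(picks, coins):
            attempts += 1
            if done >= n_swaps:
                break
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if coin:
                c, d = d, c
            # proposed rewiring: (a,b),(c,d) -> (a,c),(b,d)
            if a == c or b == d or a == d or b == c:
                continue
            new1, new2 = frozenset((a, c)), frozenset((b, d))
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(frozenset((a, b)))
            edge_set.discard(frozenset((c, d)))
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = (a, c)
            edges[e2] = (b, d)
            done += 1
    return edges, done


def generate_matched_nulls(
    net,
    n_nulls: int = 100,
    seed: int = 0,
    rewires_per_edge: int = 10,
) -> NullEnsemble:
    """Build degree-matched random surrogates of a weighted network.

    Each null randomizes the binary topology by double-edge swaps (default 10
    successful swaps per edge), which preserves the exact degree sequence,
    then randomly reassigns the original weight multiset to the rewired
    edges.  Reproducible given ``seed``.  If no legal swap exists (e.g. a
    complete graph), the null topology equals the source and a warning is
    emitted.
    """
    W = _as_weights(net)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    present = W[iu, ju] > 0
    src_edges = list(zip(iu[present].tolist(), ju[present].tolist()))
    weights = W[iu, ju][present]
    m = len(src_edges)
    if m < 2:
        raise ValueError("null generation needs at least 2 edges")
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    rng = np.random.default_rng(seed)
    complete = m == n * (n - 1) // 2
    nulls: list[np.ndarray] = []
    for _ in range(n_nulls):
        edges = list(src_edges)
        if complete:
            done = 0
        else:
            edges, done = _swap_edges(edges, rng, rewires_per_edge * m)
        if done == 0:
            warnings.warn(
                "no legal double-edge swap; null topology equals the source network",
                stacklevel=2,
            )
        perm = rng.permutation(m)
        Wn = np.zeros_like(W)
        for (i, j), w in zip(edges, weights[perm]):
            Wn[i, j] = Wn[j, i] = w
        nulls.append(Wn)
    return NullEnsemble(networks=nulls, generator_seed=seed, rewires_per_edge=rewires_per_edge)


def small_worldness(net, ensemble: NullEnsemble) -> tuple[float, float, float]:
    """gamma, lambda, sigma from ensemble-mean normalization.

    gamma = Cp / mean(Cp_null), lambda = Lp / mean(Lp_null),
    sigma = gamma / lambda.  sigma > 1 (with gamma > 1, lambda ~ 1) is the
    small-world criterion.
    """
    if not ensemble.networks:
        raise ValueError("empty null ensemble")
    Cp, _ = clustering_coefficient(net)
    Lp, _ = characteristic_path_length(net)
    cp_rand = float(np.mean([clustering_coefficient(Wn)[0] for Wn in ensemble.networks]))
    lp_rand = float(np.mean([characteristic_path_length(Wn)[0] for Wn in ensemble.networks]))
    if cp_rand <= 0 or lp_rand <= 0:
        raise ValueError("null ensemble has zero mean clustering or path length")
    gamma = Cp / cp_rand
    lambda_ = Lp / lp_rand
    return gamma, lambda_, gamma / lambda_


def global_metrics(
    net,
    n_nulls: int = 100,
    seed: int = 0,
    rewires_per_edge: int = 10,
) -> GlobalMetrics:
    """All global measures for one network, with null normalization."""
    Cp, _ = clustering_coefficient(net)
    Lp, n_unreachable = characteristic_path_length(net)
    eg = global_efficiency(net)
    el, _ = local_efficiency(net)
    ensemble = generate_matched_nulls(net, n_nulls=n_nulls, seed=seed, rewires_per_edge=rewires_per_edge)
    gamma, lambda_, sigma = small_worldness(net, ensemble)
    cp_rand = Cp / gamma
    lp_rand = Lp / lambda_
    return GlobalMetrics(
        Cp=Cp,
        Lp=Lp,
        E_glob=eg,
        E_loc=el,
        gamma=gamma,
        lambda_=lambda_,
        sigma=sigma,
        Cp_rand=cp_rand,
        Lp_rand=lp_rand,
        n_unreachable_pairs=n_unreachable,
    )


def nodal_metrics(net, degree_mode: str = "strength") -> NodalMetrics:
    """Degree and betweenness centrality, mean-normalized, with hub sets."""
    deg = degree_centrality(net, mode=degree_mode)
    btw = betweenness_centrality(net)
    deg_norm = normalize_nodal(deg) if deg.mean() > 0 else np.full_like(deg, np.nan)
    btw_norm = normalize_nodal(btw) if btw.mean() > 0 else np.full_like(btw, np.nan)
    hubs_d = identify_hubs(deg) if deg.size >= 2 else set()
    hubs_b = identify_hubs(btw) if btw.size >= 2 else set()
    return NodalMetrics(
        degree=deg,
        betweenness=btw,
        degree_norm=deg_norm,
        betweenness_norm=btw_norm,
        hubs_degree=hubs_d,
        hubs_betweenness=hubs_b,
    )
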