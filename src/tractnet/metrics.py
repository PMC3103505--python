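"""Weighted graph metrics for structural brain networks.

Six measures characterize each connectivity backbone:

* clustering ``C`` — Onnela-style weighted clustering, the geometric mean of
  triangle weights (weights scaled by the network maximum, so C_i ∈ [0, 1]);
* characteristic path length ``L`` — mean weighted geodesic with arc length
  inversely proportional to connection strength, ``l_ij = 1 / w_ij``;
* modularity ``Q`` — Newman modularity on weight fractions, optimized by
  recursive leading-eigenvector bisection with Kernighan–Lin-style
  refinement;
* global efficiency ``E_glob`` — mean inverse geodesic distance (disconnected
  pairs contribute 0);
* local efficiency ``E_loc`` — mean over nodes of the global efficiency of
  each node's first-neighbor subgraph;
* small-worldness ``sigma = gamma / lambda`` with ``gamma = C / <C_rand>``
  and ``lambda = L / <L_rand>`` over an ensemble of degree-preserving,
  weight-shuffled random reference networks.

All functions accept either a :class:`~tractnet.network.ConnectivityNetwork`
or a bare symmetric weight matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, dijkstra, floyd_warshall

logger = logging.getLogger(__name__)

__all__ = [
    "MetricSet",
    "ModulePartition",
    "clustering",
    "compute_metrics",
    "find_modules",
    "global_efficiency",
    "local_efficiency",
    "modularity_q",
    "path_length",
    "random_reference",
    "small_worldness",
]


@dataclass(frozen=True)
class MetricSet:
    """The six topological measures for one network.

    gamma = C / <C_rand>, lambda_ = L / <L_rand>, sigma = gamma / lambda_.
    """

    C: float
    L: float
    Q: float
    E_glob: float
    E_loc: float
    gamma: float
    lambda_: float
    sigma: float

    _NAMES = ("C", "L", "Q", "E_glob", "E_loc", "sigma")

    def as_dict(self) -> dict[str, float]:
        return {
            "C": self.C,
            "L": self.L,
            "Q": self.Q,
            "E_glob": self.E_glob,
            "E_loc": self.E_loc,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
        }


@dataclass(frozen=True)
class ModulePartition:
    """A community assignment (node index -> module id) and its modularity."""

    labels: np.ndarray
    q: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


def _as_matrix(network) -> np.ndarray:
    W = getattr(network, "weights", network)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    if not np.allclose(W, W.T, atol=1e-9):
        raise ValueError("weight matrix must be symmetric")
    return W


def _geodesics(W: np.ndarray) -> np.ndarray:
    """All-pairs weighted geodesic distances with arc lengths 1/w.

    Floyd–Warshall on a dense length matrix; for the network sizes this
    package works at (tens to a few hundred nodes) the vectorized dense
    update beats sparse Dijkstra including its setup cost.
    """
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, 0.0)
    if n > 400:  # sparse Dijkstra wins on large, sparse networks
        return dijkstra(csr_array(lengths), directed=False)
    return floyd_warshall(lengths, directed=False)


def _global_eff_from_dist(D: np.ndarray) -> float:
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(D[off]), 0.0, 1.0 / D[off])
    return float(inv.mean())


def _clustering_fast(W: np.ndarray, scaled: bool = True) -> tuple[np.ndarray, float]:
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    cube = np.cbrt(W / wmax if scaled else W)
    # diag(A^3) via BLAS: sum_j (A @ A)_ij * A_ji with A symmetric
    num = ((cube @ cube) * cube).sum(axis=1)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def clustering(network, scaled: bool = True) -> tuple[np.ndarray, float]:
    """Weighted clustering: geometric mean of triangle weights around a node.

    C_i = [1 / (k_i (k_i - 1))] * sum_{j,h} (w_ij * w_ih * w_jh)^(1/3), with
    weights divided by the largest weight in the network when ``scaled``
    (the default; then C_i ∈ [0, 1]). Nodes with degree < 2 contribute 0.

    Returns (per-node values, mean over all n nodes).
    """
    W = _as_matrix(network)
    n = W.shape[0]
    if n == 0:
        raise ValueError("clustering is undefined on an empty graph")
    return _clustering_fast(W, scaled=scaled)


def path_length(network) -> tuple[np.ndarray, float]:
    """Characteristic path length with arc lengths l_ij = 1 / w_ij.

    Geodesics are the minimum sum of arc lengths; L is the mean over all
    ordered pairs i != j. Raises on disconnected input (use
    :func:`global_efficiency`, which tolerates disconnection).
    """
    W = _as_matrix(network)
    n = W.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    D = _geodesics(W)
    off = ~np.eye(n, dtype=bool)
    if np.isinf(D[off]).any():
        raise ValueError(
            "network is disconnected: characteristic path length is infinite "
            "(global_efficiency handles disconnected pairs)"
        )
    return D, float(D[off].mean())


def global_efficiency(network) -> float:
    """Mean inverse geodesic distance over ordered pairs; 1/inf = 0."""
    W = _as_matrix(network)
    n = W.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _global_eff_from_dist(_geodesics(W))


def local_efficiency(network) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph G_i.

    G_i contains the first neighbors of i (i itself excluded); nodes with
    fewer than 2 neighbors contribute 0.
    """
    W = _as_matrix(network)
    n = W.shape[0]
    if n == 0:
        raise ValueError("local efficiency is undefined on an empty graph")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(W[i])
        if len(nbrs) < 2:
            continue
        total += _global_eff_from_dist(_geodesics(W[np.ix_(nbrs, nbrs)]))
    return total / n


def modularity_q(network, labels) -> float:
    """Newman modularity Q = sum_c (e_cc - a_c^2) on weight fractions.

    e_cc is the fraction of total edge weight inside community c and a_c the
    fraction of edge ends attached to community c.
    """
    W = _as_matrix(network)
    labels = np.asarray(labels)
    if labels.shape != (W.shape[0],):
        raise ValueError("partition must assign every node exactly once")
    strength = W.sum(axis=1)
    m2 = strength.sum()
    if m2 == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_cc = W[np.ix_(mask, mask)].sum() / m2
        a_c = strength[mask].sum() / m2
        q += e_cc - a_c**2
    return float(q)


def _kl_refine(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan–Lin-style refinement of a two-way split.

    Greedily flips the single node that most increases s^T B s (each node
    moved at most once per pass, negative moves allowed), keeps the best
    intermediate state, and repeats while a pass improves the objective.
    """
    n = len(s)
    best_obj = s @ Bg @ s
    tol = 1e-10 * max(1.0, float(np.abs(Bg).sum()))
    improved = True
    max_passes = 100  # guards against cycling on float-noise-level gains
    while improved and max_passes > 0:
        max_passes -= 1
        improved = False
        s_pass = s.copy()
        moved = np.zeros(n, dtype=bool)
        obj = best_obj
        best_pass_obj, best_pass_state = obj, s_pass.copy()
        for _ in range(n):
            # gain of flipping node u: -4 s_u (Bg[u] @ s) + 4 Bg[u, u]
            gains = -4 * s_pass * (Bg @ s_pass) + 4 * np.diagonal(Bg)
            gains[moved] = -np.inf
            u = int(np.argmax(gains))
            obj += gains[u]
            s_pass[u] = -s_pass[u]
            moved[u] = True
            if obj > best_pass_obj + tol:
                best_pass_obj, best_pass_state = obj, s_pass.copy()
        if best_pass_obj > best_obj + tol:
            best_obj, s = best_pass_obj, best_pass_state
            improved = True
    return s


def find_modules(network) -> ModulePartition:
    """Community detection by Newman's spectral modularity optimization.

    Recursive leading-eigenvector bisection of the weighted modularity matrix
    B = W - k k^T / 2m, with a Kernighan–Lin-style refinement pass after each
    bisection; a group is left intact when no split increases Q.
    """
    W = _as_matrix(network)
    n = W.shape[0]
    if n == 0:
        raise ValueError("cannot partition an empty graph")
    strength = W.sum(axis=1)
    m2 = strength.sum()
    if m2 == 0:
        return ModulePartition(labels=np.zeros(n, dtype=int), q=0.0)
    B = W - np.outer(strength, strength) / m2
    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        idx = stack.pop()
        if len(idx) < 2:
            continue
        Bg = B[np.ix_(idx, idx)].copy()
        # generalized modularity matrix for a subgroup
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        vals, vecs = np.linalg.eigh(Bg)
        if vals[-1] <= 1e-12:
            continue
        s = np.where(vecs[:, -1] >= 0, 1.0, -1.0)
        s = _kl_refine(Bg, s)
        delta_q = (s @ Bg @ s) / (2.0 * m2)
        if delta_q <= 1e-12 or np.all(s == s[0]):
            continue
        group2 = idx[s < 0]
        labels[group2] = next_label
        next_label += 1
        stack.append(idx[s > 0])
        stack.append(group2)
    # relabel contiguously in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return ModulePartition(labels=labels, q=modularity_q(W, labels))


def _edge_list(W: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray]:
    iu, ju = np.triu_indices_from(W, k=1)
    mask = W[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    return edges, W[iu[mask], ju[mask]]


def _double_edge_swaps(
    edges: list[tuple[int, int]],
    weights: np.ndarray,
    n_swaps: int,
    rng: np.random.Generator,
    max_tries: int | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray, int, int]:
    """Degree-preserving double-edge swaps; weights travel with their edges.

    Swap (a,b),(c,d) -> (a,d),(c,b), rejected if it would create a self-loop
    or a parallel edge. Returns (edges, weights, swaps_done, tries_used).
    """
    edges = list(edges)
    weights = np.asarray(weights, dtype=float).copy()
    edge_set = {(min(a, b), max(a, b)) for a, b in edges}
    if max_tries is None:
        max_tries = max(100, 20 * n_swaps)
    done = tries = 0
    m = len(edges)
    picks: list[int] = []
    flips: list[bool] = []
    cursor = 0
    while done < n_swaps and tries < max_tries:
        if cursor >= len(flips):  # batch the RNG draws; per-try calls dominate
            size = min(4096, max_tries - tries)
            picks = rng.integers(0, m, size=2 * size).tolist()
            flips = (rng.random(size) < 0.5).tolist()
            cursor = 0
        e1, e2 = picks[2 * cursor], picks[2 * cursor + 1]
        flip = flips[cursor]
        cursor += 1
        tries += 1
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((a, b) if a < b else (b, a))
        edge_set.discard((c, d) if c < d else (d, c))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        done += 1
    return edges, weights, done, tries


def _edges_connected(n: int, edges: list[tuple[int, int]]) -> bool:
    """BFS connectivity check on an edge list (isolated nodes allowed only if
    they were isolated in the caller's graph — here all n nodes must join)."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    seen = bytearray(n)
    stack = [0]
    seen[0] = 1
    count = 1
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = 1
                count += 1
                stack.append(v)
    return count == n


def _connected_swaps(
    n: int,
    edges: list[tuple[int, int]],
    weights: np.ndarray,
    n_swaps: int,
    rng: np.random.Generator,
    window: int = 100,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Double-edge swaps that keep the graph connected.

    Swaps run in windows; after each window the connectivity is checked and a
    disconnecting window is rolled back (its swaps are forfeited). This keeps
    the per-swap cost O(1) amortized instead of re-drawing whole sequences.
    """
    checkpoint = list(edges)
    done = 0
    budget = 20 * n_swaps
    while done < n_swaps and budget > 0:
        chunk = min(window, n_swaps - done)
        edges, weights, made, tries = _double_edge_swaps(
            edges, weights, chunk, rng, max_tries=min(budget, 20 * chunk)
        )
        budget -= max(tries, 1)
        if made == 0:
            break
        if _edges_connected(n, edges):
            checkpoint = list(edges)
            done += made
        else:
            edges = list(checkpoint)
    return edges, weights


def _matrix_from_edges(
    n: int, edges: list[tuple[int, int]], weights: np.ndarray
) -> np.ndarray:
    W = np.zeros((n, n))
    for (i, j), w in zip(edges, weights):
        W[i, j] = W[j, i] = w
    return W


def random_reference(network, n_swaps: int, seed=None) -> np.ndarray:
    """Degree-preserving random reference network.

    The topology is randomized by ``n_swaps`` double-edge swaps and the
    original weight multiset is reassigned uniformly at random to the
    surviving edges; the degree sequence and the sorted weights are exact
    invariants. ``n_swaps = 0`` returns an unchanged copy. If no swap is
    feasible (e.g. a star graph) the input is returned with a warning.
    """
    W = _as_matrix(network)
    rng = np.random.default_rng(seed)
    edges, weights = _edge_list(W)
    if len(edges) < 2:
        raise ValueError("random_reference needs at least 2 edges")
    if n_swaps == 0:
        return W.copy()
    edges, weights, done, _ = _double_edge_swaps(edges, weights, n_swaps, rng)
    if done == 0:
        warnings.warn("no degree-preserving swap is possible; returning the input")
        return W.copy()
    weights = rng.permutation(weights)
    return _matrix_from_edges(W.shape[0], edges, weights)


def _is_connected(W: np.ndarray) -> bool:
    ncomp, _ = connected_components(csr_array(W), directed=False)
    return ncomp == 1


def small_worldness(
    network,
    ensemble_size: int = 20,
    n_swaps: int | None = None,
    seed=None,
    max_retries: int = 50,
) -> tuple[float, float, float]:
    """Small-world indices against a degree-preserving null ensemble.

    gamma = C / <C_rand>, lambda = L / <L_rand>, sigma = gamma / lambda, where
    the null ensemble consists of ``ensemble_size`` connected random
    references (swaps are applied in connectivity-preserving windows, and any
    residual disconnected draw is resampled up to ``max_retries`` times).
    ``n_swaps`` defaults to 5x the edge count. With ``n_swaps = 0`` the
    ensemble is the network itself and gamma = lambda = sigma = 1.
    """
    W = _as_matrix(network)
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be at least 1")
    if not _is_connected(W):
        raise ValueError("small_worldness requires a connected network")
    edges, _ = _edge_list(W)
    if n_swaps is None:
        n_swaps = 5 * len(edges)
    rng = np.random.default_rng(seed)
    n = W.shape[0]
    _, c_obs = _clustering_fast(W)
    D = _geodesics(W)
    off = ~np.eye(n, dtype=bool)
    l_obs = D[off].mean()
    base_edges, base_weights = _edge_list(W)
    c_rand = np.empty(ensemble_size)
    l_rand = np.empty(ensemble_size)
    for i in range(ensemble_size):
        for attempt in range(max_retries):
            if n_swaps == 0:
                R = W.copy()
            else:
                # connectivity-preserving swaps, then weight-multiset shuffle
                e_r, w_r = _connected_swaps(
                    n, base_edges, base_weights, n_swaps, rng
                )
                R = _matrix_from_edges(n, e_r, rng.permutation(w_r))
            Dr = _geodesics(R)
            if not np.isinf(Dr[off]).any():  # connected draw
                break
        else:
            raise RuntimeError(
                f"could not draw a connected random reference in {max_retries} tries"
            )
        _, c_rand[i] = _clustering_fast(R)
        l_rand[i] = Dr[off].mean()
    gamma = c_obs / c_rand.mean() if c_rand.mean() > 0 else np.inf
    lam = l_obs / l_rand.mean()
    return float(gamma), float(lam), float(gamma / lam)


def compute_metrics(
    network,
    ensemble_size: int = 20,
    n_swaps: int | None = None,
    seed=None,
    scaled_clustering: bool = True,
) -> MetricSet:
    """All six measures (plus gamma and lambda) for one connected network."""
    W = _as_matrix(network)
    _, c = clustering(W, scaled=scaled_clustering)
    _, length = path_length(W)
    part = find_modules(W)
    gamma, lam, sigma = small_worldness(
        W, ensemble_size=ensemble_size, n_swaps=n_swaps, seed=seed
    )
    return MetricSet(
        C=c,
        L=length,
        Q=part.q,
        E_glob=global_efficiency(W),
        E_loc=local_efficiency(W),
        gamma=gamma,
        lambda_=lam,
        sigma=sigma,
    )
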