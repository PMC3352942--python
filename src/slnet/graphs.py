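"""Binary graphs from connectivity matrices and their small-world metrics.

Connectivity matrices are thresholded to a fixed average degree K (the
strongest floor(N*K/2) off-diagonal entries become edges). The clustering
coefficient C and harmonic path length L are normalized against ensembles of
fixed-edge-count Erdős–Rényi graphs (G(N, M)) of identical size, so a value
of 1.0 means "as in the random case". Topology beyond C/L is assessed from
the sorted degree distribution relative to the random ensemble, compared to
three prototype families: ring-lattice small world, clustered (hub-core)
small world, and scale-free.

Metrics are computed on boolean adjacency stacks so thousand-graph ensembles
stay cheap; networkx is used only to seed the preferential-attachment
prototype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .recording import ConfigurationError
from .sl import ConnectivityMatrix

PROTOTYPE_KINDS = ("lattice_sw", "clustered_sw", "scale_free")


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph stored as a boolean adjacency matrix."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConfigurationError("adjacency must be square")
        if a.diagonal().any():
            raise ConfigurationError("self-loops are not allowed")
        if not (a == a.T).all():
            raise ConfigurationError("adjacency must be symmetric")
        self.adjacency = a

    @classmethod
    def from_edges(cls, n: int, edges) -> "BinaryGraph":
        a = np.zeros((n, n), dtype=bool)
        for u, v in edges:
            if u == v:
                raise ConfigurationError(f"self-loop ({u},{v})")
            a[u, v] = a[v, u] = True
        return cls(a)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edges(self) -> set[tuple[int, int]]:
        iu = np.triu_indices(self.n, k=1)
        mask = self.adjacency[iu]
        return {(int(i), int(j)) for i, j in zip(iu[0][mask], iu[1][mask])}

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degree_sequence(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


@dataclass
class NormalizedMetrics:
    """C and L of one graph together with their random-ensemble ratios.

    ``l_raw`` is the harmonic mean of per-vertex path lengths (itself the
    harmonic mean over pairwise distances, so unreachable pairs contribute
    zero inverse distance instead of dominating); ``l_paper`` is the unscaled
    1/sum(1/L_i) convention. The normalization constant cancels in ``l_norm``.
    """

    c_raw: float
    l_raw: float
    c_norm: float
    l_norm: float
    c_i: np.ndarray
    l_i: np.ndarray
    n_random: int
    seed: int
    c_rand_mean: float = math.nan
    l_rand_mean: float = math.nan

    @property
    def l_paper(self) -> float:
        return self.l_raw / len(self.l_i)


# ---------------------------------------------------------------------------
# batched metric kernels


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def random_gnm_adjacency(n: int, m_edges: int, size: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Stack of ``size`` fixed-edge-count Erdős–Rényi adjacency matrices."""
    total = n * (n - 1) // 2
    if not 0 <= m_edges <= total:
        raise ConfigurationError(f"cannot place {m_edges} edges on {n} vertices")
    rows, cols = _pair_index(n)
    scores = rng.random((size, total))
    chosen = np.argpartition(scores, m_edges - 1, axis=1)[:, :m_edges]
    adj = np.zeros((size, n, n), dtype=bool)
    b = np.repeat(np.arange(size), m_edges)
    adj[b, rows[chosen].ravel(), cols[chosen].ravel()] = True
    adj |= adj.transpose(0, 2, 1)
    return adj


def batch_clustering(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(C_raw, C_i) for a stack of adjacency matrices.

    C_i is the proportion of a vertex's neighbour pairs that are themselves
    connected (closed / (closed + open) triples); vertices of degree < 2 have
    no neighbour pairs and contribute C_i = 0. C_raw is the mean over all
    vertices.
    """
    a = adj.astype(float)
    deg = a.sum(axis=2)
    tri = np.einsum("bij,bjk,bki->bi", a, a, a) / 2.0
    pairs = deg * (deg - 1) / 2.0
    c_i = np.divide(tri, pairs, out=np.zeros_like(tri), where=pairs > 0)
    return c_i.mean(axis=1), c_i


def batch_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path hop counts for a stack of adjacency matrices
    (breadth-first via boolean matrix products); unreachable pairs are +inf."""
    b, n, _ = adj.shape
    dist = np.where(adj, 1.0, np.inf)
    eye = np.eye(n, dtype=bool)
    dist[:, eye] = 0.0
    reach = adj | eye
    step = adj.astype(np.float32)
    frontier = reach
    k = 2
    while True:
        nxt = (frontier.astype(np.float32) @ step) > 0
        new = nxt & ~reach
        if not new.any():
            break
        dist[new] = k
        reach |= nxt
        frontier = nxt
        k += 1
    return dist


def batch_path_length(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(L_raw, L_i) for a stack of adjacency matrices.

    L_i aggregates the distances from vertex i harmonically, so unreachable
    pairs (distance +inf) contribute zero inverse distance; L_raw is the
    harmonic mean of the L_i. A graph where no vertex reaches any other gets
    L_raw = +inf.
    """
    b, n, _ = adj.shape
    dist = batch_distances(adj)
    inv = np.zeros_like(dist)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    inv[finite] = 1.0 / dist[finite]
    inv_li = inv.sum(axis=2) / (n - 1)  # = 1 / L_i
    s = inv_li.sum(axis=1)
    with np.errstate(divide="ignore"):
        l_raw = np.where(s > 0, n / s, np.inf)
        l_i = np.where(inv_li > 0, 1.0 / inv_li, np.inf)
    return l_raw, l_i


def clustering_coefficient(g: BinaryGraph,
                           include_low_degree: bool = True
                           ) -> tuple[float, np.ndarray]:
    """Graph clustering coefficient and per-vertex values.

    Vertices of degree < 2 contribute C_i = 0; by default they stay in the
    vertex mean. ``include_low_degree=False`` averages over vertices with at
    least two neighbours instead (sensitivity variant).
    """
    _, c_i = batch_clustering(g.adjacency[None])
    c_i = c_i[0]
    if include_low_degree:
        return float(c_i.mean()), c_i
    mask = g.degree_sequence >= 2
    return float(c_i[mask].mean()) if mask.any() else 0.0, c_i


def path_length(g: BinaryGraph) -> tuple[float, np.ndarray]:
    l, l_i = batch_path_length(g.adjacency[None])
    return float(l[0]), l_i[0]


# ---------------------------------------------------------------------------
# thresholding and normalization


def threshold_to_degree(conn: ConnectivityMatrix, K: float) -> BinaryGraph:
    """Binary graph keeping the floor(N*K/2) strongest connectivity entries.

    Ties at the cut are broken deterministically by (value desc, then
    lexicographic channel-pair order).
    """
    n = conn.n_channels
    m_edges = int(n * K // 2)
    if m_edges > n * (n - 1) // 2:
        raise ConfigurationError(f"K={K} infeasible for N={n}")
    rows, cols = _pair_index(n)
    vals = conn.values[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    keep = order[:m_edges]
    adj = np.zeros((n, n), dtype=bool)
    adj[rows[keep], cols[keep]] = True
    return BinaryGraph(adj | adj.T)


def er_normalize(g: BinaryGraph, n_random: int = 1000, seed: int = 0) -> NormalizedMetrics:
    """Normalize C and L against a G(N, M) ensemble of identical size.

    Each ratio divides the empirical score by the ensemble *mean* (not a mean
    of per-graph ratios), so zero-clustering ensemble members are handled by
    construction. Disconnected members are kept; the harmonic L stays finite.
    """
    if g.n_edges == 0:
        raise ConfigurationError("cannot normalize an edgeless graph")
    rng = np.random.default_rng(seed)
    ens = random_gnm_adjacency(g.n, g.n_edges, n_random, rng)
    c_ens, _ = batch_clustering(ens)
    l_ens, _ = batch_path_length(ens)
    c_raw, c_i = clustering_coefficient(g)
    l_raw, l_i = path_length(g)
    c_mean = float(c_ens.mean())
    l_mean = float(l_ens.mean())
    return NormalizedMetrics(
        c_raw=c_raw, l_raw=l_raw,
        c_norm=c_raw / c_mean, l_norm=l_raw / l_mean,
        c_i=c_i, l_i=l_i, n_random=n_random, seed=seed,
        c_rand_mean=c_mean, l_rand_mean=l_mean,
    )


def k_sweep(conn: ConnectivityMatrix, k_values, n_random: int = 1000,
            seed: int = 0) -> list[tuple[float, BinaryGraph, NormalizedMetrics]]:
    """Threshold and normalize at each average degree K; returns
    (K, graph, metrics) rows."""
    out = []
    for i, k in enumerate(k_values):
        g = threshold_to_degree(conn, k)
        out.append((float(k), g, er_normalize(g, n_random=n_random, seed=seed + i)))
    return out


# ---------------------------------------------------------------------------
# prototype generators


def _adjust_edge_count(adj: np.ndarray, m_target: int,
                       rng: np.random.Generator,
                       prefer_degree: bool = False) -> None:
    """Add or remove edges in place until exactly ``m_target`` remain.

    With ``prefer_degree`` additions favour high-degree endpoint pairs
    (keeps preferential-attachment skew when padding).
    """
    n = adj.shape[0]
    rows, cols = _pair_index(n)
    while int(adj.sum()) // 2 != m_target:
        present = adj[rows, cols]
        if int(adj.sum()) // 2 < m_target:
            free = np.flatnonzero(~present)
            if prefer_degree:
                deg = adj.sum(axis=1)
                w = (deg[rows[free]] * deg[cols[free]] + 1).astype(float)
                pick = free[rng.choice(free.size, p=w / w.sum())]
            else:
                pick = rng.choice(free)
            adj[rows[pick], cols[pick]] = adj[cols[pick], rows[pick]] = True
        else:
            used = np.flatnonzero(present)
            pick = used[rng.integers(used.size)]
            adj[rows[pick], cols[pick]] = adj[cols[pick], rows[pick]] = False


def _rewire(adj: np.ndarray, n_rewire: int, rng: np.random.Generator) -> None:
    """Random reconnections preserving the edge count: move one endpoint of a
    random edge to a random non-adjacent vertex."""
    n = adj.shape[0]
    for _ in range(n_rewire):
        for _attempt in range(100):
            rows, cols = np.nonzero(np.triu(adj, 1))
            e = rng.integers(rows.size)
            u, v = int(rows[e]), int(cols[e])
            if rng.random() < 0.5:
                u, v = v, u
            candidates = np.flatnonzero(~adj[u])
            candidates = candidates[candidates != u]
            candidates = candidates[candidates != v]
            if candidates.size == 0:
                continue
            w = int(rng.choice(candidates))
            adj[u, v] = adj[v, u] = False
            adj[u, w] = adj[w, u] = True
            break


def gen_prototype(kind: str, N: int, K: float, n_rewire: int = 3,
                  seed: int = 0) -> BinaryGraph:
    """Prototype network of one of the three ordered families.

    lattice_sw
        ring lattice, each vertex tied to its K nearest neighbours;
    clustered_sw
        ceil(N/4) fully interconnected hub vertices, periphery vertices
        attached to two hubs each;
    scale_free
        preferential attachment (Barabási–Albert seed, padded/trimmed with
        degree-weighted edges).

    All kinds end with exactly floor(N*K/2) edges; ``n_rewire`` random
    reconnections (edge count preserved) then inject small-world shortcuts.
    """
    if kind not in PROTOTYPE_KINDS:
        raise ConfigurationError(f"unknown prototype kind {kind!r}")
    if N < 4:
        raise ConfigurationError("prototypes need N >= 4")
    m_target = int(N * K // 2)
    if not 0 < m_target <= N * (N - 1) // 2:
        raise ConfigurationError(f"infeasible N={N}, K={K}")
    rng = np.random.default_rng(seed)
    adj = np.zeros((N, N), dtype=bool)

    if kind == "lattice_sw":
        half = max(1, int(round(K / 2)))
        for i in range(N):
            for d in range(1, half + 1):
                j = (i + d) % N
                adj[i, j] = adj[j, i] = True
        _adjust_edge_count(adj, m_target, rng)
    elif kind == "clustered_sw":
        n_hub = math.ceil(N / 4)
        adj[:n_hub, :n_hub] = True
        np.fill_diagonal(adj, False)
        for p in range(n_hub, N):
            for h in rng.choice(n_hub, size=min(2, n_hub), replace=False):
                adj[p, h] = adj[h, p] = True
        _adjust_edge_count(adj, m_target, rng, prefer_degree=True)
    else:  # scale_free
        m_ba = max(1, int(round(K / 2)))
        seed_graph = nx.barabasi_albert_graph(N, m_ba, seed=int(rng.integers(2**31)))
        for u, v in seed_graph.edges():
            adj[u, v] = adj[v, u] = True
        _adjust_edge_count(adj, m_target, rng, prefer_degree=True)

    _rewire(adj, n_rewire, rng)
    return BinaryGraph(adj)


# ---------------------------------------------------------------------------
# sorted degree distributions and topology classification


def sorted_degree_ratio(graphs, n_random: int = 1000, seed: int = 0) -> np.ndarray:
    """Rank-wise mean sorted degree sequence divided by the same quantity over
    a matched G(N, M) random ensemble.

    Every input graph must share the same vertex and edge count. Degrees are
    sorted ascending per graph, averaged across graphs at each rank, then
    divided rank-wise by the random-ensemble average.
    """
    graphs = list(graphs)
    if not graphs:
        raise ConfigurationError("need at least one graph")
    n, m = graphs[0].n, graphs[0].n_edges
    for g in graphs[1:]:
        if g.n != n or g.n_edges != m:
            raise ConfigurationError("graphs must share vertex and edge counts")
    emp = np.mean([np.sort(g.degree_sequence) for g in graphs], axis=0)
    rng = np.random.default_rng(seed)
    ens = random_gnm_adjacency(n, m, n_random, rng)
    rand = np.sort(ens.sum(axis=2), axis=1).mean(axis=0)
    return emp / rand


@dataclass(frozen=True)
class TopologyThresholds:
    """Configuration of the :func:`classify_topology` decision rule.

    The classifier matches the observed ratio curve against reference mean
    curves of the three prototype families (plus the flat random-like curve)
    and returns the nearest one in root-mean-square distance. References are
    built from ``n_seeds`` seeded prototypes at the matching vertex count,
    average degree ``K`` and ``n_rewire`` reconnections, normalized against
    an ``n_random``-graph ensemble, and cached per curve length.
    """

    K: float = 4.0
    n_rewire: int = 3
    n_seeds: int = 100
    n_random: int = 1000
    seed: int = 20_000

    def reference_curves(self, n: int) -> dict[str, np.ndarray]:
        return _reference_curves(self, n)


_REFERENCE_CACHE: dict[tuple, dict[str, np.ndarray]] = {}


def _reference_curves(th: TopologyThresholds, n: int) -> dict[str, np.ndarray]:
    key = (n, th.K, th.n_rewire, th.n_seeds, th.n_random, th.seed)
    if key not in _REFERENCE_CACHE:
        refs = {}
        for kind in PROTOTYPE_KINDS:
            gs = [gen_prototype(kind, n, th.K, th.n_rewire, seed=th.seed + s)
                  for s in range(th.n_seeds)]
            refs[kind] = sorted_degree_ratio(gs, n_random=th.n_random,
                                             seed=th.seed)
        refs["random-like"] = np.ones(n)
        _REFERENCE_CACHE[key] = refs
    return _REFERENCE_CACHE[key]


def classify_topology(ratio: np.ndarray,
                      thresholds: TopologyThresholds | None = None
                      ) -> tuple[str, dict]:
    """Label a sorted-degree ratio curve by its shape.

    The label is the nearest (root-mean-square) reference curve among the
    three prototype families and the flat random-like baseline; see
    :class:`TopologyThresholds`. Reported shape statistics: ``slope`` of a
    least-squares line over normalized rank; ``s_stat``, mean of the top
    quartile minus the bottom quartile; ``flat_dev``, mean absolute deviation
    from 1; and the per-reference RMS distances.
    """
    ratio = np.asarray(ratio, dtype=float)
    if ratio.size < 5:
        raise ConfigurationError("ratio curve needs at least 5 ranks")
    th = thresholds or TopologyThresholds()
    refs = th.reference_curves(ratio.size)
    dist = {kind: float(np.sqrt(np.mean((ratio - ref) ** 2)))
            for kind, ref in refs.items()}
    label = min(dist, key=dist.get)
    x = np.linspace(0.0, 1.0, ratio.size)
    q = max(1, ratio.size // 4)
    stats = {
        "slope": float(np.polyfit(x, ratio, 1)[0]),
        "s_stat": float(ratio[-q:].mean() - ratio[:q].mean()),
        "flat_dev": float(np.abs(ratio - 1.0).mean()),
        "distances": dist,
    }
    return label, stats
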