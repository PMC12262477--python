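"""Synthetic connectome generation, directed rewiring and planted hierarchies.

These generators stand in for empirical structural connectomes in the
validation pipeline: a connected weighted graph with heavy-tailed weights
plays the role of a diffusion-MRI structural connectivity (SC) matrix, and
directionality is induced by degree-preserving directed edge swaps that
leave the binary in-/out-degree sequences, the edge-weight multiset and
connectedness untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .core import WeightedDigraph, get_logger

__all__ = [
    "SyntheticNetworkSpec",
    "generate_synthetic_sc",
    "rewire_directed",
    "plant_hierarchy_network",
    "fagiolo_clustering",
    "node_strength",
    "asymmetry_index",
]

logger = get_logger(__name__)


@dataclass
class SyntheticNetworkSpec:
    """Recipe for a synthetic weighted connectome.

    ``weight_distribution`` is ``("lognormal", mu, sigma)`` or
    ``("pareto", alpha)``; heavy-tailed laws mimic the weight distribution
    of empirical structural connectivity.
    """

    n_regions: int
    density: float
    weight_distribution: tuple = ("lognormal", 0.0, 2.0)
    rewire_fraction: float = 0.2
    seed: int = 0
    hub_sd: float = 1.0          # sd of log node attractiveness (hub strength)
    distance_decay: float = 0.25  # length scale of the connection-score decay

    def __post_init__(self) -> None:
        if self.n_regions < 10:
            raise ValueError("n_regions must be >= 10")
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if not 0 <= self.rewire_fraction <= 1:
            raise ValueError("rewire_fraction must be in [0, 1]")
        dist = self.weight_distribution[0]
        if dist not in ("lognormal", "pareto"):
            raise ValueError(f"unknown weight distribution {dist!r}")


def _draw_weights(spec: SyntheticNetworkSpec, m: int, rng: np.random.Generator):
    dist = spec.weight_distribution
    if dist[0] == "lognormal":
        return rng.lognormal(mean=dist[1], sigma=dist[2], size=m)
    # Pareto with tail index alpha on [1, inf)
    alpha = dist[1]
    return (1.0 - rng.random(m)) ** (-1.0 / alpha)


def generate_synthetic_sc(spec: SyntheticNetworkSpec) -> WeightedDigraph:
    """Generate a connected, symmetric weighted graph at the requested density.

    The generator emulates three hallmarks of empirical structural
    connectomes: spatial embedding with distance-dependent connection
    scores (an exponential-distance-rule analogue), hub structure (each
    region draws a log-normal attractiveness, and the pair score is the
    attractiveness product times the distance decay — binary degrees become
    broad, as in rich-club connectomes), and heavy-tailed weights that are
    rank-matched to the connection score so short hub-hub links are
    strongest.  A maximum-score spanning tree guarantees connectedness and
    the top-scoring remaining pairs fill in to the exact requested edge
    count; the weight multiset is exactly the requested distribution.
    The graph is returned in directed-matrix form with reciprocal edges
    (an undirected SC before directionality induction); reproducible under
    ``spec.seed``.
    """
    n = spec.n_regions
    m_undirected = int(round(spec.density * n * (n - 1) / 2))
    if m_undirected < n - 1:
        raise ValueError(
            f"density {spec.density} too low to connect {n} regions "
            f"({m_undirected} edges < {n - 1})"
        )
    rng = np.random.default_rng(spec.seed)
    points = rng.uniform(0.0, 1.0, (n, 2))
    dist_mat = squareform(pdist(points))
    attract = rng.lognormal(0.0, spec.hub_sd, n)
    score = np.outer(attract, attract) * np.exp(-dist_mat / spec.distance_decay)
    iu = np.triu_indices(n, k=1)
    pair_score = score[iu]
    # maximum-score spanning tree backbone keeps the graph connected; the
    # top-scoring remaining pairs fill in up to the requested edge count
    mst = minimum_spanning_tree(-np.log(score + 1e-300)).toarray()
    in_mst = ((mst + mst.T) != 0)[iu]
    chosen = list(np.nonzero(in_mst)[0])
    chosen_set = set(chosen)
    for e in np.argsort(pair_score)[::-1]:
        if len(chosen) >= m_undirected:
            break
        if e not in chosen_set:
            chosen.append(int(e))
            chosen_set.add(int(e))
    chosen = np.asarray(chosen)
    # largest weight on the highest-scoring edge
    by_score = chosen[np.argsort(pair_score[chosen])[::-1]]
    weights = np.sort(_draw_weights(spec, m_undirected, rng))[::-1]
    w = np.zeros((n, n))
    w[iu[0][by_score], iu[1][by_score]] = weights
    w[iu[1][by_score], iu[0][by_score]] = weights
    labels = [f"R{i:03d}" for i in range(n)]
    return WeightedDigraph(w, labels, kind="SC", meta={"spec_seed": spec.seed})


def _is_weakly_connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(adj != 0, directed=True, connection="weak")
    return n_comp == 1


def rewire_directed(
    g: WeightedDigraph, fraction: float, seed: int
) -> WeightedDigraph:
    """Reassign ``fraction`` of directed edges by degree-preserving swaps.

    Each accepted swap takes two edges a->b, c->d and rewires them to
    a->d, c->b (weights travel with their source stub), so the binary in-
    and out-degree sequences are preserved exactly.  Swaps creating a
    self-loop or duplicate edge are rejected; weak connectedness is checked
    every 10 accepted swaps with rollback of the offending batch.
    Applied to a symmetric matrix this induces directionality (edge
    asymmetry) while preserving the degree sequences, connectedness and the
    edge-weight multiset.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    adj = g.weights.copy()
    if not _is_weakly_connected(adj):
        raise ValueError("input graph must be (weakly) connected")
    rng = np.random.default_rng(seed)
    src, tgt = np.nonzero(adj.T)  # column=source, row=target -> (source, target)
    n_edges = len(src)
    sources = list(src)
    targets = list(tgt)
    needed_swaps = int(np.ceil(fraction * n_edges / 2))
    max_attempts = 100 * max(needed_swaps, 1)

    accepted = 0
    attempts = 0
    batch: list[tuple[int, int, int, int]] = []  # (edge1, edge2, old_t1, old_t2)
    BATCH = 10

    def _rollback(batch):
        for e1, e2, t1, t2 in reversed(batch):
            a, c = sources[e1], sources[e2]
            d, b = targets[e1], targets[e2]
            adj[d, a] = 0.0
            adj[b, c] = 0.0
            adj[t1, a] = _w1[e1]
            adj[t2, c] = _w1[e2]
            targets[e1], targets[e2] = t1, t2

    # weight lookup by edge id (weights travel with their source stub)
    _w1 = [adj[t, s] for s, t in zip(sources, targets)]

    while accepted < needed_swaps:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"rewiring stalled: {accepted}/{needed_swaps} swaps after "
                f"{attempts} attempts (graph too constrained)"
            )
        e1, e2 = rng.integers(0, n_edges, size=2)
        if e1 == e2:
            continue
        a, b = sources[e1], targets[e1]
        c, d = sources[e2], targets[e2]
        # proposed: a->d, c->b
        if a == d or c == b:
            continue
        if adj[d, a] != 0 or adj[b, c] != 0:
            continue
        adj[b, a] = 0.0
        adj[d, c] = 0.0
        adj[d, a] = _w1[e1]
        adj[b, c] = _w1[e2]
        batch.append((e1, e2, b, d))
        targets[e1], targets[e2] = d, b
        accepted += 1
        if len(batch) >= BATCH or accepted == needed_swaps:
            if not _is_weakly_connected(adj):
                _rollback(batch)
                accepted -= len(batch)
            batch = []

    out = WeightedDigraph(adj, list(g.region_ids), kind="ground_truth"
                          if np.all(np.diag(adj) == 0) else g.kind,
                          meta=dict(g.meta))
    out.meta["rewired_fraction"] = 2 * needed_swaps / n_edges
    return out


def fagiolo_clustering(g: WeightedDigraph) -> np.ndarray:
    """Per-node directed weighted clustering coefficient (Fagiolo).

    C_i = [ (W^[1/3] + (W^[1/3])')^3 ]_ii / (2 [d_tot (d_tot - 1) - 2 d_rec])
    where W^[1/3] is the elementwise cube root of the (nonnegative) weight
    matrix scaled by its maximum, d_tot the total binary degree and d_rec
    the number of reciprocated neighbours.  Nodes with an undefined
    denominator get 0.
    """
    w = np.abs(g.weights)
    mx = w.max()
    if mx == 0:
        return np.zeros(g.n_regions)
    what = np.cbrt(w / mx)
    a = (g.weights != 0).astype(float)
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_rec = (a * a.T).sum(axis=1)
    s = what + what.T
    num = np.diag(s @ s @ s) / 2.0
    denom = 2.0 * (d_tot * (d_tot - 1) - 2.0 * d_rec)
    out = np.zeros_like(num)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def node_strength(g: WeightedDigraph) -> np.ndarray:
    """Per-node total weighted degree (in-strength + out-strength)."""
    return g.weights.sum(axis=0) + g.weights.sum(axis=1)


def asymmetry_index(g: WeightedDigraph) -> float:
    """Fraction of edges lacking a reciprocal counterpart."""
    a = g.weights != 0
    n_edges = a.sum()
    if n_edges == 0:
        return 0.0
    return float((a & ~a.T).sum() / n_edges)


def plant_hierarchy_network(
    n: int,
    beta: np.ndarray,
    noise_sd: float,
    density: float,
    seed: int,
) -> WeightedDigraph:
    """Plant a hierarchy: edge weight j -> i equals beta_i - beta_j + noise.

    Edges live on a random connected skeleton at the given density (both
    orientations of each skeleton edge are included; ``density=1`` yields
    all ordered pairs).  The planted levels are attached as
    ``meta['planted_beta']``.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (n,):
        raise ValueError("beta must have one level per region")
    if not np.all(np.isfinite(beta)):
        raise ValueError("planted levels must be finite")
    rng = np.random.default_rng(seed)
    labels = [f"R{i:03d}" for i in range(n)]
    if density >= 1.0:
        mask = ~np.eye(n, dtype=bool)
    else:
        spec = SyntheticNetworkSpec(n_regions=n, density=density, seed=seed)
        skeleton = generate_synthetic_sc(spec)
        mask = skeleton.weights != 0
    diff = beta[:, None] - beta[None, :]  # [i, j] = beta_i - beta_j
    w = np.where(mask, diff + rng.normal(0.0, noise_sd, size=(n, n)), 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedDigraph(w, labels, kind="ground_truth",
                           meta={"planted_beta": beta.copy()})
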