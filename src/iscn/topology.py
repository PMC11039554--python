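"""Density-threshold graph topology of iSCNs.

Each similarity network is thresholded to its K% strongest edges and
binarized, a cohort-wide valid density range is selected (connectedness
at the lower bound, small-worldness sigma > floor at the upper bound),
five global metrics and three nodal centralities are computed at every
retained density, and each metric is integrated as the trapezoidal AUC
over the threshold range.

Small-worldness follows the classic normalization
sigma = (C / C_rand) / (L / L_rand) with C_rand, L_rand averaged over
degree-preserving Maslov-Sneppen rewired surrogates.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from iscn.network import SimilarityNetwork

GLOBAL_METRICS = (
    "global_efficiency",
    "clustering_coefficient",
    "small_worldness",
    "modularity",
    "assortativity",
)
NODAL_METRICS = ("degree", "betweenness", "eigenvector")


@dataclasses.dataclass
class BinaryNetwork:
    """Binarized adjacency at density K% (zero diagonal, symmetric)."""

    adjacency: np.ndarray
    density: float
    region_ids: list[int]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def _edge_count(r: int, k: float) -> int:
    """round-half-away-from-zero of K/100 * R(R-1)/2."""
    return int(np.floor(k / 100.0 * (r * (r - 1) // 2) + 0.5))


def threshold_binarize(net: SimilarityNetwork, k: float) -> BinaryNetwork:
    """Retain exactly the K% strongest off-diagonal edges and binarize.

    Ties are broken deterministically by ascending (i, j) index order so
    every subject keeps exactly the same edge count at a given K.
    """
    if not (0 < k < 100):
        raise ValueError(f"density K must be in (0, 100), got {k}")
    r = len(net.region_ids)
    iu, ju = np.triu_indices(r, 1)
    w = net.matrix[iu, ju]
    m = _edge_count(r, k)
    # primary: descending weight; ties: ascending i then j
    order = np.lexsort((ju, iu, -w))
    keep = order[:m]
    adj = np.zeros((r, r), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj[ju[keep], iu[keep]] = 1
    return BinaryNetwork(adj, float(k), list(net.region_ids))


# ---------------------------------------------------------------------------
# fast metric kernels on dense binary adjacency
# ---------------------------------------------------------------------------

def _distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(adj), method="D", unweighted=True)


def global_efficiency_adj(adj: np.ndarray) -> float:
    """Mean over ordered node pairs of 1/d; unreachable pairs contribute 0."""
    n = adj.shape[0]
    d = _distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def characteristic_path_length_adj(adj: np.ndarray) -> float:
    """Mean shortest path over reachable ordered pairs (finite entries)."""
    d = _distances(adj)
    n = adj.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return np.inf
    return float(d[finite].mean())


def clustering_coefficient_adj(adj: np.ndarray) -> float:
    """Mean nodal triangle ratio (nodes of degree < 2 contribute 0)."""
    a = adj.astype(float)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1) / 2.0
    c = np.zeros_like(deg)
    ok = denom > 0
    c[ok] = tri[ok] / denom[ok]
    return float(c.mean())


def assortativity_adj(adj: np.ndarray) -> float:
    """Pearson correlation of endpoint degrees over edges (both orientations)."""
    deg = adj.sum(axis=1).astype(float)
    i, j = np.nonzero(np.triu(adj, 1))
    x = np.concatenate([deg[i], deg[j]])
    y = np.concatenate([deg[j], deg[i]])
    sx = x.std()
    if sx == 0:
        return float("nan")  # regular graph: undefined
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * y.std()))


def is_connected_adj(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return n_comp == 1


@njit(cache=False)
def _rewire_ms(adj, eu, ev, n_attempts, seed):  # pragma: no cover - numba kernel
    np.random.seed(seed)
    m = eu.shape[0]
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = eu[e1], ev[e1]
        c, d = eu[e2], ev[e2]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # propose a-d and c-b
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        eu[e1], ev[e1] = a, d
        eu[e2], ev[e2] = c, b


def maslov_sneppen_rewire(adj: np.ndarray, seed: int, swaps_per_edge: int = 10) -> np.ndarray:
    """Degree-preserving rewired surrogate (10 x |E| swap attempts)."""
    a = np.ascontiguousarray(adj.copy().astype(np.uint8))
    i, j = np.nonzero(np.triu(a, 1))
    eu = i.astype(np.int64).copy()
    ev = j.astype(np.int64).copy()
    _rewire_ms(a, eu, ev, swaps_per_edge * eu.size, seed % (2**31 - 1))
    return a


def small_worldness_adj(
    adj: np.ndarray, n_random: int = 20, seed: int = 0, return_parts: bool = False
):
    """sigma = (C/C_rand) / (L/L_rand), surrogate-averaged reference values.

    With ``return_parts=True`` also returns the ingredient dict
    (C, L, C_rand, L_rand and the surrogate adjacencies) for auditing.
    """
    c = clustering_coefficient_adj(adj)
    lpath = characteristic_path_length_adj(adj)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    surrogates = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_random)
    for t in range(n_random):
        surr = maslov_sneppen_rewire(adj, int(child_seeds[t]))
        c_rand[t] = clustering_coefficient_adj(surr)
        l_rand[t] = characteristic_path_length_adj(surr)
        if return_parts:
            surrogates.append(surr)
    cr = c_rand.mean()
    lr = l_rand.mean()
    if cr == 0 or lpath == 0 or not np.isfinite(lr):
        sigma = float("inf") if c > 0 else float("nan")
    else:
        sigma = float((c / cr) / (lpath / lr))
    if return_parts:
        return sigma, {
            "C": c,
            "L": lpath,
            "C_rand": cr,
            "L_rand": lr,
            "surrogates": surrogates,
        }
    return sigma


def modularity_adj(adj: np.ndarray, n_restarts: int = 10, seed: int = 0) -> float:
    """Best modularity Q over seeded Leiden restarts.

    Modularity maximization is NP-hard; Leiden with multi-start attains
    the exhaustive optimum on virtually all tiny graphs and is the
    strongest practical heuristic at cohort scale, but rare degenerate
    landscapes can still defeat any restart budget.
    """
    import igraph as ig
    import leidenalg as la

    g = ig.Graph.Adjacency((adj > 0).tolist(), mode="undirected")
    best = -np.inf
    base = int(seed) % (2**31 - 101)  # keep restart seeds in C-int range
    for t in range(n_restarts):
        part = la.find_partition(
            g, la.ModularityVertexPartition, seed=base + t, n_iterations=-1
        )
        best = max(best, part.modularity)
    return float(best)


@dataclasses.dataclass
class GlobalTopology:
    global_efficiency: float
    clustering_coefficient: float
    small_worldness: float
    modularity: float
    assortativity: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class NodalTopology:
    region_ids: list[int]
    degree: np.ndarray
    betweenness: np.ndarray
    eigenvector: np.ndarray


def global_metrics(net: BinaryNetwork, n_random: int = 20, seed: int = 0) -> GlobalTopology:
    """Five global metrics of a binary network.

    Small-worldness uses ``n_random`` seeded Maslov-Sneppen surrogates;
    modularity is the best Q over 10 seeded Leiden restarts.
    Assortativity is NaN on degree-regular graphs (undefined).
    """
    adj = net.adjacency
    if adj.sum() == 0:
        raise ValueError("network has zero edges")
    return GlobalTopology(
        global_efficiency=global_efficiency_adj(adj),
        clustering_coefficient=clustering_coefficient_adj(adj),
        small_worldness=small_worldness_adj(adj, n_random=n_random, seed=seed),
        modularity=modularity_adj(adj, seed=seed),
        assortativity=assortativity_adj(adj),
    )


def nodal_metrics(net: BinaryNetwork) -> NodalTopology:
    """Degree (raw), betweenness (normalized by (R-1)(R-2)/2) and
    eigenvector centrality (principal adjacency eigenvector, max 1)."""
    adj = net.adjacency
    if adj.sum() == 0:
        raise ValueError("network has zero edges")
    degree = adj.sum(axis=1).astype(int)
    g = nx.from_numpy_array(adj)
    bc = nx.betweenness_centrality(g, normalized=True)
    betweenness = np.array([bc[i] for i in range(net.n_nodes)])
    vals, vecs = np.linalg.eigh(adj.astype(float))
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    eigenvector = v / v.max() if v.max() > 0 else v
    return NodalTopology(list(net.region_ids), degree, betweenness, eigenvector)


def select_threshold_range(
    networks: Sequence[SimilarityNetwork],
    step: int = 1,
    floor: float = 1.1,
    n_random: int = 20,
    seed: int = 0,
    k_start: int = 1,
    k_cap: int = 60,
) -> tuple[int, int]:
    """Cohort-wide valid density range (K_min, K_max), in percent.

    K_min is the smallest scanned K at which every subject's binary
    network is a single connected component; because higher densities
    only add edges, connectedness then holds throughout the range.
    K_max is the largest K of the contiguous run starting at K_min over
    which every subject's small-worldness exceeds ``floor`` (sigma
    decays toward 1 as density grows).  Surrogate seeds are derived
    deterministically from ``seed``, subject index and K.
    """
    if not networks:
        raise ValueError("empty cohort")
    k_min = None
    for k in range(k_start, k_cap + 1, step):
        if all(is_connected_adj(threshold_binarize(net, k).adjacency) for net in networks):
            k_min = k
            break
    if k_min is None:
        raise ValueError(
            f"no density K <= {k_cap} connects every subject's network; "
            "inspect the similarity matrices"
        )
    k_max = None
    for k in range(k_min, k_cap + 1, step):
        sigmas = [
            small_worldness_adj(
                threshold_binarize(net, k).adjacency,
                n_random=n_random,
                seed=_sigma_seed(seed, s, k),
            )
            for s, net in enumerate(networks)
        ]
        if min(sigmas) > floor:
            k_max = k
        else:
            break
    if k_max is None:
        raise ValueError(
            f"small-worldness of some subject is <= {floor} already at the "
            f"connectedness bound K={k_min}; no valid density range exists — "
            "inspect the similarity matrices"
        )
    return k_min, k_max


def _sigma_seed(seed: int, subject_index: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, subject_index, k]).generate_state(1)[0])


@dataclasses.dataclass
class TopologyProfile:
    """AUC-over-threshold summaries of one subject's topology."""

    subject_id: str
    auc_global: dict[str, float]
    auc_nodal: dict[str, np.ndarray]
    threshold_range: tuple[int, int]


def metric_auc(values: Sequence[float], step: float = 1.0) -> float:
    """Un-normalized trapezoidal integral of a metric over thresholds."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("AUC needs metrics at >= 2 thresholds")
    return float(np.trapezoid(values, dx=step))


def topology_profile(
    net: SimilarityNetwork,
    k_range: tuple[int, int],
    step: int = 1,
    n_random: int = 20,
    seed: int = 0,
    subject_index: int = 0,
) -> TopologyProfile:
    """Compute all metrics at each K in the range and integrate as AUC."""
    k_min, k_max = k_range
    ks = list(range(k_min, k_max + 1, step))
    if len(ks) < 2:
        raise ValueError("threshold range must contain >= 2 densities")
    glob: dict[str, list[float]] = {m: [] for m in GLOBAL_METRICS}
    nodal: dict[str, list[np.ndarray]] = {m: [] for m in NODAL_METRICS}
    for k in ks:
        b = threshold_binarize(net, k)
        gm = global_metrics(b, n_random=n_random, seed=_sigma_seed(seed, subject_index, k))
        for m, v in gm.as_dict().items():
            glob[m].append(v)
        nm = nodal_metrics(b)
        nodal["degree"].append(nm.degree.astype(float))
        nodal["betweenness"].append(nm.betweenness)
        nodal["eigenvector"].append(nm.eigenvector)
    return TopologyProfile(
        subject_id=net.subject_id,
        auc_global={m: metric_auc(v, step) for m, v in glob.items()},
        auc_nodal={m: np.trapezoid(np.array(v), dx=step, axis=0) for m, v in nodal.items()},
        threshold_range=(k_min, k_max),
    )


def profiles_frame(profiles: Sequence[TopologyProfile], region_ids: Sequence[int]) -> pd.DataFrame:
    """One row per subject: 5 global AUC + 3R nodal AUC columns."""
    rows = []
    for p in profiles:
        row: dict[str, float] = {"subject_id": p.subject_id}
        for m in GLOBAL_METRICS:
            row[f"{m}_auc"] = p.auc_global[m]
        for m in NODAL_METRICS:
            for rid, v in zip(region_ids, p.auc_nodal[m]):
                row[f"{m}_auc_r{rid}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
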