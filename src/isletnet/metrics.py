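"""Topological metrics of functional networks and their relation to
cellular activity.

The metric set: average node degree (k_avg), average clustering
coefficient (C_avg), modularity (Q) of a greedily detected partition,
global efficiency (E), average shortest path length on the largest
component (L_avg), relative largest component (S_max), small-world
coefficient (SW), per-node degree and clustering lists, and the physical
edge-length distribution (optionally normalized by the mean distance to
the eight nearest neighbors, which makes islets of different cell density
comparable).

Hub cells are the top fraction (default 1/6) of the degree ranking, and
``degree_activity_relation`` bins per-cell relative active time against
normalized degree to expose the more-active / better-connected relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .exceptions import ParameterError
from .construct import FunctionalNetwork

__all__ = [
    "NetworkMetrics",
    "compute_metrics",
    "edge_length_distribution",
    "identify_hubs",
    "degree_activity_relation",
]


@dataclass
class NetworkMetrics:
    """Flat record of the metric set for one network."""

    k_avg: float
    C_avg: float
    Q: float
    E: float
    L_avg: float
    S_max: float
    SW: float
    degree_list: np.ndarray
    clustering_list: np.ndarray
    partition: list[set] = field(default_factory=list)
    edge_lengths_um: np.ndarray | None = None
    edge_lengths_relative: np.ndarray | None = None

    def to_dict(self) -> dict:
        """Scalar metrics as a JSON-ready dict."""
        out = {}
        for key in ("k_avg", "C_avg", "Q", "E", "L_avg", "S_max", "SW"):
            v = getattr(self, key)
            out[key] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        return out


def _random_reference_stats(
    n: int, m: int, n_draws: int, seed: int, degree_sequence: list[int] | None
) -> tuple[float, float]:
    """Mean clustering and mean path length of random reference graphs.

    Density-matched references are Erdos-Renyi G(n, m) draws; the
    degree-preserving alternative rewires the observed graph by double
    edge swaps.  Path lengths are taken on the largest component.
    """
    cs, ls = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_draws):
        s = int(rng.integers(0, 2**31 - 1))
        if degree_sequence is None:
            g = nx.gnm_random_graph(n, m, seed=s)
        else:
            g = nx.configuration_model(degree_sequence, seed=s)
            g = nx.Graph(g)
            g.remove_edges_from(nx.selfloop_edges(g))
        cs.append(nx.average_clustering(g))
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        if sub.number_of_nodes() > 1:
            ls.append(nx.average_shortest_path_length(sub))
    return float(np.mean(cs)), float(np.mean(ls)) if ls else float("nan")


def compute_metrics(
    net: FunctionalNetwork,
    sw_randomizations: int = 20,
    seed: int = 0,
    sw_reference: str = "density",
) -> NetworkMetrics:
    """Compute the full metric set for a functional network.

    Parameters
    ----------
    net
        The network; at least 2 nodes.
    sw_randomizations
        Number of random reference graphs for the small-world coefficient
        SW = (C_avg / <C_rand>) / (L_avg / <L_rand>).
    seed
        Seed for the random references (the rest is deterministic).
    sw_reference
        ``"density"`` (default): references match N and edge count.
        ``"degree"``: references match the degree sequence (configuration
        model).

    Notes
    -----
    * Q is the Newman-Girvan modularity of the partition found by greedy
      modularity maximization; the partition is returned so Q can be
      recomputed from it.
    * L_avg is taken on the largest connected component (it is undefined
      for a disconnected graph); E averages 1/d over all ordered pairs
      with 1/inf = 0, so disconnection lowers E instead.
    * An empty edge set yields C_avg = 0, E = 0, Q = 0 and NaN for SW and
      L_avg.
    """
    g = net.graph
    n = net.n_nodes
    if n < 2:
        raise ParameterError("metrics need at least 2 nodes")
    m = net.n_edges

    degree_list = net.degrees()
    k_avg = 2.0 * m / n
    clustering = nx.clustering(g)
    clustering_list = np.array([clustering[c] for c in net.cell_ids], dtype=float)
    C_avg = float(clustering_list.mean())

    E = nx.global_efficiency(g)

    components = list(nx.connected_components(g))
    largest = max(components, key=len)
    S_max = len(largest) / n
    if len(largest) > 1:
        L_avg = float(nx.average_shortest_path_length(g.subgraph(largest)))
    else:
        L_avg = float("nan")

    if m == 0:
        Q = 0.0
        partition = [{c} for c in net.cell_ids]
        SW = float("nan")
    else:
        communities = nx.community.greedy_modularity_communities(g)
        partition = [set(c) for c in communities]
        Q = float(nx.community.modularity(g, partition))
        if sw_randomizations > 0 and not math.isnan(L_avg) and C_avg > 0:
            deg_seq = None
            if sw_reference == "degree":
                deg_seq = [int(d) for d in degree_list]
            elif sw_reference != "density":
                raise ParameterError(f"unknown sw_reference {sw_reference!r}")
            c_rand, l_rand = _random_reference_stats(n, m, sw_randomizations, seed, deg_seq)
            if c_rand > 0 and l_rand > 0 and not math.isnan(l_rand):
                SW = (C_avg / c_rand) / (L_avg / l_rand)
            else:
                SW = float("nan")
        else:
            SW = float("nan")

    lengths = lengths_rel = None
    if net.coords is not None:
        lengths = edge_length_distribution(net, normalize=False)
        lengths_rel = edge_length_distribution(net, normalize=True)

    return NetworkMetrics(
        k_avg=k_avg,
        C_avg=C_avg,
        Q=Q,
        E=float(E),
        L_avg=L_avg,
        S_max=float(S_max),
        SW=float(SW),
        degree_list=degree_list,
        clustering_list=clustering_list,
        partition=partition,
        edge_lengths_um=lengths,
        edge_lengths_relative=lengths_rel,
    )


def nearest_neighbor_scale(coords: np.ndarray, k: int = 8) -> float:
    """Mean over cells of the average distance to their k nearest neighbors.

    The normalization scale for relative edge lengths; with fewer than
    k + 1 cells the available N - 1 neighbors are used.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 cells")
    k_eff = min(k, n - 1)
    dmat = squareform(pdist(coords))
    np.fill_diagonal(dmat, np.inf)
    part = np.sort(dmat, axis=1)[:, :k_eff]
    return float(part.mean())


def edge_length_distribution(net: FunctionalNetwork, normalize: bool = False) -> np.ndarray:
    """Euclidean length of every edge, in micrometers.

    With ``normalize=True`` lengths are divided by the islet's
    :func:`nearest_neighbor_scale` (mean distance to the 8 nearest
    neighbors), making edge lengths comparable across islets of different
    cell density.  Islets with fewer than 9 cells fall back to all N - 1
    neighbors, with a logged warning.
    """
    if net.coords is None:
        raise ParameterError("network has no coordinates")
    idx = {c: i for i, c in enumerate(net.cell_ids)}
    lengths = np.array(
        [np.linalg.norm(net.coords[idx[u]] - net.coords[idx[v]]) for u, v in net.graph.edges],
        dtype=float,
    )
    if normalize:
        if net.n_nodes < 9:
            import logging

            logging.getLogger(__name__).warning(
                "only %d cells: normalizing with %d nearest neighbors",
                net.n_nodes, net.n_nodes - 1,
            )
        lengths = lengths / nearest_neighbor_scale(net.coords, k=8)
    return lengths


def identify_hubs(net: FunctionalNetwork, fraction: float = 1 / 6) -> set[str]:
    """Cells in the top ``fraction`` of the degree ranking (hub cells).

    Exactly ``ceil(fraction * N)`` cells are returned; ties at the cutoff
    are broken deterministically by cell-id order.
    """
    if not 0 < fraction < 1:
        raise ParameterError("fraction must be in (0, 1)")
    n_hubs = math.ceil(fraction * net.n_nodes)
    deg = dict(net.graph.degree)
    ranked = sorted(net.cell_ids, key=lambda c: (-deg[c], c))
    return set(ranked[:n_hubs])


def degree_activity_relation(
    net: FunctionalNetwork,
    relative_active_time: np.ndarray,
    n_bins: int = 10,
    normalize_activity: bool = False,
    degree_norm: str = "max",
):
    """Relate node degree to per-cell relative active time.

    Degrees are normalized per islet (``k / k_max`` by default,
    ``degree_norm="mean"`` gives ``k / k_avg``) and binned into
    ``n_bins`` equal-width bins over [0, 1]; empty bins are omitted.  With
    ``normalize_activity=True`` activity is divided by its islet mean,
    which is the form used when pooling several islets.

    Returns
    -------
    table : list of dict
        One row per non-empty bin: ``bin_center``, ``mean_activity``,
        ``sem``, ``n``.
    r : float
        Pearson correlation of (normalized degree, activity); NaN when
        degrees are constant.
    """
    rat = np.asarray(relative_active_time, dtype=float)
    if rat.shape != (net.n_nodes,):
        raise ParameterError("relative_active_time must cover all nodes")
    deg = net.degrees()
    if degree_norm == "max":
        scale = deg.max()
    elif degree_norm == "mean":
        scale = deg.mean()
    else:
        raise ParameterError(f"unknown degree_norm {degree_norm!r}")
    if scale == 0:
        norm_deg = np.zeros_like(deg)
    else:
        norm_deg = deg / scale
    act = rat / rat.mean() if (normalize_activity and rat.mean() > 0) else rat

    edges = np.linspace(0, max(1.0, norm_deg.max()), n_bins + 1)
    which = np.clip(np.digitize(norm_deg, edges) - 1, 0, n_bins - 1)
    table = []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        vals = act[mask]
        table.append(
            {
                "bin_center": float(0.5 * (edges[b] + edges[b + 1])),
                "mean_activity": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        )
    if np.ptp(deg) == 0:
        r = float("nan")  # correlation undefined for constant degrees
    elif np.ptp(act) == 0:
        r = 0.0  # flat activity: no relation
    else:
        r = float(stats.pearsonr(norm_deg, act)[0])
    return table, r
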