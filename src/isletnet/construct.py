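"""Functional-network construction from similarity matrices.

Three construction methods are provided:

``fixed_threshold``
    Connect cells i and j when their similarity coefficient strictly
    exceeds a preset threshold SC_th.

``fixed_kavg``
    Vary the threshold (bisection) until the network reaches a target
    average node degree; the default target of 8 mimics the connectivity
    of realistic beta-cell architectures.

``multilayer_mst``
    Union of edge-disjoint minimum spanning trees built sequentially on the
    abstract distance D_ij = 2 (1 - SC_ij): each layer is a Kruskal MST on
    the pairs not used by earlier layers.  One layer contributes N - 1
    edges (average degree ~2); four layers give average degree ~8.

A geometric reference network (connect physically nearby cells) stands in
for the structural, gap-junctional wiring of the islet, and an interval
carry-over helper re-applies a threshold calibrated on one protocol
interval to a second interval so that changes in coordinated activity show
up as changes in network density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import ConstructionError, InputError, ParameterError
from .similarity import SimilarityMatrix

__all__ = [
    "FunctionalNetwork",
    "DistanceMatrix",
    "fixed_threshold_network",
    "fixed_kavg_network",
    "to_distance",
    "multilayer_mst_network",
    "geometric_network",
    "interval_carryover_networks",
]

logger = logging.getLogger(__name__)


@dataclass
class FunctionalNetwork:
    """An undirected simple graph on cells, with construction provenance.

    ``graph`` is a :class:`networkx.Graph` whose nodes are cell ids (in a
    fixed order given by ``cell_ids``); ``coords`` are the planar positions
    in micrometers when known.  ``construction`` records the method and the
    threshold / layer parameters actually used.
    """

    graph: nx.Graph
    cell_ids: list[str]
    coords: np.ndarray | None = None
    construction: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.graph.nodes if c not in set(self.cell_ids)]
        if missing:
            raise ParameterError(f"graph contains unknown nodes: {missing[:5]}")
        if set(self.graph.nodes) != set(self.cell_ids):
            # ensure isolated cells are present as degree-0 nodes
            self.graph.add_nodes_from(self.cell_ids)
        if any(u == v for u, v in self.graph.edges):
            raise ParameterError("self-loops are not allowed")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (len(self.cell_ids), 2):
                raise ParameterError("coords shape does not match cell_ids")

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def k_avg(self) -> float:
        """Average node degree, 2 |E| / N."""
        return 2.0 * self.n_edges / self.n_nodes

    def edge_set(self) -> set[frozenset]:
        """Edges as a set of unordered cell-id pairs."""
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def degrees(self) -> np.ndarray:
        """Node degrees in ``cell_ids`` order."""
        d = dict(self.graph.degree)
        return np.array([d[c] for c in self.cell_ids], dtype=float)

    def coord_of(self, cell_id: str) -> np.ndarray:
        if self.coords is None:
            raise ParameterError("network has no coordinates")
        return self.coords[self.cell_ids.index(cell_id)]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative abstract distances D_ij between cells."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ParameterError("distance matrix must be square")
        finite = np.isfinite(self.values)
        if (self.values[finite] < 0).any():
            raise ParameterError("distances must be non-negative")
        if not np.array_equal(
            np.nan_to_num(self.values, posinf=9e99),
            np.nan_to_num(self.values.T, posinf=9e99),
        ):
            raise ParameterError("distance matrix is not symmetric")


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def _empty_graph(cell_ids: list[str]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(cell_ids)
    return g


def _threshold_graph(values: np.ndarray, cell_ids: list[str], th: float) -> nx.Graph:
    """Graph with an edge wherever values[i, j] > th (strict); NaN never connects."""
    with np.errstate(invalid="ignore"):
        adj = values > th
    g = _empty_graph(cell_ids)
    ii, jj = np.nonzero(np.triu(adj, k=1))
    g.add_edges_from((cell_ids[i], cell_ids[j]) for i, j in zip(ii, jj))
    return g


def _bisect_threshold(
    values: np.ndarray,
    cell_ids: list[str],
    target_kavg: float,
    tol: float,
    max_iter: int = 60,
    connect_below: bool = False,
) -> tuple[nx.Graph, float]:
    """Bisection on a scalar threshold until |k_avg - target| <= tol.

    ``connect_below=False``: edge iff value > th (similarity thresholding,
    k_avg non-increasing in th).  ``connect_below=True``: edge iff
    value <= th (geometric distance thresholding, k_avg non-decreasing).
    When ties make the tolerance unreachable the threshold whose k_avg is
    nearest the target is returned.
    """
    n = len(cell_ids)
    iu = np.triu_indices(n, k=1)
    vals = values[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ConstructionError("no finite pair values to threshold")
    max_kavg = 2.0 * finite.size / n
    if target_kavg > max_kavg + tol:
        raise ConstructionError(
            f"target k_avg {target_kavg} unreachable; maximum achievable "
            f"is {max_kavg:.3f} ({finite.size} finite pairs on {n} cells)"
        )
    if target_kavg <= 0:
        raise ParameterError("target k_avg must be positive")

    def kavg_at(th: float) -> float:
        with np.errstate(invalid="ignore"):
            m = np.count_nonzero(finite <= th) if connect_below else np.count_nonzero(finite > th)
        return 2.0 * m / n

    span = finite.max() - finite.min()
    pad = max(span, 1.0) * 1e-3
    lo = finite.min() - pad
    hi = finite.max() + pad
    # orient so that kavg(lo_end) >= target >= kavg(hi_end)
    best_th, best_err = lo, abs(kavg_at(lo) - target_kavg)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        k = kavg_at(mid)
        err = abs(k - target_kavg)
        if err < best_err - 1e-12:
            best_th, best_err = mid, err
        if err <= tol:
            best_th, best_err = mid, err
            break
        dense_side = k > target_kavg
        if connect_below:
            # k increases with th
            if dense_side:
                hi = mid
            else:
                lo = mid
        else:
            # k decreases with th
            if dense_side:
                lo = mid
            else:
                hi = mid
    if connect_below:
        with np.errstate(invalid="ignore"):
            adj = values <= best_th
        np.fill_diagonal(adj, False)
        adj &= np.isfinite(values)
        g = _empty_graph(cell_ids)
        ii, jj = np.nonzero(np.triu(adj, k=1))
        g.add_edges_from((cell_ids[i], cell_ids[j]) for i, j in zip(ii, jj))
    else:
        g = _threshold_graph(values, cell_ids, best_th)
    return g, best_th


# ----------------------------------------------------------------------
# constructions
# ----------------------------------------------------------------------

def fixed_threshold_network(
    S: SimilarityMatrix, sc_th: float, coords: np.ndarray | None = None
) -> FunctionalNetwork:
    """Connect every cell pair whose similarity strictly exceeds ``sc_th``.

    Undefined (NaN) pairs are never connected; ties at the threshold are
    excluded by the strict inequality.
    """
    g = _threshold_graph(S.values, S.cell_ids, sc_th)
    return FunctionalNetwork(
        graph=g,
        cell_ids=list(S.cell_ids),
        coords=coords,
        construction={
            "method": "fixed_threshold",
            "threshold_used": float(sc_th),
            "target_kavg": None,
            "n_layers": None,
            "similarity_method": S.method,
        },
    )


def fixed_kavg_network(
    S: SimilarityMatrix,
    target_kavg: float = 8.0,
    tol: float = 0.1,
    coords: np.ndarray | None = None,
) -> FunctionalNetwork:
    """Threshold a similarity matrix at the value that yields a target
    average degree.

    The threshold is found by bisection (at most 60 iterations); when ties
    in the similarity values make ``|k_avg - target| <= tol`` unreachable,
    the nearest achievable density is used.  The threshold actually applied
    is recorded in ``construction["threshold_used"]``.
    """
    g, th = _bisect_threshold(S.values, S.cell_ids, target_kavg, tol)
    return FunctionalNetwork(
        graph=g,
        cell_ids=list(S.cell_ids),
        coords=coords,
        construction={
            "method": "fixed_kavg",
            "threshold_used": float(th),
            "target_kavg": float(target_kavg),
            "n_layers": None,
            "similarity_method": S.method,
        },
    )


def to_distance(S: SimilarityMatrix) -> DistanceMatrix:
    """Convert similarity to the abstract distance D_ij = 2 (1 - SC_ij).

    Undefined similarity pairs map to infinite distance, so they are never
    chosen by spanning-tree construction while finite pairs remain.
    """
    d = 2.0 * (1.0 - S.values)
    d = np.where(np.isnan(S.values), np.inf, d)
    np.fill_diagonal(d, np.inf)
    return DistanceMatrix(values=d, cell_ids=list(S.cell_ids))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def multilayer_mst_network(
    S: SimilarityMatrix,
    n_layers: int = 4,
    coords: np.ndarray | None = None,
) -> FunctionalNetwork:
    """Union of ``n_layers`` edge-disjoint minimum spanning trees.

    Distances are D = 2 (1 - SC).  Layer 1 is the Kruskal MST of the
    complete distance graph; each further layer is the MST of the residual
    graph with all previously chosen edges excluded.  Every layer spans the
    N cells and contributes exactly N - 1 edges, so the union has
    ``n_layers * (N - 1)`` edges and every node has degree >= ``n_layers``.
    Equal distances are broken lexicographically on the cell-id pair for
    reproducibility.

    Raises
    ------
    ConstructionError
        If the residual graph disconnects before a layer completes; the
        message reports how many full layers were built.
    """
    if n_layers < 1:
        raise ParameterError("n_layers must be >= 1")
    D = to_distance(S)
    n = len(S.cell_ids)
    if n < 2:
        raise ParameterError("need at least 2 cells")
    iu, ju = np.triu_indices(n, k=1)
    w = D.values[iu, ju]
    finite = np.isfinite(w)
    pairs = sorted(
        zip(w[finite], iu[finite], ju[finite]),
        key=lambda t: (t[0], S.cell_ids[t[1]], S.cell_ids[t[2]]),
    )

    used: set[tuple[int, int]] = set()
    layers: list[list[tuple[int, int]]] = []
    for layer in range(n_layers):
        uf = _UnionFind(n)
        chosen: list[tuple[int, int]] = []
        for _, i, j in pairs:
            if (i, j) in used:
                continue
            if uf.union(i, j):
                chosen.append((i, j))
                if len(chosen) == n - 1:
                    break
        if len(chosen) < n - 1:
            raise ConstructionError(
                f"residual graph disconnected: completed {layer} full "
                f"layer(s), layer {layer + 1} stopped at {len(chosen)} edges"
            )
        used.update(chosen)
        layers.append(chosen)

    g = _empty_graph(list(S.cell_ids))
    for chosen in layers:
        g.add_edges_from((S.cell_ids[i], S.cell_ids[j]) for i, j in chosen)
    net = FunctionalNetwork(
        graph=g,
        cell_ids=list(S.cell_ids),
        coords=coords,
        construction={
            "method": "multilayer_mst",
            "threshold_used": None,
            "target_kavg": None,
            "n_layers": int(n_layers),
            "similarity_method": S.method,
        },
    )
    net.construction["layers"] = [
        [(S.cell_ids[i], S.cell_ids[j]) for i, j in chosen] for chosen in layers
    ]
    return net


def geometric_network(
    coords: np.ndarray,
    cell_ids: list[str] | None = None,
    mode: str = "target_kavg",
    value: float = 8.0,
    tol: float = 0.1,
) -> FunctionalNetwork:
    """Structural reference network: connect physically nearby cells.

    ``mode="distance"`` connects pairs with Euclidean separation
    <= ``value`` micrometers.  ``mode="target_kavg"`` (default) bisects the
    distance threshold until the average degree reaches ``value`` (default
    8, matching the functional networks it is compared against).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise ParameterError("coords must be an (n >= 2, 2) array")
    if not np.isfinite(coords).all():
        raise ParameterError("coords contain non-finite values")
    n = coords.shape[0]
    if cell_ids is None:
        cell_ids = [f"c{i:03d}" for i in range(n)]
    dmat = squareform(pdist(coords))
    np.fill_diagonal(dmat, np.nan)

    if mode == "distance":
        with np.errstate(invalid="ignore"):
            adj = dmat <= value
        g = _empty_graph(list(cell_ids))
        ii, jj = np.nonzero(np.triu(adj, k=1))
        g.add_edges_from((cell_ids[i], cell_ids[j]) for i, j in zip(ii, jj))
        th = float(value)
        target = None
    elif mode == "target_kavg":
        g, th = _bisect_threshold(dmat, list(cell_ids), value, tol, connect_below=True)
        target = float(value)
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    return FunctionalNetwork(
        graph=g,
        cell_ids=list(cell_ids),
        coords=coords,
        construction={
            "method": "geometric",
            "threshold_used": float(th),
            "target_kavg": target,
            "n_layers": None,
        },
    )


def interval_carryover_networks(
    S1: SimilarityMatrix,
    S2: SimilarityMatrix,
    target_kavg: float = 8.0,
    tol: float = 0.1,
    coords: np.ndarray | None = None,
) -> tuple[FunctionalNetwork, FunctionalNetwork]:
    """Calibrate a threshold on one interval, carry it to a second.

    The first network is built with the variable-threshold (fixed average
    degree) method on ``S1``; the second applies the threshold so obtained
    as a fixed threshold on ``S2``.  A rise or fall in coordinated activity
    between the intervals then appears directly as a change in the second
    network's density, which a fresh fixed-k_avg construction would hide.
    """
    if S1.cell_ids != S2.cell_ids:
        raise InputError("the two similarity matrices cover different cell sets")
    net1 = fixed_kavg_network(S1, target_kavg, tol, coords=coords)
    net2 = fixed_threshold_network(S2, net1.construction["threshold_used"], coords=coords)
    net2.construction["carryover_from"] = "interval_1"
    return net1, net2
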