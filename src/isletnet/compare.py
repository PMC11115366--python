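"""Inter-network comparison: edge overlap, hub overlap, degree pairing.

The network similarity index (NSI) is the Jaccard coefficient of two
networks' edge sets: |A intersection B| / |A union B|, 1 for identical
networks and 0 for edge-disjoint ones.  Hub overlap counts shared hub
cells (top 1/6 of the degree ranking by default) relative to the hub-set
size, and degree pairing fits a least-squares line through per-cell
(degree in A, degree in B) points, reporting its R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .construct import FunctionalNetwork
from .exceptions import InputError
from .metrics import identify_hubs

__all__ = ["NetworkSimilarityReport", "nsi", "hub_overlap", "degree_pairing", "compare_networks"]

logger = logging.getLogger(__name__)


@dataclass
class NetworkSimilarityReport:
    """Bundle of pairwise comparison results for two networks."""

    nsi: float
    hub_overlap: float
    degree_pairs: list[tuple[str, int, int]]
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "nsi": self.nsi,
            "hub_overlap": self.hub_overlap,
            "r_squared": None if np.isnan(self.r_squared) else self.r_squared,
            "degree_pairs": [
                {"cell_id": c, "degree_a": ka, "degree_b": kb}
                for c, ka, kb in self.degree_pairs
            ],
        }


def _check_same_cells(a: FunctionalNetwork, b: FunctionalNetwork) -> None:
    if set(a.cell_ids) != set(b.cell_ids):
        raise InputError("networks cover different cell sets")


def nsi(a: FunctionalNetwork, b: FunctionalNetwork) -> float:
    """Network similarity index: Jaccard overlap of the two edge sets.

    Two empty networks are defined as identical (NSI = 1) with a logged
    warning.
    """
    _check_same_cells(a, b)
    ea, eb = a.edge_set(), b.edge_set()
    union = ea | eb
    if not union:
        logger.warning("both networks are empty; NSI defined as 1")
        return 1.0
    return len(ea & eb) / len(union)


def hub_overlap(a: FunctionalNetwork, b: FunctionalNetwork, fraction: float = 1 / 6) -> float:
    """Fraction of hub cells shared by the two networks.

    Both hub sets have the same size ceil(fraction * N) by construction,
    which is the denominator.
    """
    _check_same_cells(a, b)
    ha = identify_hubs(a, fraction)
    hb = identify_hubs(b, fraction)
    return len(ha & hb) / len(ha)


def degree_pairing(a: FunctionalNetwork, b: FunctionalNetwork):
    """Per-cell degree pairs between two networks plus the R^2 of their
    least-squares linear relation.

    Returns ``(pairs, r_squared)`` where pairs is a list of
    ``(cell_id, degree_in_a, degree_in_b)``.  R^2 is NaN when either degree
    sequence is constant.
    """
    _check_same_cells(a, b)
    deg_a = dict(a.graph.degree)
    deg_b = dict(b.graph.degree)
    cells = sorted(a.cell_ids)
    pairs = [(c, int(deg_a[c]), int(deg_b[c])) for c in cells]
    ka = np.array([p[1] for p in pairs], dtype=float)
    kb = np.array([p[2] for p in pairs], dtype=float)
    if np.ptp(ka) == 0 or np.ptp(kb) == 0:
        return pairs, float("nan")
    fit = stats.linregress(ka, kb)
    return pairs, float(fit.rvalue**2)


def compare_networks(
    a: FunctionalNetwork, b: FunctionalNetwork, hub_fraction: float = 1 / 6
) -> NetworkSimilarityReport:
    """Full comparison report: NSI, hub overlap, degree pairing."""
    pairs, r2 = degree_pairing(a, b)
    return NetworkSimilarityReport(
        nsi=nsi(a, b),
        hub_overlap=hub_overlap(a, b, hub_fraction),
        degree_pairs=pairs,
        r_squared=r2,
    )
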