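"""Cell-pair similarity matrices: Pearson correlation, coactivity, and
normalized mutual information.

Pearson correlation is computed on (filtered) continuous traces; coactivity
and mutual information operate on binarized activity rasters.  All three
return a symmetric N x N :class:`SimilarityMatrix` whose diagonal and
undefined entries carry a NaN sentinel, which downstream edge logic ignores.

Conventions
-----------
* Coactivity is the cosine of the two binary activity vectors,
  ``sum(x_i * x_j) / sqrt(sum(x_i) * sum(x_j))`` — the unit-normalized dot
  product, which is 1 for identical rasters and 0 for non-overlapping ones.
  A ``literal_denominator`` flag computes the un-rooted variant
  ``sum(x_i * x_j) / (sum(x_i) * sum(x_j))`` for comparison; that form does
  not reach 1 for identical vectors.
* Entropies are in bits (base-2 logarithms).  Mutual information between
  two binary rasters is ``H_i + H_j - H_ij`` with probabilities estimated
  by frequency counts, and is normalized by the geometric mean
  ``sqrt(H_i * H_j)`` so that a series paired with itself scores exactly 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .preprocess import BinarizedActivity
from .recording import CalciumRecording

__all__ = [
    "SimilarityMatrix",
    "pearson_matrix",
    "coactivity_matrix",
    "entropy",
    "nmi_matrix",
]

logger = logging.getLogger(__name__)

#: Sentinel for undefined similarity entries (diagonal, degenerate cells).
UNDEFINED = np.nan


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise similarity coefficients SC_ij.

    ``values[i, j] == values[j, i]``; the diagonal is NaN and so are pairs
    involving degenerate cells (zero variance, all-inactive, or zero
    entropy, depending on the method).  ``method`` is one of
    ``{"correlation", "coactivity", "mutual_information"}``; ``source``
    is a free-form provenance record (band, interval, binarization
    parameters).
    """

    values: np.ndarray
    method: str
    cell_ids: list[str]
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ParameterError(f"similarity matrix must be square, got {self.values.shape}")
        if len(self.cell_ids) != n:
            raise ParameterError("cell_ids length does not match matrix size")
        if not np.array_equal(
            np.nan_to_num(self.values, nan=-9e9),
            np.nan_to_num(self.values.T, nan=-9e9),
        ):
            raise ParameterError("similarity matrix is not symmetric")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Finite upper-triangle entries (the pairs edge logic sees)."""
        iu = np.triu_indices(self.n_cells, k=1)
        vals = self.values[iu]
        return vals[np.isfinite(vals)]


def _finish(values: np.ndarray, method: str, cell_ids: list[str], source: dict | None) -> SimilarityMatrix:
    values = (values + values.T) / 2.0  # exact symmetry despite BLAS rounding
    np.fill_diagonal(values, UNDEFINED)
    return SimilarityMatrix(values=values, method=method, cell_ids=list(cell_ids), source=source or {})


# ----------------------------------------------------------------------
def pearson_matrix(rec: CalciumRecording, source: dict | None = None) -> SimilarityMatrix:
    """Pairwise sample Pearson correlation of the (filtered) traces.

    Zero-variance cells get a NaN row/column and a logged warning.  Requires
    at least 3 frames.
    """
    if rec.n_frames < 3:
        raise ParameterError("Pearson correlation needs at least 3 frames")
    x = rec.traces
    sd = x.std(axis=0)
    degenerate = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.corrcoef(x, rowvar=False)
    values = np.asarray(values, dtype=float)
    if degenerate.any():
        for j in np.flatnonzero(degenerate):
            logger.warning("cell %s has zero variance; correlations undefined", rec.cell_ids[j])
        values[degenerate, :] = UNDEFINED
        values[:, degenerate] = UNDEFINED
    values = np.clip(values, -1.0, 1.0)
    return _finish(values, "correlation", rec.cell_ids, source)


def coactivity_matrix(
    bin_act: BinarizedActivity,
    literal_denominator: bool = False,
    source: dict | None = None,
) -> SimilarityMatrix:
    """Coactivity coefficient CA_ij between binary activity vectors.

    The default (``literal_denominator=False``) is the unit-normalized dot
    product; see the module docstring for the variant.
    Cells with no active frame get a NaN row/column and a logged warning.
    """
    b = bin_act.states.astype(float)
    counts = b.sum(axis=0)
    overlap = b.T @ b
    if literal_denominator:
        denom = np.outer(counts, counts)
    else:
        denom = np.sqrt(np.outer(counts, counts))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = overlap / denom
    empty = counts == 0
    if empty.any():
        for j in np.flatnonzero(empty):
            logger.warning("cell %s has no active frames; coactivity undefined", bin_act.cell_ids[j])
        values[empty, :] = UNDEFINED
        values[:, empty] = UNDEFINED
    return _finish(values, "coactivity", bin_act.cell_ids, source)


# ----------------------------------------------------------------------
def entropy(bin_vector: np.ndarray) -> float:
    """Shannon entropy of a binary vector in bits.

    Probabilities are frequency counts over the vector length;
    ``0 * log2(0)`` is taken as 0, so a constant vector has zero entropy.
    """
    v = np.asarray(bin_vector)
    if v.size == 0:
        raise ParameterError("entropy of an empty vector is undefined")
    p1 = float(np.count_nonzero(v)) / v.size
    h = 0.0
    for p in (p1, 1.0 - p1):
        if p > 0:
            h -= p * np.log2(p)
    return h


def nmi_matrix(bin_act: BinarizedActivity, source: dict | None = None) -> SimilarityMatrix:
    """Normalized mutual information between binary activity vectors.

    MI_ij = H_i + H_j - H_ij with the joint entropy over the four
    (s_i, s_j) state combinations, all in bits; the matrix entry is
    MI_ij / sqrt(H_i * H_j).  Pairs involving a zero-entropy cell
    (constant raster) are NaN with a logged warning.
    """
    b = bin_act.states.astype(float)
    n_frames, n_cells = b.shape
    counts = b.sum(axis=0)

    # joint counts of the four (s_i, s_j) combinations, all pairs at once
    n11 = b.T @ b
    n10 = counts[:, None] - n11          # i active, j inactive
    n01 = counts[None, :] - n11
    n00 = n_frames - n11 - n10 - n01

    def plogp(n: np.ndarray) -> np.ndarray:
        p = n / n_frames
        with np.errstate(divide="ignore", invalid="ignore"):
            term = p * np.log2(p)
        return np.where(n > 0, term, 0.0)

    h_joint = -(plogp(n11) + plogp(n10) + plogp(n01) + plogp(n00))

    h_marg = np.array([entropy(b[:, j]) for j in range(n_cells)])
    mi = h_marg[:, None] + h_marg[None, :] - h_joint
    mi = np.maximum(mi, 0.0)  # clip tiny negative rounding

    denom = np.sqrt(np.outer(h_marg, h_marg))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = mi / denom
    zero_h = h_marg == 0
    if zero_h.any():
        for j in np.flatnonzero(zero_h):
            logger.warning("cell %s has zero entropy; NMI undefined", bin_act.cell_ids[j])
        values[zero_h, :] = UNDEFINED
        values[:, zero_h] = UNDEFINED
    values = np.clip(values, 0.0, 1.0)
    # enforce exact symmetry against floating-point asymmetry in the BLAS product
    values = (values + values.T) / 2.0
    return _finish(values, "mutual_information", bin_act.cell_ids, source)
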