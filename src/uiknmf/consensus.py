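"""Consensus matrices over NMF restarts and the cophenetic correlation.

One NMF run clusters the samples: each sample goes to the metagene with the
largest coefficient in its column of ``H``.  The run's *connectivity matrix*
is the binary sample-by-sample indicator of shared cluster membership; the
*consensus matrix* averages connectivity over restarts, so entry (j, k)
estimates the probability that samples j and k co-cluster.  The *cophenetic
correlation coefficient* measures how tree-like the consensus is: it is the
Pearson correlation between the consensus-induced distances ``1 - C`` and the
ultrametric (cophenetic) distances of their average-linkage dendrogram.
Values near 1 indicate stable clustering at that rank.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .errors import ArgumentError, DimensionError

__all__ = [
    "ConnectivityMatrix",
    "ConsensusMatrix",
    "connectivity",
    "consensus",
    "cophenetic_coefficient",
]


@dataclass
class ConnectivityMatrix:
    """Binary n x n co-clustering indicator from a single run."""

    values: np.ndarray
    derived_from: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class ConsensusMatrix:
    """Mean of connectivity matrices over restarts; entries in [0, 1]."""

    values: np.ndarray
    n_runs: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


def connectivity(H: np.ndarray, derived_from: str = "") -> ConnectivityMatrix:
    """Connectivity matrix of the coefficient matrix ``H`` (r x n).

    Sample j is assigned to ``argmax`` over the r rows of column j; ties, and
    all-zero columns (with a warning), resolve to the lowest row index.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise DimensionError(f"H must be a 2-D r x n array, got shape {H.shape}")
    zero_cols = np.flatnonzero(H.sum(axis=0) == 0)
    if zero_cols.size:
        warnings.warn(
            f"all-zero coefficient columns {zero_cols.tolist()} assigned to metagene 0",
            stacklevel=2,
        )
    assign = np.argmax(H, axis=0)  # argmax takes the first maximum: ties -> lowest row
    values = (assign[:, None] == assign[None, :]).astype(float)
    return ConnectivityMatrix(values=values, derived_from=derived_from)


def consensus(runs: list[ConnectivityMatrix]) -> ConsensusMatrix:
    """Elementwise mean of connectivity matrices over restarts."""
    if not runs:
        raise ArgumentError("consensus requires at least one connectivity matrix")
    mats = [np.asarray(r.values, dtype=float) for r in runs]
    n = mats[0].shape[0]
    for M in mats:
        if M.shape != (n, n):
            raise DimensionError(f"connectivity shapes differ: {M.shape} vs {(n, n)}")
    C = np.mean(mats, axis=0)
    np.fill_diagonal(C, 1.0)
    return ConsensusMatrix(values=C, n_runs=len(mats))


def cophenetic_coefficient(C: ConsensusMatrix | np.ndarray) -> float:
    """Cophenetic correlation of a consensus matrix.

    The consensus is turned into the distance matrix ``D = 1 - C``, clustered
    by average linkage, and the Pearson correlation between the n(n-1)/2
    off-diagonal distances and the dendrogram's cophenetic distances is
    returned.  A perfectly uniform consensus has zero distance variance and
    no defined correlation: NaN is returned as the flagged-undefined value so
    rank surveys over degenerate ranks still complete.
    """
    V = C.values if isinstance(C, ConsensusMatrix) else np.asarray(C, dtype=float)
    n = V.shape[0]
    if V.ndim != 2 or V.shape != (n, n):
        raise DimensionError(f"consensus must be square, got shape {V.shape}")
    if n < 3:
        raise ArgumentError(f"cophenetic correlation needs n >= 3 samples, got {n}")
    D = 1.0 - V
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry before condensing
    d = squareform(D, checks=False)
    if d.std() == 0.0:
        return math.nan
    Z = linkage(d, method="average")
    coph_d = cophenet(Z)
    if coph_d.std() == 0.0:
        return math.nan
    return float(np.corrcoef(d, coph_d)[0, 1])
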