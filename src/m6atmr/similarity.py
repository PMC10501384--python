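"""Sequence-set similarity from pairwise Manhattan distances.

The m sequences of a dataset are compared through the Manhattan (L1)
distance between their k-mer frequency vectors, giving an m-by-m distance
matrix.  Downstream graph operations need an affinity in [0, 1] oriented
"large = similar", so the distance matrix is passed through a
distance-to-similarity transform: an RBF kernel exp(-d/sigma) with sigma set
to the median off-diagonal distance (default), or the max-complement
1 - d/max(d).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["manhattan", "build_distance_matrix", "distance_to_similarity"]


def manhattan(u: np.ndarray, v: np.ndarray) -> float:
    """L1 distance sum_j |u_j - v_j| between two equal-length vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(np.abs(u - v).sum())


def build_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """Full m-by-m pairwise Manhattan distance matrix (m >= 2 rows)."""
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two row vectors")
    D = cdist(X, X, metric="cityblock")
    return 0.5 * (D + D.T)  # enforce exact symmetry


def distance_to_similarity(D: np.ndarray, mode: str = "rbf",
                           bandwidth_quantile: float = 0.5) -> np.ndarray:
    """Map a distance matrix to a symmetric affinity in [0, 1], diagonal 1.

    ``rbf``: exp(-d/sigma) with sigma the given quantile of the strictly-
    upper-triangle distances (default: the median; smaller quantiles give a
    sharper, more neighborhood-concentrated affinity; falls back to the mean,
    then to 1, when the quantile is zero).  ``max-complement``: 1 - d/max(d);
    an all-zero D yields an all-ones matrix with a warning.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    if not 0.0 < bandwidth_quantile <= 1.0:
        raise ValueError("bandwidth_quantile must lie in (0, 1]")
    if mode == "rbf":
        upper = D[np.triu_indices_from(D, k=1)]
        sigma = float(np.quantile(upper, bandwidth_quantile)) if upper.size else 0.0
        if sigma == 0.0:
            sigma = float(np.mean(upper)) if upper.size else 0.0
        if sigma == 0.0:
            sigma = 1.0
        S = np.exp(-D / sigma)
    elif mode == "max-complement":
        dmax = D.max()
        if dmax == 0.0:
            warnings.warn("all distances are zero; similarity matrix is all ones")
            S = np.ones_like(D)
        else:
            S = 1.0 - D / dmax
    else:
        raise ValueError(f"unknown mode {mode!r} (rbf | max-complement)")
    np.fill_diagonal(S, 1.0)
    return 0.5 * (S + S.T)
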