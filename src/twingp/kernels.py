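"""Kernel feature maps for the twin regression models.

Two feature maps are supported: the identity (linear model in marker
space) and the Gaussian radial basis function

    K(x, x') = exp(-||x - x'||^2 / (2 sigma^2)),

which maps samples into a reproducing kernel Hilbert space; the fitted
weight vector then has one entry per training sample.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances

from .data import GenotypeMatrix


def _values(X) -> np.ndarray:
    """Row matrix of an array or GenotypeMatrix; single rows allowed."""
    if isinstance(X, GenotypeMatrix):
        return X.values
    return np.atleast_2d(np.asarray(X, dtype=float))


def rbf_kernel(A, B, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix between the rows of A and the rows of B.

    Entry (i, j) is ``exp(-||A_i - B_j||^2 / (2 sigma^2))``.

    Parameters
    ----------
    A : (a, m) array
    B : (b, m) array
    sigma : float
        Kernel width, strictly positive.

    Returns
    -------
    (a, b) ndarray with entries in (0, 1].
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"column mismatch: A has {A.shape[1]} features, B has {B.shape[1]}"
        )
    sq = euclidean_distances(A, B, squared=True)
    np.maximum(sq, 0.0, out=sq)
    K = np.exp(-sq / (2.0 * sigma * sigma))
    return K


def build_feature_matrix(X, train_X, kernel: str = "linear",
                         sigma: float | None = None) -> np.ndarray:
    """Feature matrix H used inside the twin linear systems.

    For ``kernel='linear'`` this is X itself (the bias column is handled
    explicitly by the solver, not appended here).  For ``kernel='rbf'``
    it is the n x n_train kernel matrix K(X, train_X).
    """
    Xv = _values(X)
    if kernel == "linear":
        return Xv
    if kernel == "rbf":
        Tv = _values(train_X)
        if Xv.shape[1] != Tv.shape[1]:
            raise ValueError(
                f"marker count mismatch: {Xv.shape[1]} vs {Tv.shape[1]}"
            )
        if sigma is None:
            raise ValueError("sigma is required for the rbf kernel")
        return rbf_kernel(Xv, Tv, sigma)
    raise ValueError(f"unknown kernel {kernel!r} (expected 'linear' or 'rbf')")
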