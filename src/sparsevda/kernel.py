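"""Gaussian kernel evaluation for nonlinear VDA."""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf


def rbf_kernel(X1: np.ndarray, X2: np.ndarray, gamma: float) -> np.ndarray:
    """Entry (i, j) = exp(-gamma * ||x1_i - x2_j||^2).

    Symmetric and positive semidefinite when ``X1 is X2``; gamma sets the
    inverse squared length scale of the decision boundary.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("feature dimensions differ")
    return _sk_rbf(X1, X2, gamma=gamma)
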