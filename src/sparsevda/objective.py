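"""The epsilon-insensitive risk, its quadratic MM surrogate, and gradients.

The empirical risk of a slope matrix B on data (X, Y) is

    f(B) = (1/2n) sum_i max(0, ||y_i - B^T x_i|| - eps)^2,

an epsilon-insensitive squared loss: a residual incurs no loss while the
prediction stays within a Euclidean eps-ball of its class vertex.  Distance
majorization of each term around an anchor B_m yields an ordinary
least-squares surrogate with *shifted responses* z_i,

    g(B | B_m) = (1/2n) ||Z_m - X B||_F^2,

where z_i equals the anchor prediction for loss-free samples and otherwise
pulls the response toward y_i with weight w_i = (||r_i|| - eps)/||r_i||.
Sparsity enters through the penalized objective

    f_rho(B) = f(B) + (rho/2) dist(B, S)^2,

majorized by g(B | B_m) + (rho/2) ||B - P_S(B_m)||_F^2.  By MM tangency the
gradient of f_rho at the anchor equals the surrogate gradient there, which
is what the solvers' stopping rules exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .projections import Constraint


@dataclass
class SurrogateState:
    """Per-iteration MM bookkeeping around an anchor matrix B_m.

    ``pred`` caches the anchor predictions X B_m so downstream gradient
    evaluations need no extra multiply: Z - X B_m equals the weighted
    residual rows w_i r_i by construction.
    """

    B_anchor: np.ndarray
    Z: np.ndarray
    weights: np.ndarray
    residual_norms: np.ndarray
    P: Optional[np.ndarray] = field(default=None)
    pred: Optional[np.ndarray] = field(default=None, repr=False)


def _check_shapes(B, X, Y=None):
    B = np.asarray(B, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != B.shape[0]:
        raise ValueError(
            f"design has {X.shape[1]} columns but B has {B.shape[0]} rows")
    if Y is not None:
        Y = np.asarray(Y, dtype=float)
        if Y.shape != (X.shape[0], B.shape[1]):
            raise ValueError("Y shape inconsistent with X and B")
    return B, X, Y


def epsilon_risk(B: np.ndarray, X: np.ndarray, Y: np.ndarray,
                 epsilon: float) -> float:
    """(1/2n) sum_i max(0, ||y_i - B^T x_i|| - eps)^2.

    ``X`` is the design matrix actually multiplying ``B`` (a ones column is
    the caller's responsibility when an intercept row is present).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    B, X, Y = _check_shapes(B, X, Y)
    r = np.linalg.norm(Y - X @ B, axis=1)
    excess = np.maximum(0.0, r - epsilon)
    return float(0.5 * np.mean(excess**2))


def surrogate_responses(B_anchor: np.ndarray, X: np.ndarray, Y: np.ndarray,
                        epsilon: float) -> SurrogateState:
    """Shifted responses Z_m and weights w_m around the anchor.

    Samples with ||r_i|| <= eps (boundary inclusive) are loss-free and get
    z_i equal to their own anchor prediction; the rest get the convex
    combination w_i y_i + (1 - w_i) x_i^T B_m with
    w_i = (||r_i|| - eps)/||r_i||.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    B_anchor, X, Y = _check_shapes(B_anchor, X, Y)
    pred = X @ B_anchor
    R = Y - pred
    r = np.linalg.norm(R, axis=1)
    w = np.zeros_like(r)
    outside = r > epsilon
    w[outside] = (r[outside] - epsilon) / r[outside]
    Z = pred + w[:, None] * R
    return SurrogateState(B_anchor=B_anchor, Z=Z, weights=w,
                          residual_norms=r, P=None, pred=pred)


def surrogate_value(B: np.ndarray, state: SurrogateState, X: np.ndarray,
                    rho: float) -> float:
    """(1/2n)||Z - XB||_F^2 + (rho/2)||B - P||_F^2.

    ``state.P`` must have been filled by the solver (the projection of the
    anchor onto the constraint set, intercept row copied through when the
    model has one -- so the penalty vanishes on that row at the anchor).
    """
    if state.P is None:
        raise ValueError("state.P is unset; project the anchor first")
    B, X, _ = _check_shapes(B, X)
    n = X.shape[0]
    value = 0.5 / n * np.linalg.norm(state.Z - X @ B) ** 2
    if rho > 0:
        value += 0.5 * rho * np.linalg.norm(B - state.P) ** 2
    return float(value)


def penalized_objective(B: np.ndarray, X: np.ndarray, Y: np.ndarray,
                        epsilon: float, constraint: Optional[Constraint],
                        rho: float) -> float:
    """f_rho(B) = epsilon risk + (rho/2) dist(B, S)^2."""
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    value = epsilon_risk(B, X, Y, epsilon)
    if constraint is not None and rho > 0:
        value += 0.5 * rho * constraint.distance(np.asarray(B, dtype=float)) ** 2
    return float(value)


def surrogate_gradient(B: np.ndarray, state: SurrogateState, X: np.ndarray,
                       rho: float) -> np.ndarray:
    """-n^{-1} X^T (Z - XB) + rho (B - P).

    Evaluated at B = B_anchor this equals the gradient of the penalized
    objective at the anchor (MM tangency), including the intercept row,
    whose penalty term is identically zero there.
    """
    if state.P is None and rho > 0:
        raise ValueError("state.P is unset; project the anchor first")
    B, X, _ = _check_shapes(B, X)
    n = X.shape[0]
    G = -(X.T @ (state.Z - X @ B)) / n
    if rho > 0:
        G = G + rho * (B - state.P)
    return G
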