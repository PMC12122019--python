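"""MM solvers for penalized VDA and the annealed proximal distance iteration.

For a fixed penalty strength rho the quadratic surrogate is minimized either

* exactly (``method="direct"``): the update
  B+ = (n^{-1} X^T X + rho I)^{-1} (n^{-1} X^T Z + rho P)
  is evaluated through a thin SVD of the design so that only a diagonal
  depending on (singular values, n, rho) changes as rho moves along the
  annealing path; or
* by one exact line search along the negative gradient
  (``method="steepest"``), with step
  gamma = ||G||_F^2 / (n^{-1} ||X G||_F^2 + rho ||G||_F^2),
  which is the 1-D minimizer of the quadratic surrogate and never requires
  a factorization.

The outer loop anneals rho geometrically, warm-starting each subproblem from
the previous solution.  Convergence is declared when the gradient norm of
the penalized objective (computed through MM tangency) is small AND the
distance to the constraint set is either small or has stopped changing --
possibly well before rho reaches its cap (early exit).  The returned
coefficients are exactly feasible: the last iterate is projected onto the
constraint set, optionally followed by a "polish" refit of the surviving
coordinates at rho = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .objective import SurrogateState, surrogate_responses
from .projections import Constraint


# --------------------------------------------------------------------------
# SVD cache

@dataclass
class SVDCache:
    """Thin SVD of a design matrix, trimmed to numerical rank."""

    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray

    @property
    def r(self) -> int:
        return len(self.singular_values)


def build_svd_cache(design: np.ndarray) -> SVDCache:
    """Thin SVD of ``design`` with small singular values dropped.

    Computed once per training design and reused across every (k, rho,
    epsilon) setting the solvers visit.
    """
    design = np.asarray(design, dtype=float)
    if design.size == 0:
        raise ValueError("design is empty")
    if not np.all(np.isfinite(design)):
        raise ValueError("design contains non-finite entries")
    U, s, Vt = np.linalg.svd(design, full_matrices=False)
    tol = s[0] * max(design.shape) * np.finfo(float).eps if s.size else 0.0
    r = int(np.sum(s > tol))
    return SVDCache(U=U[:, :r], singular_values=s[:r], V=Vt[:r].T)


# --------------------------------------------------------------------------
# Controls / results

@dataclass
class SolverControls:
    """Tolerances and iteration caps shared by the inner and outer loops.

    ``grad_tol`` of None resolves to grad_tol_base * sqrt(q * c) *
    max(1, rho): the gradient criterion scales with the size of the
    coefficient matrix and relaxes with the penalty strength.  The inner
    solutions at *small* rho decide which coordinates ultimately survive,
    so they are solved to high precision; at large rho the gradient is
    dominated by the (rho-proportional) penalty term and chasing an
    absolute tolerance there buys nothing.
    """

    grad_tol: Optional[float] = None
    grad_tol_base: float = 3e-6
    dist_tol: float = 1e-3
    dist_change_tol: float = 1e-6
    max_inner: int = 1000
    accel: bool = True
    seed: int = 0

    def resolved_grad_tol(self, q: int, c: int, rho: float = 1.0) -> float:
        if self.grad_tol is not None:
            return self.grad_tol
        return self.grad_tol_base * np.sqrt(q * c) * max(1.0, rho)


@dataclass
class AnnealingSchedule:
    """Geometric schedule rho_t = min(rho_max, rho0 * multiplier^t).

    The path starts at a rho small enough that the loss still dominates
    (the support-determining phase) and grows geometrically until the
    iterate is numerically feasible; the outer loop usually exits on the
    distance criterion long before rho_max.
    """

    rho0: float = 1e-4
    multiplier: float = 3.0
    rho_max: float = 1e6
    max_outer: int = 40

    def __post_init__(self):
        if not (self.rho0 > 0 and self.multiplier > 1 and
                self.rho_max >= self.rho0):
            raise ValueError("require rho0 > 0, multiplier > 1, "
                             "rho_max >= rho0")

    def rho(self, t: int) -> float:
        return min(self.rho_max, self.rho0 * self.multiplier**t)


@dataclass
class FitResult:
    """Outcome of a proximal distance fit.

    ``B`` includes the intercept row when the model has one and lies exactly
    in the constraint set.  ``support`` indexes nonzero slope rows;
    ``per_class_support`` holds one index array per class for column-sparse
    constraints.
    """

    B: np.ndarray
    support: np.ndarray
    per_class_support: Optional[list]
    converged: bool
    rho_final: float
    n_outer: int
    n_inner_total: int
    objective_trace: List[List[float]] = field(default_factory=list, repr=False)
    dist_trace: List[float] = field(default_factory=list, repr=False)


# --------------------------------------------------------------------------
# Updates

def mm_direct_update(state: SurrogateState, X: np.ndarray, rho: float,
                     cache: Optional[SVDCache] = None) -> np.ndarray:
    """Exact surrogate minimizer (n^{-1}X^T X + rho I)^{-1}(n^{-1}X^T Z + rho P).

    With a cache the inverse is applied through the thin SVD X = U S V^T:

        (n^{-1} V S^2 V^T + rho I)^{-1} M
            = V diag(1/(s^2/n + rho)) V^T M + (M - V V^T M) / rho,

    so changing rho only changes a diagonal.  Without a cache a dense
    symmetric solve is used (the independent oracle path in the tests).
    """
    if rho <= 0:
        raise ValueError("rho must be positive; use fit_unconstrained "
                         "for the unpenalized solve")
    if state.P is None:
        raise ValueError("state.P is unset")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    M = X.T @ state.Z / n + rho * state.P
    if cache is None:
        q = X.shape[1]
        return np.linalg.solve(X.T @ X / n + rho * np.eye(q), M)
    s, V = cache.singular_values, cache.V
    d = 1.0 / (s**2 / n + rho) - 1.0 / rho
    VtM = V.T @ M
    return V @ (d[:, None] * VtM) + M / rho


def steepest_descent_update(state: SurrogateState, X: np.ndarray, rho: float,
                            G: Optional[np.ndarray] = None):
    """One exact-step gradient move on the surrogate; returns (B_new, step)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if G is None:
        from .objective import surrogate_gradient
        G = surrogate_gradient(state.B_anchor, state, X, rho)
    gsq = np.linalg.norm(G) ** 2
    if gsq == 0.0:
        return state.B_anchor.copy(), 0.0
    denom = np.linalg.norm(X @ G) ** 2 / n + rho * gsq
    gamma = gsq / denom
    return state.B_anchor - gamma * G, float(gamma)


def _risk_from_norms(residual_norms: np.ndarray, epsilon: float) -> float:
    excess = np.maximum(0.0, residual_norms - epsilon)
    return float(0.5 * np.mean(excess**2))


def _evaluate(B, X, Y, epsilon, constraint, rho):
    """Surrogate state at B plus f_rho(B); P filled from the constraint."""
    state = surrogate_responses(B, X, Y, epsilon)
    f = _risk_from_norms(state.residual_norms, epsilon)
    if constraint is not None:
        state.P = constraint.project(B)
        if rho > 0:
            f += 0.5 * rho * np.linalg.norm(B - state.P) ** 2
    return state, f


def _gradient_at(B, state, X, rho):
    n = X.shape[0]
    if state.pred is not None and B is state.B_anchor:
        resid = state.Z - state.pred  # equals the weighted residuals w_i r_i
    else:
        resid = state.Z - X @ B
    G = -(X.T @ resid) / n
    if rho > 0 and state.P is not None:
        G = G + rho * (B - state.P)
    return G


def inner_solve(B_init: np.ndarray, X: np.ndarray, Y: np.ndarray,
                epsilon: float, constraint: Optional[Constraint], rho: float,
                controls: SolverControls, method: str = "direct",
                cache: Optional[SVDCache] = None):
    """Minimize f_rho at fixed rho by MM until the gradient criterion holds.

    Returns ``(B, info)`` where ``info`` records iterations, the final
    gradient norm, whether the gradient condition was met, and the trace of
    penalized objective values.  With Nesterov acceleration, momentum steps
    that increase the objective are discarded and the momentum restarted.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    grad_tol = controls.resolved_grad_tol(*B_init.shape, rho=rho)

    def step(state):
        if method == "direct":
            return mm_direct_update(state, X, rho, cache=cache)
        if method == "steepest":
            G = _gradient_at(state.B_anchor, state, X, rho)
            return steepest_descent_update(state, X, rho, G=G)[0]
        raise ValueError(f"unknown method {method!r}")

    B = np.asarray(B_init, dtype=float).copy()
    B_old = B
    state, f_cur = _evaluate(B, X, Y, epsilon, constraint, rho)
    trace = [f_cur]
    gnorm = np.inf
    converged = False
    m_used = 0
    for m in range(controls.max_inner):
        G = _gradient_at(B, state, X, rho)
        gnorm = float(np.linalg.norm(G))
        if gnorm <= grad_tol:
            converged = True
            break
        use_momentum = controls.accel and m >= 1
        if use_momentum:
            weight = (m - 1) / (m + 2)
            C = B + weight * (B - B_old)
            state_C, _ = _evaluate(C, X, Y, epsilon, constraint, rho)
            B_new = step(state_C)
            state_new, f_new = _evaluate(B_new, X, Y, epsilon, constraint, rho)
            if f_new > f_cur + 1e-12:  # restart: plain MM step from B
                B_new = step(state)
                state_new, f_new = _evaluate(B_new, X, Y, epsilon,
                                             constraint, rho)
                B_old = B_new  # momentum reset
            else:
                B_old = B
        else:
            B_new = step(state)
            state_new, f_new = _evaluate(B_new, X, Y, epsilon, constraint, rho)
            B_old = B
        B, state, f_cur = B_new, state_new, f_new
        trace.append(f_cur)
        m_used = m + 1
    info = {"n_iter": m_used, "grad_norm": gnorm, "grad_ok": converged,
            "trace": trace}
    return B, info


def fit_unconstrained(X: np.ndarray, Y: np.ndarray, epsilon: float,
                      cache: Optional[SVDCache] = None,
                      B_init: Optional[np.ndarray] = None,
                      grad_tol: Optional[float] = None,
                      max_iter: int = 200,
                      rcond: float = 1e-6) -> np.ndarray:
    """Minimize the plain epsilon-insensitive risk (no penalty).

    Each MM step solves the shifted least-squares problem by the minimum-norm
    solution through the design's thin SVD; when the design is rank deficient
    the iterates stay in its row space, so the result is the canonical
    minimum-norm minimizer.  Singular values below ``rcond`` times the
    largest are dropped from the solve: kernel designs have continuously
    decaying spectra, and inverting the tail produces astronomically large
    interpolators that poison everything downstream.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if cache is None:
        cache = build_svd_cache(X)
    n, q = X.shape
    c = Y.shape[1]
    if grad_tol is None:
        grad_tol = 1e-4 * np.sqrt(q * c)
    U, s, V = cache.U, cache.singular_values, cache.V
    keep = s > rcond * s[0]
    U, s, V = U[:, keep], s[keep], V[:, keep]
    B = np.zeros((q, c)) if B_init is None else np.asarray(B_init, float).copy()
    for _ in range(max_iter):
        state = surrogate_responses(B, X, Y, epsilon)
        G = _gradient_at(B, state, X, 0.0)
        # stationarity is only attainable within the retained row space
        if np.linalg.norm(V.T @ G) <= grad_tol:
            break
        B = V @ ((U.T @ state.Z) / s[:, None])
    return B


# --------------------------------------------------------------------------
# Outer iteration

def _support_from_B(B: np.ndarray, constraint: Constraint):
    slopes = B[1:] if constraint.exclude_intercept else B
    row_norms = np.linalg.norm(slopes, axis=1)
    support = np.flatnonzero(row_norms > 0)
    per_class = None
    if constraint.variant in ("col_sparse", "global_sparse", "l1_col", "l1"):
        per_class = [np.flatnonzero(slopes[:, j] != 0)
                     for j in range(slopes.shape[1])]
    return support, per_class


def _polish_on_support(B: np.ndarray, X: np.ndarray, Y: np.ndarray,
                       epsilon: float, max_iter: int = 100,
                       tol: float = 1e-8) -> np.ndarray:
    """Refit the nonzero coordinates of a feasible B at rho = 0.

    Column-separable given the shifted responses: each class column solves an
    ordinary least-squares problem restricted to its own active design
    columns.  Projection alone truncates coefficients; this removes that
    bias without altering the selected support.
    """
    B = B.copy()
    masks = [np.flatnonzero(B[:, j] != 0) for j in range(B.shape[1])]
    pinvs = [np.linalg.pinv(X[:, idx]) if idx.size else None for idx in masks]
    for _ in range(max_iter):
        state = surrogate_responses(B, X, Y, epsilon)
        B_prev = B.copy()
        for j, idx in enumerate(masks):
            if idx.size:
                B[idx, j] = pinvs[j] @ state.Z[:, j]
        if np.linalg.norm(B - B_prev) <= tol * (1 + np.linalg.norm(B)):
            break
    return B


def proximal_distance_fit(X: np.ndarray, Y: np.ndarray, epsilon: float,
                          constraint: Constraint,
                          schedule: Optional[AnnealingSchedule] = None,
                          controls: Optional[SolverControls] = None,
                          method: str = "direct",
                          cache: Optional[SVDCache] = None,
                          B_init: Optional[np.ndarray] = None,
                          polish: bool = False) -> FitResult:
    """Annealed proximal distance iteration with warm starts and early exit.

    At each outer step t the subproblem at rho_t is solved from the previous
    solution; convergence requires BOTH the inner gradient condition and the
    distance condition (q_t <= dist_tol, or |q_t - q_{t-1}| <= the change
    tolerance), whether or not rho has reached its maximum.  The final
    iterate is projected onto the constraint set so the returned matrix is
    exactly feasible.
    """
    schedule = schedule or AnnealingSchedule()
    controls = controls or SolverControls()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, q = X.shape
    c = Y.shape[1]
    if method == "direct" and cache is None:
        cache = build_svd_cache(X)
    B = np.zeros((q, c)) if B_init is None else np.asarray(B_init, float).copy()

    obj_trace: List[List[float]] = []
    dist_trace: List[float] = []
    converged = False
    rho = schedule.rho0
    n_inner = 0
    t_used = 0
    q_prev = None
    for t in range(schedule.max_outer):
        rho = schedule.rho(t)
        B, info = inner_solve(B, X, Y, epsilon, constraint, rho, controls,
                              method=method, cache=cache)
        n_inner += info["n_iter"]
        obj_trace.append(info["trace"])
        q_t = constraint.distance(B)
        dist_trace.append(q_t)
        t_used = t + 1
        # Feasibility is judged relative to the coefficient scale: a
        # diffuse small-magnitude iterate (e.g. kernel weights) can sit
        # within any absolute threshold of a sparse set while still being
        # far from a meaningful sparse model.
        scale = max(np.linalg.norm(B), np.finfo(float).tiny)
        # The stall exit (distance no longer moving) is only trusted once
        # the penalty has real strength; early on, consecutive solutions
        # are near-identical by construction and would exit spuriously.
        stalled = (q_prev is not None and rho >= 1.0 and
                   abs(q_t - q_prev) <= controls.dist_change_tol * scale)
        if info["grad_ok"] and (q_t <= controls.dist_tol * scale or stalled):
            converged = True
            break
        q_prev = q_t

    B_hat = constraint.project(B)
    if polish:
        B_hat = _polish_on_support(B_hat, X, Y, epsilon)
    support, per_class = _support_from_B(B_hat, constraint)
    result = FitResult(B=B_hat, support=support, per_class_support=per_class,
                       converged=converged, rho_final=rho, n_outer=t_used,
                       n_inner_total=n_inner, objective_trace=obj_trace,
                       dist_trace=dist_trace)
    result.B_relaxed = B  # pre-projection iterate, used for continuation
    return result


def continuation_ladder(p: int, k: int, num: int = 7) -> list:
    """Decreasing model sizes from near-dense down to the target k.

    Intermediate stops are drawn from a logarithmic grid over [1, p]; each
    stop warm-starts the next, letting mass migrate between correlated
    features gradually instead of committing to a support in one shot.
    """
    grid = np.unique(np.round(np.logspace(0, np.log10(p), num)).astype(int))
    ks = [int(v) for v in grid[::-1] if k < v < p]
    return ks + [int(k)]


def proximal_distance_path(X: np.ndarray, Y: np.ndarray, epsilon: float,
                           ks: Sequence[int], variant: str = "row_sparse",
                           schedule: Optional[AnnealingSchedule] = None,
                           controls: Optional[SolverControls] = None,
                           method: str = "direct",
                           cache: Optional[SVDCache] = None,
                           B_init: Optional[np.ndarray] = None,
                           exclude_intercept: bool = True,
                           polish: bool = False) -> dict:
    """Solve a decreasing sequence of model sizes with warm starts.

    Returns ``{k: FitResult}``.  Each model size continues from the
    previous (pre-projection) iterate, so the whole path costs little more
    than the hardest single fit while being far more reliable than fitting
    small k cold: with strongly correlated designs a one-shot fit tends to
    commit to spurious features, whereas the gradually shrinking support
    lets coefficients reconcentrate on the informative ones.
    """
    ks = sorted(set(int(k) for k in ks), reverse=True)
    if method == "direct" and cache is None:
        cache = build_svd_cache(X)
    results = {}
    B = B_init
    for k in ks:
        cons = Constraint(variant=variant, k=k,
                          exclude_intercept=exclude_intercept)
        res = proximal_distance_fit(X, Y, epsilon, cons, schedule=schedule,
                                    controls=controls, method=method,
                                    cache=cache, B_init=B, polish=polish)
        results[k] = res
        B = res.B_relaxed
    return results
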