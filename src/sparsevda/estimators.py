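"""Scikit-learn style estimators for linear and kernel sparse VDA.

:class:`VDAClassifier` fits a multiclass linear classifier by minimizing the
epsilon-insensitive vertex risk under an exact sparsity (or l1-ball)
constraint, solved by the annealed proximal distance iteration.
:class:`KernelVDAClassifier` replaces the feature design with an RBF kernel
matrix; row sparsity then selects *avatars* -- the training instances that
carry the decision boundary, the analogue of support vectors.

Both estimators follow the sklearn contract (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``predict``/``decision_function``)
and compose with pipelines and model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .encoding import encode_labels, nearest_vertex_index
from .projections import Constraint
from .solvers import (AnnealingSchedule, SolverControls, build_svd_cache,
                      continuation_ladder, fit_unconstrained,
                      proximal_distance_fit, proximal_distance_path)

SPARSE_K_VARIANTS = {"row": "row_sparse", "col": "col_sparse",
                     "global": "global_sparse"}
L1_LAM_VARIANTS = {"l1": "l1", "l1_row": "l1_row", "l1_col": "l1_col"}


def _standardize_fit(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


class _BaseVDA(ClassifierMixin, BaseEstimator):
    """Shared machinery: constraint resolution, solver plumbing, prediction."""

    def _resolve_constraint(self, p: int, c: int):
        if self.constraint is None or (
                self.constraint in SPARSE_K_VARIANTS and self.k is None):
            return None
        if self.constraint in SPARSE_K_VARIANTS:
            variant = SPARSE_K_VARIANTS[self.constraint]
            cons = Constraint(variant=variant, k=self.k,
                              exclude_intercept=self.fit_intercept)
        elif self.constraint in L1_LAM_VARIANTS:
            cons = Constraint(variant=L1_LAM_VARIANTS[self.constraint],
                              lam=self.lam,
                              exclude_intercept=self.fit_intercept)
        else:
            raise ValueError(f"unknown constraint {self.constraint!r}")
        return None if cons.is_vacuous(p, c) else cons

    def _schedule(self):
        return AnnealingSchedule(rho0=self.rho0, multiplier=self.rho_mult,
                                 rho_max=self.rho_max,
                                 max_outer=self.max_outer)

    def _controls(self):
        return SolverControls(grad_tol=self.grad_tol, dist_tol=self.dist_tol,
                              dist_change_tol=self.dist_change_tol,
                              max_inner=self.max_inner, accel=self.accel)

    def _solve(self, design, Y, constraint, design_cache=None, B_init=None):
        cache = design_cache
        if cache is None and self.method == "direct":
            cache = build_svd_cache(design)
        self.design_cache_ = cache
        if constraint is None:
            B = fit_unconstrained(design, Y, self.epsilon, cache=cache,
                                  B_init=B_init,
                                  grad_tol=self.grad_tol)
            self.fit_result_ = None
            self.converged_ = True
            return B
        use_path = (self.continuation and constraint.variant in
                    ("row_sparse", "col_sparse", "global_sparse") and
                    np.ndim(constraint.k) == 0)
        if use_path:
            p_eff = design.shape[1] - (1 if self.fit_intercept else 0)
            limit = p_eff if constraint.variant != "global_sparse" \
                else p_eff * Y.shape[1]
            if B_init is None:
                B_init = fit_unconstrained(design, Y, self.epsilon,
                                           cache=cache,
                                           grad_tol=self.grad_tol)
            ks = continuation_ladder(limit, constraint.k)
            results = proximal_distance_path(
                design, Y, self.epsilon, ks, variant=constraint.variant,
                schedule=self._schedule(), controls=self._controls(),
                method=self.method, cache=cache, B_init=B_init,
                exclude_intercept=constraint.exclude_intercept,
                polish=self.polish)
            result = results[int(constraint.k)]
        else:
            result = proximal_distance_fit(
                design, Y, self.epsilon, constraint,
                schedule=self._schedule(), controls=self._controls(),
                method=self.method, cache=cache, B_init=B_init,
                polish=self.polish)
        self.fit_result_ = result
        self.converged_ = result.converged
        return result.B


class VDAClassifier(_BaseVDA):
    """Linear vertex discriminant analysis with exact sparsity constraints.

    Parameters
    ----------
    constraint : {"row", "col", "global", "l1", "l1_row", "l1_col"} or None
        Constraint family.  ``"row"`` selects at most ``k`` features shared
        by all classes; ``"col"`` selects at most ``k`` features *per class*
        (supports may differ between classes); ``"global"`` bounds the total
        number of nonzero coefficients.  The l1 variants are the convex
        shrinkage analogues with radius ``lam``.  ``None`` (or ``k=None``
        for a sparsity family) fits the dense model.
    k : int or None
        Sparsity budget for the sparsity families.
    lam : float or None
        l1-ball radius for the l1 families.
    epsilon : float, default 0.5
        Insensitivity radius; residuals within an epsilon-ball of the class
        vertex incur no loss.  Kept below sqrt(2)/2, half the inter-vertex
        distance.
    fit_intercept, standardize : bool
        Add an (unconstrained) intercept row; z-score columns using
        training statistics.
    method : {"direct", "steepest"}
        Exact surrogate minimization through a cached thin SVD, or
        factorization-free exact-step gradient descent.
    rho0, rho_mult, rho_max, max_outer
        Geometric annealing schedule of the distance penalty.
    grad_tol, dist_tol, dist_change_tol, max_inner, accel
        Inner-solver controls; ``grad_tol=None`` uses a criterion scaled by
        sqrt((p+1) * c) and by the current penalty strength.
    continuation : bool, default True
        Reach the target model size through a decreasing ladder of
        intermediate sizes with warm starts, which is far more reliable on
        correlated designs than a one-shot fit at k.
    polish : bool, default False
        Refit the selected coordinates at rho = 0 after the final
        projection (removes the truncation bias of plain projection).

    Attributes
    ----------
    classes_ : ndarray of class labels.
    coef_ : ndarray of shape (p, c); column j scores class ``classes_[j]``.
    intercept_ : ndarray of shape (c,).
    support_ : indices of features with a nonzero coefficient row.
    per_class_support_ : list of per-class index arrays (class-specific
        families), else None.
    """

    def __init__(self, constraint="row", k=None, lam=None, epsilon=0.5,
                 fit_intercept=True, standardize=True, method="direct",
                 rho0=1e-4, rho_mult=3.0, rho_max=1e6, max_outer=40,
                 grad_tol=None, dist_tol=1e-3, dist_change_tol=1e-6,
                 max_inner=1000, accel=True, polish=False,
                 continuation=True):
        self.constraint = constraint
        self.k = k
        self.lam = lam
        self.epsilon = epsilon
        self.fit_intercept = fit_intercept
        self.standardize = standardize
        self.method = method
        self.rho0 = rho0
        self.rho_mult = rho_mult
        self.rho_max = rho_max
        self.max_outer = max_outer
        self.grad_tol = grad_tol
        self.dist_tol = dist_tol
        self.dist_change_tol = dist_change_tol
        self.max_inner = max_inner
        self.accel = accel
        self.polish = polish
        self.continuation = continuation

    def fit(self, X, y, design_cache=None, B_init=None):
        """Fit on features X and labels y.

        ``design_cache`` (a precomputed :class:`SVDCache` of this exact
        training design) and ``B_init`` (warm start) are pass-throughs used
        by the cross-validation driver; ordinary callers omit them.
        """
        X, y = check_X_y(X, y, dtype=float)
        self.encoding_ = encode_labels(y)
        self.classes_ = self.encoding_.class_order
        Y = self.encoding_.Y
        n, p = X.shape
        c = self.encoding_.c

        if self.standardize:
            self.mean_, self.scale_ = _standardize_fit(X)
            Xs = (X - self.mean_) / self.scale_
        else:
            self.mean_ = np.zeros(p)
            self.scale_ = np.ones(p)
            Xs = X
        design = np.column_stack([np.ones(n), Xs]) if self.fit_intercept \
            else Xs

        constraint = self._resolve_constraint(p, c)
        B = self._solve(design, Y, constraint, design_cache=design_cache,
                        B_init=B_init)

        if self.fit_intercept:
            self.intercept_ = B[0].copy()
            self.coef_ = B[1:].copy()
        else:
            self.intercept_ = np.zeros(c)
            self.coef_ = B.copy()
        row_norms = np.linalg.norm(self.coef_, axis=1)
        self.support_ = np.flatnonzero(row_norms > 0)
        self.per_class_support_ = (
            self.fit_result_.per_class_support
            if self.fit_result_ is not None else None)
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        """Vertex-space predictions, one row per sample, one column per class."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        Xs = (X - self.mean_) / self.scale_
        return Xs @ self.coef_ + self.intercept_

    def predict(self, X):
        V = self.decision_function(X)
        return self.classes_[nearest_vertex_index(V)]


def median_heuristic_gamma(X, max_samples=500, seed=0) -> float:
    """1 / median pairwise squared distance -- the usual RBF scale anchor."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] > max_samples:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], max_samples, replace=False)]
    d2 = euclidean_distances(X, squared=True)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0


class KernelVDAClassifier(_BaseVDA):
    """Nonlinear VDA through a Gaussian (RBF) kernel with avatar selection.

    The design matrix is the kernel matrix W with W_ij = exp(-gamma
    ||x_i - x_j||^2); the model stays linear in its coefficients, so all the
    linear solver machinery carries over.  A row-sparsity constraint of
    budget ``k`` keeps at most k training instances (avatars) with nonzero
    coefficient rows; ``constraint="col"`` lets each class keep its own
    avatar set.  Prediction only ever touches the avatar rows.
    """

    def __init__(self, constraint="row", k=None, gamma="median", epsilon=0.5,
                 fit_intercept=True, standardize=True, method="direct",
                 rho0=1e-4, rho_mult=3.0, rho_max=1e6, max_outer=40,
                 grad_tol=None, dist_tol=1e-3, dist_change_tol=1e-6,
                 max_inner=1000, accel=True, polish=False,
                 continuation=True):
        self.constraint = constraint
        self.k = k
        self.gamma = gamma
        self.epsilon = epsilon
        self.fit_intercept = fit_intercept
        self.standardize = standardize
        self.method = method
        self.rho0 = rho0
        self.rho_mult = rho_mult
        self.rho_max = rho_max
        self.max_outer = max_outer
        self.grad_tol = grad_tol
        self.dist_tol = dist_tol
        self.dist_change_tol = dist_change_tol
        self.max_inner = max_inner
        self.accel = accel
        self.polish = polish
        self.continuation = continuation
        self.lam = None  # kernel VDA uses the sparsity families only

    def _resolve_gamma(self, Xs):
        if self.gamma == "median":
            return median_heuristic_gamma(Xs)
        return float(self.gamma)

    def fit(self, X, y, design_cache=None, B_init=None):
        from .kernel import rbf_kernel

        X, y = check_X_y(X, y, dtype=float)
        n, p = X.shape
        if self.k is not None and self.k > n:
            raise ValueError(f"k={self.k} exceeds the number of training "
                             f"instances n={n}")
        self.encoding_ = encode_labels(y)
        self.classes_ = self.encoding_.class_order
        Y = self.encoding_.Y
        c = self.encoding_.c

        if self.standardize:
            self.mean_, self.scale_ = _standardize_fit(X)
        else:
            self.mean_, self.scale_ = np.zeros(p), np.ones(p)
        Xs = (X - self.mean_) / self.scale_
        self.X_train_ = Xs
        self.gamma_ = self._resolve_gamma(Xs)
        W = rbf_kernel(Xs, Xs, self.gamma_)
        design = np.column_stack([np.ones(n), W]) if self.fit_intercept else W

        constraint = self._resolve_constraint(n, c)
        B = self._solve(design, Y, constraint, design_cache=design_cache,
                        B_init=B_init)

        if self.fit_intercept:
            self.intercept_ = B[0].copy()
            self.dual_coef_ = B[1:].copy()
        else:
            self.intercept_ = np.zeros(c)
            self.dual_coef_ = B.copy()
        self.avatars_ = np.flatnonzero(
            np.linalg.norm(self.dual_coef_, axis=1) > 0)
        self.per_class_avatars_ = (
            self.fit_result_.per_class_support
            if self.fit_result_ is not None else None)
        self.n_features_in_ = p
        return self

    def decision_function(self, X):
        from .kernel import rbf_kernel

        check_is_fitted(self, "dual_coef_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        Xs = (X - self.mean_) / self.scale_
        if X.shape[0] == 0:
            return np.zeros((0, len(self.classes_)))
        idx = self.avatars_
        W = rbf_kernel(Xs, self.X_train_[idx], self.gamma_)
        return W @ self.dual_coef_[idx] + self.intercept_

    def predict(self, X):
        V = self.decision_function(X)
        return self.classes_[nearest_vertex_index(V)]
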