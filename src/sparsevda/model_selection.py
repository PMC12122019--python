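"""Nested cross-validation for sparse VDA and stability reporting.

The pipeline holds out a test set, then on the remaining samples runs
K-fold cross validation in two stages over the *same* folds: first the
insensitivity radius epsilon (and the kernel scale gamma in the nonlinear
case; gamma is fixed at 0 for linear models) is tuned with the dense,
unconstrained model; then, with (epsilon, gamma) frozen, the model size k
is tuned for the chosen constraint family.  Ties in mean validation
accuracy always resolve to the smaller epsilon / gamma / k (the more
parsimonious model).  The final model is refit on the full training set at
the chosen hyperparameters and scored once on the held-out test set.

Repeated cross validation re-runs the whole pipeline under distinct seeds
and aggregates which features (per class, for class-specific constraints)
are selected how often, together with quantiles of the selected model size
-- the stability evidence that should accompany any greedy variable
selection procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .encoding import encode_labels, nearest_vertex_index
from .estimators import KernelVDAClassifier, VDAClassifier, _standardize_fit
from .kernel import rbf_kernel
from .projections import Constraint
from .solvers import (AnnealingSchedule, SolverControls, build_svd_cache,
                      fit_unconstrained, proximal_distance_path)

SPARSE_FAMILIES = {"row": "row_sparse", "col": "col_sparse",
                   "global": "global_sparse"}


def k_grid_log(p: int, num: int = 6, upper_frac: float = 0.5) -> np.ndarray:
    """Log-spaced model sizes covering a fraction of [1, p].

    By default the grid spans [1, p/2]: candidate models are genuinely
    sparse, and the dense model (which in the p > n regime interpolates and
    can dominate validation accuracy without generalizing) is deliberately
    not a candidate.
    """
    upper = max(1, int(round(p * upper_frac)))
    grid = np.unique(np.round(np.logspace(0, np.log10(upper),
                                          num)).astype(int))
    return grid[(grid >= 1) & (grid <= p)]


@dataclass
class CVConfig:
    """Grids, fold counts and seeding for the nested CV pipeline."""

    n_folds: int = 3
    eps_grid: Sequence[float] = tuple(np.logspace(np.log10(0.05),
                                                  np.log10(0.70), 7))
    gamma_grid: Sequence[float] = (0.0,)
    k_grid: Optional[Sequence[int]] = None
    test_fraction: float = 0.25
    n_repeats: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if len(self.eps_grid) == 0 or len(self.gamma_grid) == 0:
            raise ValueError("hyperparameter grids must be nonempty")


@dataclass
class CVResult:
    chosen_eps: float
    chosen_gamma: float
    chosen_k: int
    fold_scores: dict
    test_error_pct: float
    final_model: object
    support: np.ndarray
    per_class_support: Optional[list]
    seed: int
    train_idx: Optional[np.ndarray] = None
    test_idx: Optional[np.ndarray] = None


@dataclass
class StabilityReport:
    """Selection frequencies and model-size spread across CV replicates."""

    feature_counts: np.ndarray
    per_class_counts: Optional[np.ndarray]
    model_sizes: List[int]
    size_quantiles: np.ndarray  # empirical 10/50/90% (linear interpolation)
    coef_sums: np.ndarray      # signed coefficient totals across replicates
    replicates: List[dict] = field(default_factory=list)
    n_repeats: int = 0

    def top_features(self, n_top: int = 50):
        """(indices, counts) of the most frequently selected features."""
        order = np.argsort(-self.feature_counts, kind="stable")[:n_top]
        return order, self.feature_counts[order]


# --------------------------------------------------------------------------
# Splitting

def split_train_test(n: int, test_fraction: float, seed: int,
                     stratified: bool = True, labels=None):
    """Disjoint, exhaustive, seeded train/test index sets."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    idx = np.arange(n)
    strat = labels if (stratified and labels is not None) else None
    if strat is not None:
        classes, counts = np.unique(strat, return_counts=True)
        lacking = classes[counts < 2]
        if lacking.size:
            raise ValueError(f"class {lacking[0]!r} has fewer than 2 "
                             "members; cannot stratify the split")
    train, test = train_test_split(idx, test_size=test_fraction,
                                   random_state=seed, stratify=strat)
    return np.sort(train), np.sort(test)


def _make_folds(y, n_folds: int, seed: int, stratified: bool):
    if stratified:
        classes, counts = np.unique(y, return_counts=True)
        lacking = classes[counts < n_folds]
        if lacking.size:
            raise ValueError(
                f"class {lacking[0]!r} has fewer than {n_folds} members; "
                "cannot stratify")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(y)), y))


# --------------------------------------------------------------------------
# Fold preparation (design + SVD computed once per fold, shared by both
# tuning stages)

class _Fold:
    def __init__(self, X, y, tr_idx, val_idx, enc, kernel: bool,
                 fit_intercept: bool = True, standardize: bool = True):
        self.tr_idx, self.val_idx = tr_idx, val_idx
        X_tr, X_val = X[tr_idx], X[val_idx]
        if standardize:
            mean, scale = _standardize_fit(X_tr)
        else:
            mean, scale = np.zeros(X.shape[1]), np.ones(X.shape[1])
        self.Xtr_s = (X_tr - mean) / scale
        self.Xval_s = (X_val - mean) / scale
        self.Y_tr = enc.transform(y[tr_idx])
        self.y_val = y[val_idx]
        self.enc = enc
        self.kernel = kernel
        self.fit_intercept = fit_intercept
        self._designs = {}   # keyed by gamma (0.0 for linear)

    def design(self, gamma: float):
        """(train design, SVD cache, validation design) for this fold."""
        if gamma not in self._designs:
            if self.kernel and gamma > 0:
                D_tr = rbf_kernel(self.Xtr_s, self.Xtr_s, gamma)
                D_val = rbf_kernel(self.Xval_s, self.Xtr_s, gamma)
            else:
                D_tr, D_val = self.Xtr_s, self.Xval_s
            if self.fit_intercept:
                D_tr = np.column_stack([np.ones(len(D_tr)), D_tr])
                D_val = np.column_stack([np.ones(len(D_val)), D_val])
            self._designs[gamma] = (D_tr, build_svd_cache(D_tr), D_val)
        return self._designs[gamma]


def _accuracy(B, D_val, y_val, enc):
    pred = enc.class_order[nearest_vertex_index(D_val @ B)]
    return float(np.mean(pred == y_val))


def _prepare_folds(X, y, cfg: CVConfig, kernel: bool):
    enc = encode_labels(y)
    folds = [_Fold(X, y, tr, val, enc, kernel)
             for tr, val in _make_folds(y, cfg.n_folds, cfg.seed,
                                        cfg.stratified)]
    return enc, folds


# --------------------------------------------------------------------------
# Stage 1: (epsilon, gamma)

def _tune_eps_gamma_on(folds, cfg: CVConfig):
    best = (-np.inf, None, None)
    scores = {}
    for eps in sorted(cfg.eps_grid):
        for gamma in sorted(cfg.gamma_grid):
            accs = []
            for fold in folds:
                D_tr, cache, D_val = fold.design(gamma)
                B = fit_unconstrained(D_tr, fold.Y_tr, eps, cache=cache)
                accs.append(_accuracy(B, D_val, fold.y_val, fold.enc))
            mean_acc = float(np.mean(accs))
            scores[(eps, gamma)] = mean_acc
            if mean_acc > best[0] + 1e-12:  # strict: ties keep smaller values
                best = (mean_acc, eps, gamma)
    return best[1], best[2], scores


def tune_eps_gamma(X, y, cfg: CVConfig, kernel: bool = False):
    """K-fold grid search for (epsilon, gamma) with the dense model."""
    _, folds = _prepare_folds(np.asarray(X, float), np.asarray(y), cfg, kernel)
    eps, gamma, _ = _tune_eps_gamma_on(folds, cfg)
    return eps, gamma


# --------------------------------------------------------------------------
# Stage 2: model size k

def _tune_k_on(folds, cfg: CVConfig, eps: float, gamma: float,
               family: str, schedule, controls, polish: bool):
    """Validation accuracy per model size, evaluated largest-to-smallest.

    Within each fold the grid is solved as one continuation path: each k
    warm-starts the next smaller one, which both saves work and avoids the
    spurious supports that one-shot fits at small k commit to on
    correlated designs.
    """
    variant = SPARSE_FAMILIES[family]
    k_grid = sorted(cfg.k_grid)
    per_fold_scores = []
    for fold in folds:
        D_tr, cache, D_val = fold.design(gamma)
        p_eff = D_tr.shape[1] - 1
        limit = p_eff if variant != "global_sparse" else p_eff * fold.enc.c
        B0 = fit_unconstrained(D_tr, fold.Y_tr, eps, cache=cache)
        active = [k for k in k_grid if k < limit]
        results = proximal_distance_path(D_tr, fold.Y_tr, eps, active,
                                         variant=variant,
                                         schedule=schedule,
                                         controls=controls, cache=cache,
                                         B_init=B0, polish=polish)
        scores = {}
        for k in k_grid:
            B = results[k].B if k in results else B0
            scores[k] = _accuracy(B, D_val, fold.y_val, fold.enc)
        per_fold_scores.append(scores)
    k_scores = {k: float(np.mean([s[k] for s in per_fold_scores]))
                for k in k_grid}
    best = max(k_scores.values())
    chosen = min(k for k, v in k_scores.items() if v >= best - 1e-12)
    return chosen, k_scores


def tune_k(X, y, cfg: CVConfig, eps: float, gamma: float,
           family: str = "row", schedule: Optional[AnnealingSchedule] = None,
           controls: Optional[SolverControls] = None, kernel: bool = False,
           polish: bool = False):
    """K-fold grid search for k at fixed (epsilon, gamma), same folds.

    Returns the smallest k attaining the maximal mean validation accuracy.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    cfg = _with_default_k_grid(cfg, X, kernel)
    _, folds = _prepare_folds(X, y, cfg, kernel)
    schedule = schedule or AnnealingSchedule()
    controls = controls or SolverControls()
    chosen, _ = _tune_k_on(folds, cfg, eps, gamma, family, schedule,
                           controls, polish)
    return chosen


def _with_default_k_grid(cfg: CVConfig, X, kernel: bool) -> CVConfig:
    if cfg.k_grid is not None:
        return cfg
    limit = X.shape[0] if kernel else X.shape[1]
    from dataclasses import replace
    return replace(cfg, k_grid=k_grid_log(limit))


# --------------------------------------------------------------------------
# Full pipeline

def nested_cv(X, y, cfg: CVConfig, family: str = "row",
              schedule: Optional[AnnealingSchedule] = None,
              controls: Optional[SolverControls] = None,
              kernel: bool = False, polish: bool = False,
              X_test=None, y_test=None) -> CVResult:
    """Split -> tune (epsilon, gamma) -> tune k -> refit -> one test score.

    When ``X_test``/``y_test`` are given they serve as the held-out test
    set and all of ``X`` is used for tuning; otherwise a stratified split
    of ``test_fraction`` is made first.  Test samples never enter any fold.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    schedule = schedule or AnnealingSchedule()
    controls = controls or SolverControls()

    if X_test is None:
        train_idx, test_idx = split_train_test(
            len(y), cfg.test_fraction, cfg.seed, cfg.stratified, labels=y)
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
    else:
        train_idx = np.arange(len(y))
        test_idx = None
        X_tr, y_tr = X, y
        X_te, y_te = np.asarray(X_test, float), np.asarray(y_test)

    cfg = _with_default_k_grid(cfg, X_tr, kernel)
    _, folds = _prepare_folds(X_tr, y_tr, cfg, kernel)
    eps, gamma, eps_scores = _tune_eps_gamma_on(folds, cfg)
    chosen_k, k_scores = _tune_k_on(folds, cfg, eps, gamma, family,
                                    schedule, controls, polish)

    solver_kwargs = dict(
        epsilon=eps, rho0=schedule.rho0, rho_mult=schedule.multiplier,
        rho_max=schedule.rho_max, max_outer=schedule.max_outer,
        grad_tol=controls.grad_tol, dist_tol=controls.dist_tol,
        dist_change_tol=controls.dist_change_tol,
        max_inner=controls.max_inner, accel=controls.accel, polish=polish)
    if kernel:
        model = KernelVDAClassifier(constraint=family, k=chosen_k,
                                    gamma=gamma, **solver_kwargs)
    else:
        model = VDAClassifier(constraint=family, k=chosen_k, **solver_kwargs)
    model.fit(X_tr, y_tr)
    test_error = 100.0 * (1.0 - float(np.mean(model.predict(X_te) == y_te)))

    support = (model.avatars_ if kernel else model.support_)
    per_class = (model.per_class_avatars_ if kernel
                 else model.per_class_support_)
    return CVResult(chosen_eps=eps, chosen_gamma=gamma, chosen_k=chosen_k,
                    fold_scores={"eps_gamma": eps_scores, "k": k_scores},
                    test_error_pct=test_error, final_model=model,
                    support=support, per_class_support=per_class,
                    seed=cfg.seed, train_idx=train_idx, test_idx=test_idx)


def repeated_cv(X, y, cfg: CVConfig, family: str = "row",
                schedule: Optional[AnnealingSchedule] = None,
                controls: Optional[SolverControls] = None,
                kernel: bool = False, polish: bool = False,
                X_test=None, y_test=None) -> StabilityReport:
    """Re-run nested CV under distinct seeds and aggregate selections."""
    from dataclasses import replace

    X = np.asarray(X, float)
    p = X.shape[0] if kernel else X.shape[1]
    c = len(np.unique(y))
    feature_counts = np.zeros(p)
    per_class_counts = np.zeros((p, c)) if family in ("col", "global") \
        else None
    coef_sums = np.zeros((p, c))
    sizes, rows = [], []
    for r in range(cfg.n_repeats):
        sub = replace(cfg, seed=cfg.seed + r)
        res = nested_cv(X, y, sub, family=family, schedule=schedule,
                        controls=controls, kernel=kernel, polish=polish,
                        X_test=X_test, y_test=y_test)
        feature_counts[res.support] += 1
        if per_class_counts is not None and res.per_class_support is not None:
            for j, idx in enumerate(res.per_class_support):
                per_class_counts[idx, j] += 1
        model = res.final_model
        coefs = model.dual_coef_ if kernel else model.coef_
        if not kernel:  # kernel coefficient rows live on fold-dependent rows
            coef_sums += coefs
        sizes.append(len(res.support))
        rows.append({"seed": sub.seed, "eps": res.chosen_eps,
                     "gamma": res.chosen_gamma, "k": res.chosen_k,
                     "test_error_pct": res.test_error_pct,
                     "support_size": len(res.support)})
    quantiles = np.quantile(sizes, [0.1, 0.5, 0.9])
    return StabilityReport(feature_counts=feature_counts,
                           per_class_counts=per_class_counts,
                           model_sizes=sizes, size_quantiles=quantiles,
                           coef_sums=coef_sums, replicates=rows,
                           n_repeats=cfg.n_repeats)
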