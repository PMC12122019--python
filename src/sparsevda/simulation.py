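"""Synthetic classification data with known sparse ground truth.

The generator emulates a standard support-recovery benchmark for sparse
multiclass classifiers:

1. draw n rows of predictors x ~ N(0, Sigma) with Toeplitz covariance
   Sigma_ij = corr^|i-j| (an AR(1) dependence between adjacent features);
2. draw a ground-truth slope matrix B* in {-1, 0, 1}^{p x c} whose nonzero
   pattern has exactly k_star informative rows -- shared by all classes
   (*homogeneous* regime) or split into disjoint per-class subsets of size
   k_star / c (*heterogeneous* regime);
3. assign each sample the class whose simplex vertex is nearest to B*^T x;
4. draw i.i.d. Gaussian noise E with variance sigma^2 calibrated so that
   the average label-column variance over sigma^2 equals the requested
   signal-to-noise ratio;
5. solve for a sparse shift matrix S, supported on the informative columns,
   such that (X + S) B* + E = Y exactly.  The shift aligns the linear
   predictions with the assigned labels, making B* a genuine (noisy) data
   generating model rather than just a labeling device.

An independent test set is generated by the same mechanism with fresh
randomness.  The module also provides support-recovery metrics (TPR / PPV)
and small 2-D nonlinear toys (concentric circles with a known 20% Bayes
error, Gaussian clouds, spirals) for exercising the kernel classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np

from .encoding import nearest_vertex_index


@dataclass
class SimulationScenario:
    """Generator parameters for one benchmark condition."""

    n: int = 500
    p: int = 1000
    c: int = 3
    k_star: int = 30
    toeplitz_corr: float = 0.1
    snr: float = 1.0
    regime: str = "homogeneous"
    n_test: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.toeplitz_corr < 1:
            raise ValueError("toeplitz_corr must lie in [0, 1)")
        if self.k_star > self.p:
            raise ValueError("k_star cannot exceed p")
        if self.regime not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "heterogeneous" and self.k_star % self.c:
            raise ValueError("heterogeneous regime needs c to divide k_star")


@dataclass
class SimulationTruth:
    """Ground truth attached to a generated training set."""

    B_star: np.ndarray
    support: np.ndarray
    per_class_support: Optional[list]
    sigma2: float
    shift: np.ndarray = field(repr=False)
    noise: np.ndarray = field(repr=False)


@dataclass
class SimulationData:
    """Train/test split plus the generating truth."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    truth: SimulationTruth


def toeplitz_gaussian_design(n: int, p: int, corr: float,
                             rng) -> np.ndarray:
    """n i.i.d. rows from N(0, Sigma), Sigma_ij = corr^|i-j|.

    Uses the AR(1) recursion x_j = corr x_{j-1} + sqrt(1 - corr^2) z_j,
    whose stationary covariance is exactly the Toeplitz matrix, in O(np).
    """
    if not 0 <= corr < 1:
        raise ValueError("corr must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    Z = rng.standard_normal((n, p))
    if corr == 0:
        return Z
    X = np.empty((n, p))
    X[:, 0] = Z[:, 0]
    scale = np.sqrt(1.0 - corr**2)
    for j in range(1, p):
        X[:, j] = corr * X[:, j - 1] + scale * Z[:, j]
    return X


def sample_true_slopes(p: int, c: int, k_star: int, regime: str, rng):
    """Draw B* and its support(s); resampled until B*_J has full column rank.

    Homogeneous: k_star rows drawn uniformly, entries of chosen rows i.i.d.
    uniform on {-1, +1} so every informative feature is active in every
    class.  Heterogeneous: disjoint per-class supports of size k_star / c,
    entries on each class's own support from {-1, +1} and zero elsewhere
    (full column rank is then automatic).
    """
    rng = np.random.default_rng(rng)
    per_class = None
    for _ in range(100):
        B = np.zeros((p, c))
        if regime == "homogeneous":
            support = np.sort(rng.choice(p, size=k_star, replace=False))
            B[support] = rng.choice([-1.0, 1.0], size=(k_star, c))
        else:
            support = np.sort(rng.choice(p, size=k_star, replace=False))
            shuffled = rng.permutation(support)
            size = k_star // c
            per_class = [np.sort(shuffled[j * size:(j + 1) * size])
                         for j in range(c)]
            for j, idx in enumerate(per_class):
                B[idx, j] = rng.choice([-1.0, 1.0], size=size)
        if np.linalg.matrix_rank(B[support]) == c:
            return B, support, per_class
    raise RuntimeError("could not draw a full-column-rank slope matrix")


def assign_labels(X: np.ndarray, B_star: np.ndarray) -> np.ndarray:
    """Class indices by the nearest-vertex rule applied to B*^T x."""
    if not np.any(B_star):
        raise ValueError("B_star is identically zero; labels would be "
                         "degenerate ties")
    return nearest_vertex_index(X @ B_star)


def noise_sigma_from_snr(Y: np.ndarray, snr: float) -> float:
    """sigma^2 = mean over classes of Var(Y column) / SNR (empirical)."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    var = np.var(Y, axis=0).mean()
    if var == 0:
        warnings.warn("degenerate labels (single class): sigma^2 = 0")
    return float(var / snr)


def apply_shift(X: np.ndarray, B_star: np.ndarray, Y: np.ndarray,
                E: np.ndarray, support: np.ndarray):
    """Minimum-norm sparse shift S with (X + S) B* + E = Y exactly.

    S is zero outside the support columns; on them, S_J = M B_J^+ with
    M = Y - X B* - E and B_J^+ the Moore-Penrose right inverse of the
    restricted slope block (full column rank required).
    """
    B_J = B_star[support]
    if np.linalg.matrix_rank(B_J) < B_star.shape[1]:
        raise ValueError("B_star restricted to its support is rank "
                         "deficient; resample B_star")
    M = Y - X @ B_star - E
    S_J = M @ np.linalg.pinv(B_J)
    shift = np.zeros_like(X)
    shift[:, support] = S_J
    return X + shift, shift


def _generate_split(n, scenario, B_star, support, rng):
    X = toeplitz_gaussian_design(n, scenario.p, scenario.toeplitz_corr, rng)
    labels = assign_labels(X, B_star)
    Y = np.zeros((n, scenario.c))
    Y[np.arange(n), labels] = 1.0
    sigma2 = noise_sigma_from_snr(Y, scenario.snr)
    E = rng.standard_normal((n, scenario.c)) * np.sqrt(sigma2)
    X_shifted, shift = apply_shift(X, B_star, Y, E, support)
    return X_shifted, labels, sigma2, shift, E


def simulate_classification(scenario: SimulationScenario) -> SimulationData:
    """Full pipeline producing a training set, a fresh test set, and truth."""
    rng = np.random.default_rng(scenario.seed)
    B_star, support, per_class = sample_true_slopes(
        scenario.p, scenario.c, scenario.k_star, scenario.regime, rng)
    X_tr, y_tr, sigma2, shift, E = _generate_split(
        scenario.n, scenario, B_star, support, rng)
    X_te, y_te, _, _, _ = _generate_split(
        scenario.n_test, scenario, B_star, support, rng)
    truth = SimulationTruth(B_star=B_star, support=support,
                            per_class_support=per_class, sigma2=sigma2,
                            shift=shift, noise=E)
    return SimulationData(X_train=X_tr, y_train=y_tr, X_test=X_te,
                          y_test=y_te, truth=truth)


# --------------------------------------------------------------------------
# Support-recovery metrics

def support_metrics(estimated, truth) -> tuple:
    """(TPR, PPV) of an estimated support against the true one.

    Empty estimated support gives PPV 1 when the truth is also empty and 0
    otherwise.  Inputs are index collections.
    """
    est = set(np.asarray(estimated).tolist())
    true = set(np.asarray(truth).tolist())
    hits = len(est & true)
    tpr = hits / len(true) if true else 1.0
    if not est:
        ppv = 1.0 if not true else 0.0
    else:
        ppv = hits / len(est)
    return tpr, ppv


def per_class_support_metrics(estimated: list, truth: list) -> tuple:
    """Class-wise TPR/PPV averaged over classes."""
    pairs = [support_metrics(e, t) for e, t in zip(estimated, truth)]
    tprs, ppvs = zip(*pairs)
    return float(np.mean(tprs)), float(np.mean(ppvs))


# --------------------------------------------------------------------------
# 2-D nonlinear toys

def toy_nonlinear(name: str, n: int, seed: int = 0, noise: float = 0.1,
                  flip: float = 0.20, n_classes: int = 3):
    """2-D datasets with nonlinear class boundaries.

    ``circles``: two concentric rings (radii 1 and 2, radial jitter
    ``noise``) with labels flipped independently with probability ``flip``;
    the Bayes error of the generating rule is exactly ``flip``.
    ``clouds``: ``n_classes`` unit-variance Gaussian blobs centered on a
    circle of radius 3.  ``spirals`` / ``spirals-hard``: Archimedean arms
    with angular noise (the hard variant doubles it).
    """
    rng = np.random.default_rng(seed)
    if name == "circles":
        labels = rng.integers(0, 2, size=n)
        radius = np.where(labels == 0, 1.0, 2.0) + noise * rng.standard_normal(n)
        theta = rng.uniform(0, 2 * np.pi, size=n)
        X = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        flips = rng.random(n) < flip
        y = np.where(flips, 1 - labels, labels)
        return X, y
    if name == "clouds":
        labels = rng.integers(0, n_classes, size=n)
        angles = 2 * np.pi * labels / n_classes
        centers = 3.0 * np.column_stack([np.cos(angles), np.sin(angles)])
        X = centers + rng.standard_normal((n, 2))
        return X, labels
    if name in ("spirals", "spirals-hard"):
        ang_noise = 0.2 if name == "spirals" else 0.4
        labels = rng.integers(0, n_classes, size=n)
        t = rng.uniform(0.5, 3.0, size=n)
        theta = (2 * np.pi * labels / n_classes + 1.5 * t
                 + ang_noise * rng.standard_normal(n))
        X = np.column_stack([t * np.cos(theta), t * np.sin(theta)])
        return X, labels
    raise ValueError(f"unknown toy dataset {name!r}")
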