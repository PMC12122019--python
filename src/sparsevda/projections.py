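"""Projections onto sparsity sets and l1 balls, and distances to them.

Six constraint sets are supported for a slope matrix B in R^{p x c}:

* ``row_sparse``    -- at most k nonzero rows (shared support across classes);
* ``col_sparse``    -- at most k nonzero entries per column (class-specific
  supports; k may also be a per-column vector);
* ``global_sparse`` -- at most k nonzero entries overall;
* ``l1``, ``l1_row``, ``l1_col`` -- the convex analogues: l1 balls of radius
  lam on the flattened matrix, each row, or each column.

Projections onto the nonconvex sparsity sets can be set-valued when norms
tie at the selection boundary; every operator here breaks ties toward the
lowest index (column-major position for the global variant) so results are
reproducible.  When a model carries an intercept its row is exempt from the
constraint: :meth:`Constraint.project` copies the intercept row through
unchanged and :meth:`Constraint.distance` ignores it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SPARSE_VARIANTS = ("row_sparse", "col_sparse", "global_sparse")
L1_VARIANTS = ("l1", "l1_row", "l1_col")


def _top_indices(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values, ties broken by lower index."""
    # stable sort on the negated values keeps tied entries in index order
    return np.argsort(-values, kind="stable")[:k]


def project_row_sparse(B: np.ndarray, k: int) -> np.ndarray:
    """Keep the k rows of largest Euclidean norm, zero the rest."""
    B = np.asarray(B, dtype=float)
    p = B.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range [1, {p}]")
    if k == p:
        return B.copy()
    keep = _top_indices(np.linalg.norm(B, axis=1), k)
    out = np.zeros_like(B)
    out[keep] = B[keep]
    return out


def project_col_sparse(B: np.ndarray, k) -> np.ndarray:
    """Keep the k largest-magnitude entries of each column independently.

    ``k`` may be a scalar or a length-c vector of per-column budgets.
    """
    B = np.asarray(B, dtype=float)
    p, c = B.shape
    ks = np.broadcast_to(np.asarray(k, dtype=int), (c,))
    if np.any(ks < 1) or np.any(ks > p):
        raise ValueError(f"k={k} out of range [1, {p}]")
    out = np.zeros_like(B)
    for j in range(c):
        keep = _top_indices(np.abs(B[:, j]), ks[j])
        out[keep, j] = B[keep, j]
    return out


def project_global_sparse(B: np.ndarray, k: int) -> np.ndarray:
    """Keep the k largest-magnitude entries of the whole matrix."""
    B = np.asarray(B, dtype=float)
    total = B.size
    if not 1 <= k <= total:
        raise ValueError(f"k={k} out of range [1, {total}]")
    flat = B.flatten(order="F")  # ties broken by column-major position
    keep = _top_indices(np.abs(flat), k)
    out = np.zeros_like(flat)
    out[keep] = flat[keep]
    return out.reshape(B.shape, order="F")


def _project_l1_vector(v: np.ndarray, lam: float) -> np.ndarray:
    """Euclidean projection of a vector onto the l1 ball of radius lam.

    Soft thresholding at the data-dependent level theta solving
    sum(max(|v_i| - theta, 0)) = lam (Duchi et al.'s sort-based rule).
    """
    a = np.abs(v)
    if a.sum() <= lam:
        return v.copy()
    u = np.sort(a)[::-1]
    css = np.cumsum(u)
    j = np.arange(1, len(u) + 1)
    rho = np.max(j[u * j > css - lam])
    theta = (css[rho - 1] - lam) / rho
    return np.sign(v) * np.maximum(a - theta, 0.0)


def project_l1(B: np.ndarray, lam: float, variant: str = "l1") -> np.ndarray:
    """Project onto an l1 ball globally, per row, or per column."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        return _project_l1_vector(B, lam)
    if variant == "l1":
        return _project_l1_vector(B.ravel(), lam).reshape(B.shape)
    if variant == "l1_row":
        return np.vstack([_project_l1_vector(row, lam) for row in B])
    if variant == "l1_col":
        return np.column_stack([_project_l1_vector(col, lam) for col in B.T])
    raise ValueError(f"unknown l1 variant {variant!r}")


@dataclass(frozen=True)
class Constraint:
    """A tagged constraint set with its projection and distance.

    Parameters
    ----------
    variant : str
        One of ``row_sparse``, ``col_sparse``, ``global_sparse``, ``l1``,
        ``l1_row``, ``l1_col``.
    k : int or sequence, optional
        Sparsity budget (sparsity variants only; per-column vector allowed
        for ``col_sparse``).
    lam : float, optional
        l1 radius (l1 variants only).
    exclude_intercept : bool
        When True, row 0 of the matrices handed to :meth:`project` /
        :meth:`distance` is an intercept: it passes through projection
        unchanged and contributes nothing to the distance.
    """

    variant: str
    k: object = None
    lam: float = None
    exclude_intercept: bool = False

    def __post_init__(self):
        if self.variant in SPARSE_VARIANTS:
            if self.k is None:
                raise ValueError(f"{self.variant} requires k")
        elif self.variant in L1_VARIANTS:
            if self.lam is None or self.lam <= 0:
                raise ValueError(f"{self.variant} requires lam > 0")
        else:
            raise ValueError(f"unknown constraint variant {self.variant!r}")

    def _project_slopes(self, B: np.ndarray) -> np.ndarray:
        if self.variant == "row_sparse":
            return project_row_sparse(B, self.k)
        if self.variant == "col_sparse":
            return project_col_sparse(B, self.k)
        if self.variant == "global_sparse":
            return project_global_sparse(B, self.k)
        return project_l1(B, self.lam, self.variant)

    def project(self, B: np.ndarray) -> np.ndarray:
        """Nearest feasible matrix; intercept row (if any) copied verbatim."""
        B = np.asarray(B, dtype=float)
        if self.exclude_intercept:
            out = B.copy()
            out[1:] = self._project_slopes(B[1:])
            return out
        return self._project_slopes(B)

    def distance(self, B: np.ndarray) -> float:
        """Frobenius distance from B to the set (intercept excluded)."""
        return float(np.linalg.norm(B - self.project(B)))

    def is_feasible(self, B: np.ndarray, tol: float = 0.0) -> bool:
        return self.distance(B) <= tol

    def is_vacuous(self, p: int, c: int) -> bool:
        """True when every p x c slope matrix is feasible."""
        if self.variant == "row_sparse":
            return self.k >= p
        if self.variant == "col_sparse":
            return np.all(np.asarray(self.k) >= p)
        if self.variant == "global_sparse":
            return self.k >= p * c
        return False


def distance_to_set(B: np.ndarray, constraint: Constraint) -> float:
    """Frobenius distance from B to the constraint set.

    For row sparsity this equals the square root of the summed squared
    norms of the dropped rows; zero iff B is feasible.
    """
    return constraint.distance(np.asarray(B, dtype=float))
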