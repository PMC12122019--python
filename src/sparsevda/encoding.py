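"""Vertex encoding of class labels and the nearest-vertex decision rule.

Classes are represented by the standard basis vectors e_1, ..., e_c of R^c
(vertices of a regular simplex; any two distinct vertices are sqrt(2) apart).
A linear classifier predicts a point in vertex space and assigns the class
whose vertex is nearest in Euclidean distance.  The deliberately
overparameterized encoding (c dimensions rather than c - 1) gives every class
its own coefficient column, which is what makes class-specific variable
selection possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VertexEncoding:
    """Bijection between class labels and simplex vertices.

    Attributes
    ----------
    class_order : np.ndarray
        Distinct class identifiers; column ``j`` of any one-hot matrix and
        the vertex ``e_j`` both correspond to ``class_order[j]``.
    Y : np.ndarray of shape (n, c)
        One-hot label matrix for the labels the encoding was built from.
    """

    class_order: np.ndarray
    Y: np.ndarray = field(repr=False)

    @property
    def c(self) -> int:
        return len(self.class_order)

    def transform(self, labels) -> np.ndarray:
        """One-hot encode ``labels`` (must all be members of class_order)."""
        return _one_hot(np.asarray(labels), self.class_order)

    def decode(self, Y: np.ndarray):
        """Map one-hot rows (or vertex indices) back to class labels."""
        Y = np.asarray(Y)
        idx = Y if Y.ndim == 1 and not np.issubdtype(Y.dtype, np.floating) \
            else np.argmax(Y, axis=1)
        return self.class_order[np.asarray(idx, dtype=int)]


def _one_hot(labels: np.ndarray, class_order: np.ndarray) -> np.ndarray:
    lookup = {label: j for j, label in enumerate(class_order)}
    try:
        idx = np.array([lookup[label] for label in labels], dtype=int)
    except KeyError as err:
        raise ValueError(
            f"label {err.args[0]!r} does not appear in class_order"
        ) from None
    Y = np.zeros((len(labels), len(class_order)))
    Y[np.arange(len(labels)), idx] = 1.0
    return Y


def encode_labels(labels, class_order=None) -> VertexEncoding:
    """Build a :class:`VertexEncoding` from a label vector.

    When ``class_order`` is omitted it defaults to the sorted distinct
    labels, so the encoding is deterministic.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    if class_order is None:
        class_order = np.unique(labels)
    else:
        class_order = np.asarray(class_order)
    return VertexEncoding(class_order=class_order, Y=_one_hot(labels, class_order))


def predict_vertices(B: np.ndarray, X: np.ndarray, has_intercept: bool = False
                     ) -> np.ndarray:
    """Linear predictions B^T x per sample, as rows of an (m, c) matrix.

    When ``has_intercept`` the first row of ``B`` is the intercept and a
    constant column of ones is implicitly appended to ``X``.
    """
    B = np.asarray(B, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = B.shape[0] - (1 if has_intercept else 0)
    if X.shape[1] != p:
        raise ValueError(f"X has {X.shape[1]} columns, expected {p}")
    if has_intercept:
        return X @ B[1:] + B[0]
    return X @ B


def nearest_vertex_index(V: np.ndarray) -> np.ndarray:
    """Index of the nearest simplex vertex for each row of ``V``.

    ||v - e_j||^2 = ||v||^2 - 2 v_j + 1, so the nearest vertex maximizes the
    j-th coordinate; ``argmax`` breaks ties toward the lowest class index.
    """
    return np.argmax(np.atleast_2d(V), axis=1)


def classify(B: np.ndarray, X: np.ndarray, enc: VertexEncoding,
             has_intercept: bool = False):
    """Assign each sample to the class whose vertex is nearest its prediction."""
    V = predict_vertices(B, X, has_intercept=has_intercept)
    if V.shape[1] != enc.c:
        raise ValueError("B column count does not match the encoding")
    return enc.decode(nearest_vertex_index(V))
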