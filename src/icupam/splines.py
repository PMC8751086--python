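"""P-spline building blocks: B-spline bases, difference penalties, tensors.

Bases follow the standard P-spline recipe: equally spaced knots extending
beyond the covariate range, a B-spline design matrix, and a difference
penalty on adjacent coefficients. Sum-to-zero identifiability constraints
are absorbed by a null-space reparameterization so constrained smooths stay
ordinary penalized blocks.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def bspline_design(x, xmin: float, xmax: float, nbasis: int, degree: int = 3) -> np.ndarray:
    """Dense B-spline design matrix with *nbasis* columns on [xmin, xmax].

    Values outside the range are clamped to the boundary (constant
    extrapolation of the boundary basis functions), which is the safe choice
    for prediction slightly outside the training range.
    """
    if nbasis <= degree:
        raise ValueError("nbasis must exceed the spline degree")
    x = np.clip(np.asarray(x, dtype=float), xmin, xmax)
    dx = (xmax - xmin) / (nbasis - degree)
    knots = xmin + dx * np.arange(-degree, nbasis + 1)
    dm = BSpline.design_matrix(x, knots, degree, extrapolate=True)
    return dm.toarray()


def difference_penalty(nbasis: int, order: int = 2) -> np.ndarray:
    """Penalty matrix D'D for an order-``order`` difference penalty."""
    D = np.diff(np.eye(nbasis), n=order, axis=0)
    return D.T @ D


def sum_to_zero_constraint(X: np.ndarray) -> np.ndarray:
    """Null-space transform Z (k x k-1) enforcing mean(X @ Z @ b) = 0.

    Multiplying the basis by Z removes the direction confounded with the
    intercept; the penalty must be transformed as Z' S Z.
    """
    c = X.mean(axis=0, keepdims=True)  # 1 x k
    # Orthonormal basis of the null space of c via full SVD.
    _, _, vt = np.linalg.svd(c)
    return vt[1:, :].T


def row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product (the tensor-product design construction)."""
    if A.shape[0] != B.shape[0]:
        raise ValueError("row counts must agree")
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


def tensor_penalties(k1: int, k2: int, order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Marginal roughness penalties for a k1 x k2 tensor-product smooth."""
    S1 = np.kron(difference_penalty(k1, order), np.eye(k2))
    S2 = np.kron(np.eye(k1), difference_penalty(k2, order))
    return S1, S2
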