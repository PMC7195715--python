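"""Penalized B-spline bases for smooth terms.

A smooth term is represented by a cubic B-spline basis with clamped
boundary knots and interior knots at covariate quantiles, a second-order
difference penalty, and a sum-to-zero identifiability constraint absorbed
by a Householder reparameterisation.

The penalty differences are taken with respect to the basis' Greville
abscissae rather than the coefficient index.  B-splines reproduce linear
functions exactly when their coefficients are linear in the Greville
positions, so this choice makes the penalty null space (after absorbing
the constant into the intercept) exactly the linear trend in the
covariate: an infinitely penalized smooth degenerates to the straight-line
fit, which is what the effective-degrees-of-freedom limits and the
linear-model cross-checks in this package rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


@dataclass
class SmoothBasis:
    """Centered design columns + penalty for one smooth term."""

    knots: np.ndarray  # full (clamped) knot vector
    raw_dim: int  # k, number of raw basis functions
    X_s: np.ndarray  # n x (k-1) centered basis
    S: np.ndarray  # (k-1) x (k-1) PSD penalty in the constrained basis
    center_transform: np.ndarray  # k x (k-1), maps constrained -> raw coefs
    boundary: tuple


def bspline_basis(
    x: np.ndarray,
    n_basis: int,
    degree: int = 3,
    boundary: tuple | None = None,
):
    """Cubic B-spline design matrix with clamped boundary knots.

    Interior knots sit at quantiles of ``x``.  Rows sum to one (partition
    of unity); evaluation outside ``boundary`` is an error — no
    extrapolation.

    Returns ``(B, knots)`` where ``B`` is ``len(x) x n_basis``.
    """
    x = np.asarray(x, dtype=float)
    if boundary is None:
        boundary = (float(x.min()), float(x.max()))
    lo, hi = boundary
    if not lo < hi:
        raise ValueError("boundary interval is degenerate")
    if x.min() < lo - 1e-12 or x.max() > hi + 1e-12:
        raise ValueError("covariate values outside the basis boundary")
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError("n_basis must be at least degree + 1")
    if n_interior > 0:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(x, probs)
        if np.any(np.diff(interior) <= 0) or interior[0] <= lo or interior[-1] >= hi:
            raise ValueError(
                "tied covariate quantiles produce coincident knots; reduce k"
            )
    else:
        interior = np.empty(0)
    knots = np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])
    xq = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xq, knots, degree, extrapolate=False).toarray()
    return B, knots


def greville_abscissae(knots: np.ndarray, degree: int = 3) -> np.ndarray:
    """Knot averages at which B-spline coefficients act like function values."""
    k = len(knots) - degree - 1
    return np.array([knots[q + 1 : q + degree + 1].mean() for q in range(k)])


def difference_penalty(
    n_basis: int, order: int = 2, positions: np.ndarray | None = None
) -> np.ndarray:
    """P-spline difference penalty DᵀD of the given order.

    With ``positions`` given, divided differences with respect to those
    positions are used, so the null space consists of coefficient
    sequences linear (for order 2) in the positions; the default uses the
    coefficient index.
    """
    if n_basis < order + 1:
        raise ValueError("n_basis must exceed the difference order")
    pos = np.arange(n_basis, dtype=float) if positions is None else np.asarray(positions, float)
    D = np.eye(n_basis)
    for _ in range(order):
        step = pos[1:] - pos[:-1]
        D = (D[1:] - D[:-1]) / step[:, None]
        pos = 0.5 * (pos[1:] + pos[:-1])
    S = D.T @ D
    return 0.5 * (S + S.T)


def apply_centering(B: np.ndarray, S: np.ndarray, knots=None, boundary=None) -> SmoothBasis:
    """Absorb the sum-to-zero-over-samples constraint.

    The constraint ``1ᵀ B beta = 0`` is absorbed by an orthonormal basis Z
    of the orthogonal complement of the column-sum vector; the penalty is
    transformed congruently (ZᵀSZ), so quadratic forms are preserved.
    """
    n, k = B.shape
    c = B.sum(axis=0)
    Q, _ = np.linalg.qr(np.column_stack([c, np.eye(k)[:, : k - 1]]))
    # first column of Q spans c; the rest span the constraint space
    Z = Q[:, 1:]
    X_s = B @ Z
    X_s = X_s - X_s.mean(axis=0)  # remove numerical drift in column sums
    Sc = Z.T @ S @ Z
    Sc = 0.5 * (Sc + Sc.T)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X_s])) < k:
        raise ValueError(
            "rank-deficient centered basis on these covariate values; reduce k"
        )
    return SmoothBasis(
        knots=np.asarray(knots) if knots is not None else np.empty(0),
        raw_dim=k,
        X_s=X_s,
        S=Sc,
        center_transform=Z,
        boundary=boundary if boundary is not None else (np.nan, np.nan),
    )


def build_smooth(x: np.ndarray, k: int = 10, boundary: tuple | None = None) -> SmoothBasis:
    """Full smooth-term construction: basis, Greville penalty, centering.

    The penalty is rescaled to unit spectral norm so that smoothing
    parameters live on a data-scale-free axis and the selection grid
    covers both the unpenalized and the fully linearized limits for any
    covariate spacing.
    """
    B, knots = bspline_basis(x, n_basis=k, degree=3, boundary=boundary)
    xi = greville_abscissae(knots, degree=3)
    S = difference_penalty(k, order=2, positions=xi)
    S = S / np.linalg.eigvalsh(S).max()
    if boundary is None:
        boundary = (float(np.min(x)), float(np.max(x)))
    return apply_centering(B, S, knots=knots, boundary=boundary)
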