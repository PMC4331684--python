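"""Plain non-negative matrix factorization by multiplicative updates.

Factorizes a non-negative M x N matrix X as X ~ U V^T with U (M x K) and
V (N x K) non-negative, minimizing the squared Frobenius reconstruction
error.  The multiplicative updates never increase the objective, so the
recorded objective trace is non-increasing.

This is the unregularized base case of the graph- and label-regularized
factorization in :mod:`rnmfnet.rnmf`, which reduces to it when both
regularization weights are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NmfFactors", "nmf_objective", "nmf_update", "nmf_fit", "EPS"]

#: Floor applied to multiplicative-update denominators.  Keeps the updates
#: defined when a factor column collapses to zero; small enough to preserve
#: monotonicity to numerical precision.
EPS = 1e-12


@dataclass
class NmfFactors:
    """Basis U (M x K), coefficients V (N x K), and the objective trace."""

    U: np.ndarray
    V: np.ndarray
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.ndim != 2 or self.V.ndim != 2:
            raise ValueError("U and V must be 2-D")
        if self.U.shape[1] != self.V.shape[1]:
            raise ValueError(
                f"rank mismatch: U has {self.U.shape[1]} components, "
                f"V has {self.V.shape[1]}"
            )
        if np.any(self.U < 0) or np.any(self.V < 0):
            raise ValueError("factors must be non-negative")


def nmf_objective(X: np.ndarray, factors: NmfFactors) -> float:
    """Squared Frobenius reconstruction error ``||X - U V^T||_F^2``."""
    X = np.asarray(X, dtype=float)
    M, N = X.shape
    if factors.U.shape[0] != M or factors.V.shape[0] != N:
        raise ValueError(
            f"X is {X.shape} but factors reconstruct "
            f"({factors.U.shape[0]}, {factors.V.shape[0]})"
        )
    resid = X - factors.U @ factors.V.T
    return float(np.sum(resid * resid))


def _check_finite(mat: np.ndarray, name: str, iteration: int | None) -> None:
    if not np.all(np.isfinite(mat)):
        where = f" at iteration {iteration}" if iteration is not None else ""
        raise FloatingPointError(
            f"non-finite values appeared in factor {name}{where}"
        )


def nmf_update(
    X: np.ndarray, factors: NmfFactors, *, iteration: int | None = None
) -> NmfFactors:
    """One synchronous multiplicative pass: U first, then V using the new U.

        U <- U * (X V) / (U V^T V)
        V <- V * (X^T U) / (V U^T U)

    Denominators are floored at :data:`EPS`.  The pass never increases the
    reconstruction objective (to numerical precision).
    """
    X = np.asarray(X, dtype=float)
    U, V = factors.U, factors.V
    U = U * (X @ V) / np.maximum(U @ (V.T @ V), EPS)
    _check_finite(U, "U", iteration)
    V = V * (X.T @ U) / np.maximum(V @ (U.T @ U), EPS)
    _check_finite(V, "V", iteration)
    return NmfFactors(U=U, V=V, objective_trace=list(factors.objective_trace))


def nmf_fit(
    X: np.ndarray,
    K: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmfFactors:
    """Fit a rank-K factorization from a uniform (0, 1) random start.

    Iterates :func:`nmf_update` until the relative objective change drops
    below ``tol`` or ``max_iter`` passes have run.  The trace holds the
    objective after each pass.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if K < 1:
        raise ValueError("K must be a positive integer")
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    M, N = X.shape
    rng = np.random.default_rng(seed)
    factors = NmfFactors(U=rng.uniform(size=(M, K)), V=rng.uniform(size=(N, K)))
    prev = nmf_objective(X, factors)
    for it in range(max_iter):
        factors = nmf_update(X, factors, iteration=it)
        obj = nmf_objective(X, factors)
        factors.objective_trace.append(obj)
        if prev > 0 and abs(prev - obj) / prev < tol:
            break
        prev = obj
    return factors
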