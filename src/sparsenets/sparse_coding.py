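"""ℓ1-regularized sparse coding of signals against a dictionary.

For a signal ``s`` and dictionary ``D`` (m×k, unit-ball atoms) the code is

    α* = argmin_α  ½‖s − Dα‖₂² + λ‖α‖₁

solved by cyclic coordinate descent with covariance updates (the Gram
matrix ``G = DᵀD`` and correlations ``c = Dᵀs`` are precomputed, so a full
coordinate sweep costs O(k²) per signal regardless of m).  Because the
columns of a signal matrix are independent problems sharing the same
dictionary, all columns are swept simultaneously as vectorized updates, and
columns that have converged are frozen out of later sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError
from .io import SignalMatrix

__all__ = ["SparseCode", "sparse_code", "sparse_code_all", "lasso_objective"]

#: coefficients with |α| above this count as nonzero
NONZERO_TOL = 1e-10
#: convergence: max coefficient change within a sweep
CONVERGENCE_TOL = 1e-10
MAX_SWEEPS = 10_000


@dataclass(frozen=True)
class SparseCode:
    """Solution of the single-signal lasso problem."""

    coefficients: np.ndarray
    objective: float
    n_nonzero: int


def lasso_objective(
    s: np.ndarray, D: np.ndarray, alpha: np.ndarray, lam: float
) -> float:
    """½‖s − Dα‖² + λ‖α‖₁ — also valid for matrices (Frobenius + entrywise ℓ1)."""
    resid = np.asarray(s) - np.asarray(D) @ np.asarray(alpha)
    return float(0.5 * np.sum(resid**2) + lam * np.sum(np.abs(alpha)))


def _check_inputs(S: np.ndarray, D: np.ndarray, lam: float) -> None:
    if D.ndim != 2:
        raise ShapeError(f"dictionary must be 2D, got shape {D.shape}")
    if S.shape[0] != D.shape[0]:
        raise ShapeError(
            f"signal has {S.shape[0]} rows but dictionary has {D.shape[0]}"
        )
    if not np.isfinite(S).all() or not np.isfinite(D).all() or not np.isfinite(lam):
        raise ValueError("non-finite values in sparse coding inputs")
    if lam < 0:
        raise ValueError(f"lam must be non-negative, got {lam}")
    if lam == 0:
        m, k = D.shape
        if k > m or np.linalg.matrix_rank(D) < k:
            raise ValueError(
                "lam = 0 requires k <= m and a full-column-rank dictionary"
            )


def _coordinate_descent(
    G: np.ndarray,
    C: np.ndarray,
    lam: float,
    tol: float = CONVERGENCE_TOL,
    max_sweeps: int = MAX_SWEEPS,
) -> np.ndarray:
    """Cyclic coordinate descent on all columns at once.

    G is k×k (DᵀD), C is k×n (DᵀS).  Returns the k×n coefficient matrix.
    Zero atoms (G_jj = 0) contribute nothing and keep zero coefficients.
    """
    k, n = C.shape
    A = np.zeros((k, n))
    diag = np.diag(G).copy()
    live = diag > 0.0
    # R[j, c] = c_j - (G A)_jc : partial correlations, maintained incrementally
    cols = np.arange(n)
    R = C.copy()
    A_w = A  # views into the unconverged working set
    R_w = R
    for _ in range(max_sweeps):
        max_delta = np.zeros(A_w.shape[1])
        for j in range(k):
            if not live[j]:
                continue
            rj = R_w[j] + diag[j] * A_w[j]
            if lam > 0.0:
                new = np.sign(rj) * np.maximum(np.abs(rj) - lam, 0.0) / diag[j]
            else:
                new = rj / diag[j]
            delta = new - A_w[j]
            nz = delta != 0.0
            if np.any(nz):
                A_w[j] = new
                R_w -= np.outer(G[:, j], delta)
                np.maximum(max_delta, np.abs(delta), out=max_delta)
        still = max_delta >= tol
        if not np.any(still):
            break
        if not np.all(still):
            # columns are independent problems: converged ones are final
            A[:, cols] = A_w
            cols = cols[still]
            A_w = A[:, cols].copy()
            R_w = R_w[:, still].copy()
    A[:, cols] = A_w
    return A


def sparse_code(s: np.ndarray, D, lam: float) -> SparseCode:
    """Solve the single-signal lasso problem against dictionary ``D``."""
    atoms = getattr(D, "atoms", D)
    atoms = np.asarray(atoms, dtype=float)
    s = np.asarray(s, dtype=float).ravel()
    _check_inputs(s[:, None], atoms, lam)
    G = atoms.T @ atoms
    C = atoms.T @ s[:, None]
    alpha = _coordinate_descent(G, C, lam)[:, 0]
    obj = lasso_objective(s, atoms, alpha, lam)
    return SparseCode(
        coefficients=alpha,
        objective=obj,
        n_nonzero=int(np.count_nonzero(np.abs(alpha) > NONZERO_TOL)),
    )


def sparse_code_all(S, D, lam: float) -> np.ndarray:
    """Sparse-code every column of a signal matrix; returns the k×n matrix α.

    Columns are solved independently — the result never depends on the order
    in which they are processed.
    """
    data = S.data if isinstance(S, SignalMatrix) else np.asarray(S, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    atoms = getattr(D, "atoms", D)
    atoms = np.asarray(atoms, dtype=float)
    _check_inputs(data, atoms, lam)
    G = atoms.T @ atoms
    C = atoms.T @ data
    return _coordinate_descent(G, C, lam)
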