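"""Nonnegativity-constrained strictly convex quadratic programming.

Block principal pivoting (Kim & Park style) for

    min_x  1/2 x^T Q x - c^T x   s.t.  x >= 0,

with Q symmetric positive definite.  Finite termination is guaranteed for
P-matrices by falling back to single-index (Murty) exchanges when the
number of infeasibilities stops decreasing.  Solutions are exact on the
active set: bound coordinates are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["nnqp", "NNQPResult"]


@dataclass
class NNQPResult:
    x: np.ndarray
    grad: np.ndarray        # Q x - c (the dual/KKT residual vector)
    iterations: int
    converged: bool
    kkt_residual: float


def _solve_free(Q: np.ndarray, c: np.ndarray, free: np.ndarray) -> np.ndarray:
    x = np.zeros(c.shape[0])
    if free.any():
        idx = np.flatnonzero(free)
        sub = Q[np.ix_(idx, idx)]
        x[idx] = cho_solve(cho_factor(sub, lower=True, check_finite=False),
                           c[idx], check_finite=False)
    return x


def nnqp(Q: np.ndarray, c: np.ndarray, tol: float = 1e-12,
         max_iter: int | None = None,
         start_free: np.ndarray | None = None) -> NNQPResult:
    """Solve min 1/2 x'Qx - c'x subject to x >= 0 by block pivoting.

    ``tol`` is relative to the problem scale max(|c|, diag Q);
    ``start_free`` optionally seeds the initial free set (the converged
    solution does not depend on it).
    """
    n = c.shape[0]
    if max_iter is None:
        max_iter = max(50, 10 * n)
    scale = max(np.abs(c).max(initial=0.0), np.abs(np.diag(Q)).max(initial=1.0))
    eps = tol * scale

    if start_free is None:
        free = np.zeros(n, dtype=bool)  # start all-bound (x = 0)
    else:
        free = np.asarray(start_free, dtype=bool).copy()
    best_ninf = n + 1
    backup = 3  # full exchanges allowed before reverting to single swaps

    for it in range(1, max_iter + 1):
        x = _solve_free(Q, c, free)
        grad = Q @ x - c
        bad_x = free & (x < -eps)            # free coordinates gone negative
        bad_g = (~free) & (grad < -eps)      # bound coordinates pulling inward
        ninf = int(bad_x.sum() + bad_g.sum())
        if ninf == 0:
            x[~free] = 0.0
            np.clip(x, 0.0, None, out=x)
            kkt = max(
                np.abs(grad[free]).max(initial=0.0),
                -grad[~free].min(initial=0.0),
            )
            return NNQPResult(x, grad, it, True, float(kkt) / scale)
        if ninf < best_ninf:
            best_ninf = ninf
            backup = 3
            free[bad_x] = False
            free[bad_g] = True
        elif backup > 0:
            backup -= 1
            free[bad_x] = False
            free[bad_g] = True
        else:
            # Murty's single-index rule: flip only the largest-index violator
            k = max(np.flatnonzero(bad_x | bad_g))
            free[k] = ~free[k]

    x = _solve_free(Q, c, free)
    grad = Q @ x - c
    np.clip(x, 0.0, None, out=x)
    kkt = float(max(np.abs(grad[free]).max(initial=0.0),
                    -grad[~free].min(initial=0.0))) / scale
    return NNQPResult(x, grad, max_iter, False, kkt)
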