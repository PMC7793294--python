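"""Sign-constrained L2-regularized linear regression with learnable bias.

The training problem for weights ``w`` (w_i >= 0 on excitatory rows,
w_i <= 0 on inhibitory rows) and bias ``b`` is

    E(w, b) = 1/2 sum_mu (sum_i w_i x_{i mu} + b - y_mu)^2
              + (N gamma / 2) sum_i w_i^2 .

A gauge transformation (flipping the sign of inhibitory input rows) maps
this to a nonnegativity-constrained ridge problem, solved exactly on the
active set by block principal pivoting; a learned bias is eliminated by
centering over the pattern index.  Inactive weights are exactly zero, which
makes the zero-weight fraction well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from ._qp import nnqp
from .signals import Dataset

__all__ = ["FitConfig", "FitResult", "Diagnostics", "fit", "diagnostics",
           "save_fit"]


@dataclass(frozen=True)
class FitConfig:
    """Solver configuration.

    bias_mode : "learned" optimizes b jointly; "fixed" clamps b to bias_value
        (the balance-theory convention b = I sqrt(N) is left to the caller).
    sign_constrained : disable to obtain the unconstrained ridge baseline.
    zero_threshold : relative threshold under which a rescaled weight
        sqrt(N) w is counted as silent (guards external solver routes; the
        native solver returns exact zeros).
    """

    gamma: float = 0.1
    bias_mode: str = "learned"
    bias_value: float = 0.0
    sign_constrained: bool = True
    kkt_tol: float = 1e-10
    max_iter: int | None = None
    zero_threshold: float = 1e-6

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.bias_mode not in ("learned", "fixed"):
            raise ValueError("bias_mode must be 'learned' or 'fixed'")
        if self.kkt_tol <= 0:
            raise ValueError("kkt_tol must be positive")


@dataclass
class FitResult:
    """Trained weights and the simulation-side observables."""

    w: np.ndarray
    b: float
    energy_density: float      # E / N
    error_density: float       # energy_density - (gamma/2) * v
    v: float                   # sum_i w_i^2
    h_tilde: float             # mean-input component  sum_c N_c wbar_c xbar_c + b
    c: float                   # weight-input correlation (1/(sqrt(N) P)) sum dw_i x_imu
    p0: float                  # fraction of exactly-zero weights
    converged: bool
    iterations: int
    kkt_residual: float

    def rescaled_weights(self) -> np.ndarray:
        """sqrt(N) * w, the O(1) scale of the mean-field weight density."""
        return np.sqrt(self.w.shape[0]) * self.w


@dataclass
class Diagnostics:
    h_tilde: float
    c: float
    p0: float
    hist: np.ndarray = field(repr=False)
    bin_edges: np.ndarray = field(repr=False)


def _balance_terms(w: np.ndarray, b: float, dataset: Dataset) -> tuple[float, float]:
    pop, N, P = dataset.pop, dataset.N, dataset.P
    ne = pop.n_exc(N)
    h = b
    dw = np.empty(N)
    for sl, xbar in ((slice(0, ne), pop.xbar_E), (slice(ne, N), pop.xbar_I)):
        wc = w[sl]
        if wc.size:
            h += wc.size * wc.mean() * xbar
            dw[sl] = wc - wc.mean()
        # empty population contributes nothing
    c = float(dw @ dataset.X.sum(axis=1)) / (np.sqrt(N) * P)
    return float(h), c


def fit(dataset: Dataset, config: FitConfig) -> FitResult:
    """Globally minimize the regression loss over the sign-feasible orthant.

    Returns the exact constrained minimizer (unique for gamma > 0); raises
    no exception on non-convergence, which is reported on the result.
    """
    X, y, pop = dataset.X, dataset.y, dataset.pop
    N, P = X.shape
    gamma = config.gamma

    if config.sign_constrained:
        s = pop.signs(N)
        Xs = X * s[:, None]
    else:
        s = np.ones(N)
        Xs = X

    if config.bias_mode == "learned":
        col_means = Xs.mean(axis=1)
        Xc = Xs - col_means[:, None]
        yc = y - y.mean()
    else:
        Xc = Xs
        yc = y - config.bias_value

    iterations = 0
    converged = True
    kkt = 0.0
    if not config.sign_constrained:
        if gamma > 0:
            Q = Xc @ Xc.T + N * gamma * np.eye(N)
            wt = np.linalg.solve(Q, Xc @ yc)
        else:
            wt, *_ = np.linalg.lstsq(Xc.T, yc, rcond=None)
    elif gamma > 0:
        Q = Xc @ Xc.T
        Q[np.diag_indices_from(Q)] += N * gamma
        res = nnqp(Q, Xc @ yc, tol=config.kkt_tol, max_iter=config.max_iter)
        wt, iterations, converged = res.x, res.iterations, res.converged
        kkt = res.kkt_residual
    else:
        # gamma = 0: the normal-equation matrix may be singular; use the
        # Lawson-Hanson route on the design matrix instead.
        wt, _ = _scipy_nnls(Xc.T, yc)
        iterations = -1

    w = s * wt
    if config.bias_mode == "learned":
        b = float(y.mean() - col_means @ wt)
    else:
        b = config.bias_value

    resid = Xc.T @ wt - yc
    v = float(w @ w)
    energy = 0.5 * float(resid @ resid) + 0.5 * N * gamma * v
    eps = energy / N
    eps_err = eps - 0.5 * gamma * v

    p0 = _zero_fraction(wt, config.zero_threshold)
    h_tilde, c = _balance_terms(w, b, dataset)

    return FitResult(
        w=w, b=b, energy_density=eps, error_density=eps_err, v=v,
        h_tilde=h_tilde, c=c, p0=p0, converged=converged,
        iterations=iterations, kkt_residual=kkt,
    )


def _zero_fraction(wt: np.ndarray, rel_threshold: float) -> float:
    active = np.abs(wt[wt != 0])
    if active.size == 0:
        return 1.0
    thr = rel_threshold * np.median(active)
    return float(np.mean(np.abs(wt) <= thr))


def save_fit(result: FitResult, prefix) -> None:
    """Serialize scalars to ``<prefix>.fit.json`` and weights to CSV."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scalars = {
        k: getattr(result, k)
        for k in ("b", "energy_density", "error_density", "v", "h_tilde",
                  "c", "p0", "converged", "iterations", "kkt_residual")
    }
    with open(f"{prefix}.fit.json", "w") as fh:
        json.dump(scalars, fh, indent=1)
    np.savetxt(f"{prefix}.weights.csv", result.w, delimiter=",")


def diagnostics(result: FitResult, dataset: Dataset, bins: int = 60) -> Diagnostics:
    """Balance decomposition and the rescaled-weight histogram.

    The histogram is over sqrt(N) w (density-normalized), the scale on which
    the mean-field weight distribution is stated.
    """
    wr = result.rescaled_weights()
    hist, edges = np.histogram(wr, bins=bins, density=True)
    return Diagnostics(result.h_tilde, result.c, result.p0, hist, edges)
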