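"""Mean-field theory conditioned on the sample-covariance spectrum.

For rotationally invariant input ensembles (xi = U S V^T with Haar U, V)
the typical learning curves depend on the data only through the eigenvalue
distribution of the sample covariance xi xi^T / N and the output expansion
coefficients c_mu on the right singular basis.  The constrained theory
reduces to a scalar self-consistency coupling the (unchanged) entropic
relation with the Stieltjes transform of the input spectrum; the resulting
effective parameter Lambda-tilde_w enters the loss exactly where the ridge
gamma enters the unconstrained pseudo-inverse formula — it acts as an
implicit regularization, and Lambda-tilde_w > gamma always.

Averaging conventions: the w-side (resolvent) average runs over the full
length-N eigenvalue multiset, zeros included; the energetic averages
<lam_y ... / (lam_x + .)> are (1/P)-normalized sums over the P output
components, paired by rank, with lam_x = 0 beyond min(N, P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .ec_theory import (
    ECOrderParams,
    G,
    TheoryPrediction,
    _pop_arrays,
    weight_distribution,
)
from .perceptron import FitResult, _balance_terms, _zero_fraction
from .signals import Dataset, PopulationSpec, SCSpectralModel

__all__ = [
    "SCOrderParams",
    "MarchenkoPasturSpectrum",
    "solve_sc",
    "unconstrained_sc",
    "pseudo_inverse_fit",
]


@dataclass
class SCOrderParams:
    dq_w: float
    q_w: float
    A: float
    B: float
    C: float
    I: float
    Lam_w: float            # effective (implicit) regularization
    dq_u: float
    q_u: float
    phase: str = "error"
    residual: float = 0.0


@dataclass(frozen=True)
class MarchenkoPasturSpectrum:
    """Analytic i.i.d.-input spectrum (closed-form Stieltjes transform)."""

    alpha: float

    def resolvent_N(self, shift):
        """N-averaged <1/(lam + shift)>: root of m = 1/(shift + alpha/(1+m))."""
        b = shift + self.alpha - 1.0
        return (-b + np.sqrt(b * b + 4.0 * shift)) / (2.0 * shift)

    def paired_mean(self, shift: float, power: int = 1) -> float:
        """(1/P)-normalized <1/(lam_x + shift)^power> with uniform lam_y = 1."""
        a = self.alpha

        def p1(s):
            m = self.resolvent_N(s)
            if a <= 1.0:
                return (m - (1.0 - a) / s) / a
            return m / a + (1.0 - 1.0 / a) / s

        if power == 1:
            return float(np.real(p1(shift)))
        if power == 2:
            h = 1e-20  # complex-step derivative: exact to machine precision
            return float(-np.imag(p1(shift + 1j * h)) / h)
        raise ValueError("power must be 1 or 2")


def _resolvent_N(model, shift: float) -> float:
    if isinstance(model, MarchenkoPasturSpectrum):
        return float(model.resolvent_N(shift))
    lam = np.asarray(model.lam_x, dtype=float)
    return float(np.mean(1.0 / (lam + shift)))


def _pmean(model, shift: float, power: int = 1) -> float:
    """Energetic average <lam_y / (lam_x + shift)^power> (P-convention)."""
    if isinstance(model, MarchenkoPasturSpectrum):
        return model.paired_mean(shift, power)
    lx, ly = model.paired_spectra()
    return float(np.mean(ly / (lx + shift) ** power))


def _loss_at(model, pop: PopulationSpec, gamma: float, alpha: float):
    """Solve the scalar self-consistency; return (A, dq, Lam, eps) or None."""
    f, eta, sgn, sigma, kap = _pop_arrays(pop, gamma)

    def pieces(A: float):
        dq = float(np.sum(f * 0.5 / kap(A)))
        lam = 1.0 / dq - A
        return dq, lam

    def resid(A: float):
        dq, lam = pieces(A)
        if lam <= 0:
            return math.nan
        return dq - _resolvent_N(model, lam)

    grid = np.logspace(-12.0, 12.0, 241)
    vals = np.array([resid(A) for A in grid])
    ok = ~np.isnan(vals)
    hit = np.flatnonzero(ok & (vals == 0.0))
    idx = np.flatnonzero(ok[:-1] & ok[1:] & (vals[:-1] * vals[1:] < 0))
    if hit.size:
        A = float(grid[hit[0]])
    elif idx.size == 0:
        return None
    else:
        k = idx[0]
        A = brentq(resid, grid[k], grid[k + 1], xtol=1e-300, rtol=8.9e-16)
    dq, lam = pieces(A)
    eps = 0.5 * alpha * pop.sigma_y**2 * lam * _pmean(model, lam, 1)
    return A, dq, lam, eps


def solve_sc(
    model, pop: PopulationSpec, gamma: float, alpha: float | None = None
) -> tuple[SCOrderParams, TheoryPrediction]:
    """Solve the sample-covariance theory with an optimal bias (B = 0).

    ``model`` is an :class:`~dalereg.signals.SCSpectralModel` (finite
    eigenvalue multiset) or a :class:`MarchenkoPasturSpectrum`.  The squared
    weight norm v is obtained from the envelope identity v = 2 de/dgamma
    (exact in the unconstrained limit, where it reproduces the
    pseudo-inverse result); the remaining entropic order parameters follow
    from v and the shared truncated-Gaussian relations.
    """
    if alpha is None:
        alpha = model.alpha
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    sol = _loss_at(model, pop, gamma, alpha)
    if sol is None:
        if gamma == 0 and alpha <= 0.5 + 1e-12:
            params = SCOrderParams(math.inf, math.nan, 0.0, 0.0, math.nan,
                                   math.nan, 0.0, math.nan, math.nan,
                                   phase="zero_error")
            pred = TheoryPrediction(0.0, 0.0, math.nan, math.nan, None,
                                    math.nan, math.nan, math.nan, math.nan,
                                    math.nan)
            return params, pred
        raise RuntimeError("no root found for the sample-covariance system")
    A, dq, lam, eps = sol

    # v = 2 de/dgamma by a finite difference along the solution path
    h = 1e-6 * max(1.0, gamma)
    if gamma - h > 0:
        e_hi = _loss_at(model, pop, gamma + h, alpha)[3]
        e_lo = _loss_at(model, pop, gamma - h, alpha)[3]
        v = (e_hi - e_lo) / h
    else:
        e_hi = _loss_at(model, pop, gamma + h, alpha)[3]
        v = 2.0 * (e_hi - eps) / h
    eps_err = eps - 0.5 * gamma * v

    f, eta, sgn, sigma, kap = _pop_arrays(pop, gamma)
    kappa = kap(A)
    C = 2.0 * v / float(np.sum(f / (sigma**2 * kappa**2)))
    q_w = 0.5 * C * float(np.sum(f / kappa**2))
    I = -math.sqrt(C) * float(G(0.0)) * float(np.sum(f * sgn * eta / kappa))
    dq_u = ((alpha - 1.0) + lam * dq) / alpha
    q_u = 2.0 * eps_err / alpha

    params = SCOrderParams(dq, q_w, A, 0.0, C, I, lam, dq_u, q_u,
                           residual=abs(dq - _resolvent_N(model, lam)))
    ec_like = ECOrderParams(dq, q_w, A, 0.0, C, I)
    dist = weight_distribution(ec_like, pop, gamma)
    pred = TheoryPrediction(
        eps=eps, eps_err=eps_err, v=v, I=I, b=None, p0=dist.p0,
        M_E=dist.means[0], M_I=dist.means[1],
        S_E=dist.stds[0], S_I=dist.stds[1],
    )
    return params, pred


def unconstrained_sc(
    model, gamma: float, sigma_y: float, alpha: float | None = None
) -> tuple[float, float]:
    """Exact unconstrained (ridge / pseudo-inverse) ensemble averages.

    Returns (eps_unc, q_w_unc):
        eps_unc = (alpha/2) sigma_y^2 gamma <lam_y / (lam_x + gamma)>,
        q_w_unc = alpha sigma_y^2 <lam_x lam_y / (lam_x + gamma)^2>.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if alpha is None:
        alpha = model.alpha
    p1 = _pmean(model, gamma, 1)
    p2 = _pmean(model, gamma, 2)
    eps_unc = 0.5 * alpha * sigma_y**2 * gamma * p1
    q_w_unc = alpha * sigma_y**2 * (p1 - gamma * p2)
    return eps_unc, q_w_unc


def pseudo_inverse_fit(
    dataset: Dataset, gamma: float, bias_mode: str = "learned",
    bias_value: float = 0.0, zero_threshold: float = 1e-6,
) -> FitResult:
    """Unconstrained ridge (gamma > 0) or minimum-norm interpolating solution.

    Computed through the SVD of the (bias-centered) input matrix,
    w* = U diag(s / (s^2 + N gamma)) V^T y_c — an independent route from the
    normal-equation solver used by :func:`dalereg.perceptron.fit`.
    """
    X, y = dataset.X, dataset.y
    N, P = X.shape
    if gamma == 0 and P > N + (bias_mode == "learned"):
        raise ValueError("gamma = 0 requires P <= N for an interpolating solution")
    if bias_mode == "learned":
        col_means = X.mean(axis=1)
        Xc = X - col_means[:, None]
        yc = y - y.mean()
    elif bias_mode == "fixed":
        Xc = X
        yc = y - bias_value
    else:
        raise ValueError("bias_mode must be 'learned' or 'fixed'")

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if gamma > 0:
        filt = s / (s**2 + N * gamma)
    else:
        filt = np.where(s > s.max(initial=0.0) * max(N, P) * np.finfo(float).eps,
                        np.divide(1.0, s, out=np.zeros_like(s), where=s > 0), 0.0)
    w = U @ (filt * (Vt @ yc))
    b = float(y.mean() - col_means @ w) if bias_mode == "learned" else bias_value

    resid = Xc.T @ w - yc
    v = float(w @ w)
    energy = 0.5 * float(resid @ resid) + 0.5 * N * gamma * v
    h_tilde, c = _balance_terms(w, b, dataset)
    return FitResult(
        w=w, b=b, energy_density=energy / N,
        error_density=energy / N - 0.5 * gamma * v, v=v,
        h_tilde=h_tilde, c=c, p0=_zero_fraction(w, zero_threshold),
        converged=True, iterations=1, kkt_residual=0.0,
    )
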