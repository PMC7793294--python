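"""Mean-field (replica-symmetric) theory with a known ensemble covariance.

Zero-temperature saddle-point equations for the sign-constrained ridge
regression problem.  The scaled order parameters are

    dq_w  (written Delta-q-tilde): scaled overlap gap, diverging at capacity,
    A, C : scaled entropic conjugates,
    B    : scaled bias conjugate (B = 0 exactly when the bias is optimized),
    q_w  : second moment of the rescaled weights J_i = sigma_i sqrt(N) w_i,
    I    : scaled bias current, b = I sqrt(N) (+ ybar at order 1).

Spectral averages run over the eigenvalue multiset {lam_mu} of the P x P
pattern covariance; (1/N) sums over the P = alpha N eigenvalues are written
alpha * mean(.).  The per-population entropic denominators are
kappa_c = A + gamma / sigma_c^2 (the regularization acts on w, not on the
rescaled J, so larger input fluctuations weaken its pull on J).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .signals import PopulationSpec

__all__ = [
    "ECOrderParams",
    "TheoryPrediction",
    "WeightDistribution",
    "solve_ec_optimal_bias",
    "solve_ec_fixed_bias",
    "critical_capacity",
    "critical_capacity_numeric",
    "ec_predict",
    "weight_distribution",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


def H(x):
    """Standard normal upper-tail probability."""
    return 1.0 - ndtr(x)


def G(x):
    """Standard normal density."""
    return np.exp(-0.5 * np.asarray(x, dtype=float) ** 2) / _SQRT2PI


@dataclass
class ECOrderParams:
    dq_w: float
    q_w: float
    A: float
    B: float
    C: float
    I: float
    phase: str = "error"        # "error" or "zero_error" (gamma=0, alpha<=1/2)
    residual: float = 0.0
    converged: bool = True


@dataclass
class TheoryPrediction:
    """Ensemble predictions on the scale of the simulation observables."""

    eps: float                 # loss density <E>/N
    eps_err: float             # eps - (gamma/2) v
    v: float                   # expected sum_i w_i^2
    I: float                   # scaled optimal bias
    b: float | None            # I sqrt(N) + ybar when N is supplied
    p0: float                  # zero-weight fraction
    M_E: float
    M_I: float
    S_E: float
    S_I: float


def _pop_arrays(pop: PopulationSpec, gamma: float):
    f = np.array([pop.f_E, pop.f_I])
    eta = np.array([pop.eta_E, pop.eta_I])
    sgn = np.array([1.0, -1.0])
    sigma = np.array([pop.sigma_E, pop.sigma_I])
    kappa_of_A = lambda A: A + gamma / sigma**2
    return f, eta, sgn, sigma, kappa_of_A


def _T_factor(B: float, eta: np.ndarray, sgn: np.ndarray) -> np.ndarray:
    """Second moment of the unit truncated Gaussian: E[((z - eta B)_{s})^2]."""
    a = eta * B
    return (1.0 + a**2) * H(sgn * a) - sgn * a * G(a)


def _A_of_dq(dq: float, lam_x: np.ndarray, alpha: float) -> float:
    """(1/N) sum_mu lam_mu / (1 + dq lam_mu) over the P = alpha N eigenvalues."""
    return alpha * float(np.mean(lam_x / (1.0 + dq * lam_x)))


def _pair_spectra(lam_x, lam_y) -> tuple[np.ndarray, np.ndarray]:
    lam_x = np.sort(np.asarray(lam_x, dtype=float))[::-1]
    lam_y = np.sort(np.asarray(lam_y, dtype=float))[::-1]
    if lam_x.shape != lam_y.shape:
        raise ValueError("lam_x and lam_y must have equal length (paired by rank)")
    return lam_x, lam_y


def _solve_C_qw(dq, A, B, lam_x, lam_y, pop, gamma, alpha):
    f, eta, sgn, sigma, kap = _pop_arrays(pop, gamma)
    kappa = kap(A)
    T2 = float(np.sum(f * _T_factor(B, eta, sgn) / kappa**2))
    den = (1.0 + dq * lam_x) ** 2
    S2 = alpha * float(np.mean(lam_x**2 / den))
    Sy = pop.sigma_y**2 * alpha * float(np.mean(lam_x * lam_y / den))
    q_w = T2 * Sy / (1.0 - T2 * S2)
    C = Sy + q_w * S2
    return C, q_w


def _I_of_B(B, C, A, pop, gamma) -> float:
    f, eta, sgn, sigma, kap = _pop_arrays(pop, gamma)
    kappa = kap(A)
    a = eta * B
    return math.sqrt(C) * float(
        np.sum(f * (eta**2 * B * H(sgn * a) - sgn * eta * G(a)) / kappa)
    )


def _system_residual(p: ECOrderParams, lam_x, lam_y, pop, gamma, alpha) -> float:
    """Max absolute residual of the five saddle-point equations."""
    f, eta, sgn, sigma, kap = _pop_arrays(pop, gamma)
    kappa = kap(p.A)
    r1 = p.dq_w - float(np.sum(f * H(sgn * eta * p.B) / kappa))
    r2 = p.A - _A_of_dq(p.dq_w, lam_x, alpha)
    C, q_w = _solve_C_qw(p.dq_w, p.A, p.B, lam_x, lam_y, pop, gamma, alpha)
    r3 = p.C - C
    r4 = p.q_w - q_w
    r5 = p.I - _I_of_B(p.B, p.C, p.A, pop, gamma)
    scale = max(1.0, abs(p.dq_w), abs(p.C), abs(p.q_w))
    return max(abs(r) for r in (r1, r2, r3, r4, r5)) / scale


def solve_ec_optimal_bias(
    lam_x, lam_y, pop: PopulationSpec, gamma: float, alpha: float
) -> ECOrderParams:
    """Solve the saddle point with the bias chosen optimally (B = 0).

    Bias stationarity forces B = 0, reducing the system to a scalar fixed
    point for dq_w coupling the entropic relation
    dq_w = sum_c f_c / (2 kappa_c) with the spectral relation for A.
    For gamma = 0 and alpha <= 1/2 no finite solution exists (zero-error
    phase); this is reported via ``phase`` rather than an exception.
    """
    lam_x, lam_y = _pair_spectra(lam_x, lam_y)
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    f, eta, sgn, sigma, kap = _pop_arrays(pop, gamma)

    def resid(dq: float) -> float:
        A = _A_of_dq(dq, lam_x, alpha)
        return dq - float(np.sum(f * 0.5 / kap(A)))

    grid = np.logspace(-12, 12, 241)
    vals = np.array([resid(d) for d in grid])
    hit = np.flatnonzero(vals == 0.0)
    sign_change = np.flatnonzero(vals[:-1] * vals[1:] < 0)
    if hit.size:
        dq = float(grid[hit[0]])
    elif sign_change.size == 0:
        # Divergent-overlap criterion: as dq -> inf the load term saturates
        # at alpha times the positive-eigenvalue mass while the entropic
        # side demands 1/2 at gamma = 0; below that asymptote no finite
        # root exists (zero-error phase).
        if gamma == 0 and alpha * _positive_mass(lam_x) <= 0.5 + 1e-12:
            return ECOrderParams(math.inf, math.nan, 0.0, 0.0, math.nan,
                                 math.nan, phase="zero_error")
        raise RuntimeError(
            "no representable root of the overlap equation; for spectra "
            "decaying below machine precision the gamma = 0 overlap exceeds "
            "floating-point range just above capacity"
        )
    else:
        k = sign_change[0]
        dq = brentq(resid, grid[k], grid[k + 1], xtol=1e-300, rtol=8.9e-16)
    A = _A_of_dq(dq, lam_x, alpha)
    C, q_w = _solve_C_qw(dq, A, 0.0, lam_x, lam_y, pop, gamma, alpha)
    I = _I_of_B(0.0, C, A, pop, gamma)
    p = ECOrderParams(dq, q_w, A, 0.0, C, I)
    p.residual = _system_residual(p, lam_x, lam_y, pop, gamma, alpha)
    return p


def solve_ec_fixed_bias(
    lam_x, lam_y, pop: PopulationSpec, gamma: float, alpha: float,
    I_fixed: float, damping: float = 0.5, max_iter: int = 2000,
    tol: float = 1e-9,
) -> ECOrderParams:
    """Solve the full saddle-point system with the bias clamped to I_fixed.

    Damped fixed-point iteration over (dq_w, B); requires gamma > 0 and a
    nonzero mean-rate ratio in at least one population (otherwise the bias
    conjugate cannot move).
    """
    if gamma <= 0:
        raise ValueError("fixed-bias theory requires gamma > 0")
    lam_x, lam_y = _pair_spectra(lam_x, lam_y)
    f, eta, sgn, sigma, kap = _pop_arrays(pop, gamma)
    if np.all(f * np.abs(eta) == 0):
        raise ValueError("fixed-bias equations need a population with eta != 0")

    dq = solve_ec_optimal_bias(lam_x, lam_y, pop, gamma, alpha).dq_w
    B = 0.0
    A = C = q_w = 0.0
    for it in range(1, max_iter + 1):
        A = _A_of_dq(dq, lam_x, alpha)
        dq_new = float(np.sum(f * H(sgn * eta * B) / kap(A)))
        C, q_w = _solve_C_qw(dq, A, B, lam_x, lam_y, pop, gamma, alpha)

        def ires(Bx: float) -> float:
            return _I_of_B(Bx, C, A, pop, gamma) - I_fixed

        lo, hi = -50.0, 50.0
        B_new = brentq(ires, lo, hi, xtol=1e-14)
        dq = (1.0 - damping) * dq + damping * dq_new
        B = (1.0 - damping) * B + damping * B_new
        p = ECOrderParams(dq, q_w, A, B, C, I_fixed)
        res = _system_residual(p, lam_x, lam_y, pop, gamma, alpha)
        if res < tol:
            p.residual = res
            p.converged = True
            return p
    p = ECOrderParams(dq, q_w, A, B, C, I_fixed, converged=False)
    p.residual = _system_residual(p, lam_x, lam_y, pop, gamma, alpha)
    return p


def critical_capacity(constrained: bool = True) -> float:
    """Critical load at gamma = 0 with a learned bias.

    0.5 for sign-constrained weights — independent of the covariance
    spectrum and of the E/I split — and 1 for unconstrained weights
    (generic full-rank interpolation).
    """
    return 0.5 if constrained else 1.0


def _positive_mass(lam: np.ndarray) -> float:
    """Fraction of strictly positive eigenvalues, PSD round-off forgiven.

    Eigenvalues above -1e-10 count as positive: a unit-diagonal covariance
    is positive semidefinite, so values at the round-off floor stand for
    true positive eigenvalues of a strictly positive-definite kernel.
    Spectra carrying genuine atoms at zero should be assessed analytically.
    """
    return float(np.mean(np.asarray(lam) > -1e-10))


def critical_capacity_numeric(
    eigs_for_alpha: Callable[[float], np.ndarray],
    pop: PopulationSpec | None = None,
    lo: float = 0.05,
    hi: float = 1.0,
    tol: float = 1e-6,
    positive_mass: float | None = None,
) -> float:
    """Locate the capacity as the infimum load with a finite overlap solution.

    Bisects on alpha between the zero-error and error phases of the
    gamma = 0 overlap equation.  Existence of a finite positive root is
    decided through its divergent-overlap limit: the load side saturates at
    alpha times the positive-eigenvalue mass of the spectrum while the
    entropic side equals 1/2 — the only evaluation that remains exact when
    the spectrum decays below machine precision and the overlap near
    capacity leaves floating-point range.
    """
    pop = pop or PopulationSpec()

    def has_root(alpha: float) -> bool:
        lam = np.asarray(eigs_for_alpha(alpha), dtype=float)
        mass = positive_mass if positive_mass is not None else _positive_mass(lam)
        return alpha * mass > 0.5

    if has_root(lo) or not has_root(hi):
        raise RuntimeError("capacity not bracketed by [lo, hi]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_root(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def ec_predict(
    params: ECOrderParams, lam_x, lam_y, pop: PopulationSpec,
    gamma: float, alpha: float, N: int | None = None,
) -> TheoryPrediction:
    """Evaluate the observable predictions at a solved saddle point.

    eps is the full loss density (fit error plus regularization); at B = 0
    it reduces to (sigma_y^2 / 2N) sum_mu lam^y_mu / (1 + dq_w lam^x_mu).
    """
    if params.phase == "zero_error":
        return TheoryPrediction(0.0, 0.0, math.nan, math.nan, None,
                                math.nan, math.nan, math.nan, math.nan, math.nan)
    lam_x, lam_y = _pair_spectra(lam_x, lam_y)
    f, eta, sgn, sigma, kap = _pop_arrays(pop, gamma)
    dq, A, B, C, I = params.dq_w, params.A, params.B, params.C, params.I
    kappa = kap(A)
    T = _T_factor(B, eta, sgn)

    eps_y = 0.5 * pop.sigma_y**2 * alpha * float(
        np.mean(lam_y / (1.0 + dq * lam_x))
    )
    entropic_gap = 0.5 * C * (dq - float(np.sum(f * T / kappa)))
    eps = B * math.sqrt(C) * I + entropic_gap + eps_y

    v = C * float(np.sum(f * T / (sigma**2 * kappa**2)))
    eps_err = eps - 0.5 * gamma * v

    dist = weight_distribution(params, pop, gamma)
    b = I * math.sqrt(N) + pop.ybar if N is not None else None
    return TheoryPrediction(
        eps=eps, eps_err=eps_err, v=v, I=I, b=b, p0=dist.p0,
        M_E=dist.means[0], M_I=dist.means[1],
        S_E=dist.stds[0], S_I=dist.stds[1],
    )


@dataclass
class WeightDistribution:
    """Mixture density of the rescaled weights sqrt(N) w.

    A point mass p0 at zero plus one truncated Gaussian per population,
    supported on its sign-feasible half line.
    """

    p0: float
    fracs: np.ndarray       # population fractions (f_E, f_I)
    signs: np.ndarray       # (+1, -1)
    means: np.ndarray       # untruncated component means M_c
    stds: np.ndarray        # untruncated component stds Sigma_c

    def pdf(self, x) -> np.ndarray:
        """Density of the nonzero part (the delta at zero is omitted)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for fc, sc, mc, st in zip(self.fracs, self.signs, self.means, self.stds):
            mask = sc * x > 0
            out[mask] += fc * G((x[mask] - mc) / st) / st
        return out

    def nonzero_mass(self) -> float:
        return 1.0 - self.p0

    def cdf_nonzero(self, x) -> np.ndarray:
        """CDF of the weight density conditioned on being nonzero."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros_like(x)
        fE, fI = self.fracs
        mE, mI = self.means
        sE, sI = self.stds
        # inhibitory support (-inf, 0)
        out += fI * ndtr((np.minimum(x, 0.0) - mI) / sI)
        pos = x > 0
        out[pos] += fE * (ndtr((x[pos] - mE) / sE) - ndtr(-mE / sE))
        return out / self.nonzero_mass()

    def second_moment(self) -> float:
        """E[(sqrt(N) w)^2] of the full mixture (equals the predicted v)."""
        total = 0.0
        for fc, sc, mc, st in zip(self.fracs, self.signs, self.means, self.stds):
            a = -sc * mc / st  # truncation point in standard units
            # E[x^2 1{s x > 0}] for x ~ N(m, s^2)
            total += fc * ((mc**2 + st**2) * H(a) + sc * st * mc * G(a))
        return total


def weight_distribution(
    params: ECOrderParams, pop: PopulationSpec, gamma: float
) -> WeightDistribution:
    """Mean-field distribution of sqrt(N) w at the solved saddle point.

    M_c = -eta_c B sqrt(C) / (sigma_c A + gamma / sigma_c),
    Sigma_c =        sqrt(C) / (sigma_c A + gamma / sigma_c),
    p0 = f_E H(-eta_E B) + f_I H(eta_I B)   (= 1/2 whenever B = 0).
    """
    f, eta, sgn, sigma, kap = _pop_arrays(pop, gamma)
    den = sigma * kap(params.A)  # sigma_c A + gamma / sigma_c
    stds = math.sqrt(params.C) / den
    means = -eta * params.B * math.sqrt(params.C) / den
    p0 = float(f[0] * H(-eta[0] * params.B) + f[1] * H(eta[1] * params.B))
    return WeightDistribution(p0, f, sgn, means, stds)
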