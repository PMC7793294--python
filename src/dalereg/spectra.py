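"""Eigenvalue spectra of stationary covariances and random-matrix ensembles.

For a unit-diagonal Toeplitz covariance of a stationary process the
eigenvalues approximate the power spectral density lambda(phi) evaluated on
the Fourier grid (Szego asymptotics); the closed forms for the exponential
and squared-exponential (rbf) kernels are implemented here, together with
the Marchenko-Pastur law and the Stieltjes-type averages used by the
sample-covariance theory.
"""

from __future__ import annotations

import math

import numpy as np

from .signals import TemporalCovariance, build_temporal_covariance

__all__ = [
    "exponential_spectrum",
    "rbf_spectrum",
    "toeplitz_eigenvalues",
    "temporal_eigenvalues",
    "marchenko_pastur",
    "mp_edges",
    "stieltjes_mean",
    "paired_spectral_mean",
]


def exponential_spectrum(phi, tau: float):
    """Power spectrum of C(mu-nu) = exp(-|mu-nu|/tau).

    lambda(phi) = (1 - x^2) / (1 - 2 x cos(phi) + x^2) with x = exp(-1/tau).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = math.exp(-1.0 / tau)
    phi = np.asarray(phi, dtype=float)
    return (1.0 - x**2) / (1.0 - 2.0 * x * np.cos(phi) + x**2)


def rbf_spectrum(phi, tau: float):
    """Power spectrum of C(mu-nu) = exp(-(mu-nu)^2 / (2 tau^2)).

    lambda(phi) = theta_3(phi/2, q) with nome q = exp(-1/(2 tau^2)); the
    theta series is truncated once the dropped term falls below 1e-16.
    Where the true value lies below double precision (large tau near
    phi = pi) the alternating series leaves O(1e-16) cancellation noise,
    which is clamped to the mathematically valid range [0, inf).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    q = math.exp(-1.0 / (2.0 * tau**2))
    phi = np.asarray(phi, dtype=float)
    out = np.ones_like(phi)
    nmax = int(math.ceil(6.0 * tau)) + 10
    for n in range(1, nmax + 1):
        term = q ** (n * n)
        if term < 1e-16:
            break
        out = out + 2.0 * term * np.cos(n * phi)
    return np.maximum(out, 0.0)


def toeplitz_eigenvalues(cov: TemporalCovariance) -> np.ndarray:
    """Eigenvalues of the dense covariance, sorted descending."""
    lam = np.linalg.eigvalsh(cov.C)
    return lam[::-1]


def temporal_eigenvalues(
    kind: str, tau: float | None, P: int, mode: str = "finite"
) -> np.ndarray:
    """Eigenvalue multiset of a temporal covariance used in theory averages.

    mode="finite": the P eigenvalues of the dense P x P Toeplitz matrix
    (finite-size-matched; the default when comparing with simulations).
    mode="thermo": the closed-form spectrum lambda(phi) evaluated on a
    4096-point grid on [0, pi) (thermodynamic limit).
    """
    if mode == "finite":
        return toeplitz_eigenvalues(build_temporal_covariance(kind, tau, P))
    if mode == "thermo":
        if kind == "identity":
            return np.ones(4096)
        phi = (np.arange(4096) + 0.5) * np.pi / 4096
        if kind == "exponential":
            return exponential_spectrum(phi, tau)
        if kind == "rbf":
            return rbf_spectrum(phi, tau)
        raise ValueError(f"unknown covariance kind {kind!r}")
    raise ValueError("mode must be 'finite' or 'thermo'")


def mp_edges(alpha: float) -> tuple[float, float]:
    """Support edges (1 -/+ sqrt(alpha))^2 of the Marchenko-Pastur bulk."""
    r = math.sqrt(alpha)
    return (1.0 - r) ** 2, (1.0 + r) ** 2


def marchenko_pastur(lam, alpha: float):
    """Marchenko-Pastur density of the nonzero sample-covariance eigenvalues.

    For xi (N x P) with i.i.d. unit-variance entries and load alpha = P/N
    in (0, 1], the P nonzero eigenvalues of xi xi^T / N follow

        rho(lam) = sqrt((lam_+ - lam)(lam - lam_-)) / (2 pi alpha lam)

    on [lam_-, lam_+] with edges (1 -/+ sqrt(alpha))^2, zero outside.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    lo, hi = mp_edges(alpha)
    lam = np.asarray(lam, dtype=float)
    out = np.zeros_like(lam)
    inside = (lam > lo) & (lam < hi)
    li = lam[inside]
    out[inside] = np.sqrt((hi - li) * (li - lo)) / (2.0 * np.pi * alpha * li)
    return out


def stieltjes_mean(lams, shift: float) -> float:
    """Average of 1/(lam + shift) over the supplied eigenvalue multiset.

    The caller supplies any zero-padding required by its normalization
    convention; zero eigenvalues contribute 1/shift terms.
    """
    if shift <= 0:
        raise ValueError("shift must be positive")
    lams = np.asarray(lams, dtype=float)
    if lams.size == 0:
        raise ValueError("empty spectrum")
    return float(np.mean(1.0 / (lams + shift)))


def paired_spectral_mean(lam_x, lam_y, shift: float, power: int = 1,
                         x_factor: int = 0) -> float:
    """P-normalized paired average <lam_y * lam_x^x_factor / (lam_x + shift)^power>.

    ``lam_x`` and ``lam_y`` are component-paired length-P arrays (lam_x
    zero-padded beyond min(N, P)); this is the averaging shorthand of the
    sample-covariance energy formulas.
    """
    lam_x = np.asarray(lam_x, dtype=float)
    lam_y = np.asarray(lam_y, dtype=float)
    num = lam_y * lam_x**x_factor if x_factor else lam_y
    return float(np.mean(num / (lam_x + shift) ** power))
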