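"""Synthetic input/output ensembles for the sign-constrained linear perceptron.

Inputs are an ``N x P`` rate matrix ``X`` with excitatory and inhibitory
populations, ``x_{i\\mu} = xbar_i + sigma_i * xi_{i\\mu}``; the normalized
fluctuations ``xi`` are independent across neurons and carry either a
prescribed temporal (Toeplitz) covariance across the pattern index ``mu``
or a prescribed singular-value spectrum of the sample covariance
``xi xi^T / N``.  Outputs are a ``P``-vector ``y = ybar + sigma_y * dy``
with matching machinery.
"""

from __future__ import annotations

import dataclasses
import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import toeplitz, qr

__all__ = [
    "PopulationSpec",
    "TemporalCovariance",
    "SCSpectralModel",
    "Dataset",
    "build_temporal_covariance",
    "sample_signals",
    "make_orthogonal_inputs",
    "make_spectrum_inputs",
    "make_projected_output",
    "save_dataset",
    "load_dataset",
]

_PSD_TOL = 1e-10

# fixed stream offsets for per-component RNG derivation
_STREAM_XI = 0
_STREAM_Y = 1
_STREAM_AUX = 2


def _stream(seed: int, which: int) -> np.random.Generator:
    """Derive an independent child generator from a master integer seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(which,)))


@dataclass(frozen=True)
class PopulationSpec:
    """Excitatory/inhibitory population statistics of inputs and output.

    Parameters
    ----------
    f_E : fraction of excitatory (positively constrained) weights, in [0, 1].
    xbar_E, xbar_I : mean input rates of the two populations.
    sigma_E, sigma_I : input rate standard deviations (positive).
    ybar, sigma_y : mean and standard deviation of the output signal.
    """

    f_E: float = 0.8
    xbar_E: float = 1.0
    xbar_I: float = 1.0
    sigma_E: float = 1.0
    sigma_I: float = 1.0
    ybar: float = 1.0
    sigma_y: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.f_E <= 1.0:
            raise ValueError(f"f_E must lie in [0, 1], got {self.f_E}")
        for name in ("sigma_E", "sigma_I", "sigma_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def f_I(self) -> float:
        return 1.0 - self.f_E

    @property
    def eta_E(self) -> float:
        """Rate-to-fluctuation ratio xbar_E / sigma_E."""
        return self.xbar_E / self.sigma_E

    @property
    def eta_I(self) -> float:
        return self.xbar_I / self.sigma_I

    # Dale's law sign conventions (class constants, not fields)
    s_E = 1
    s_I = -1

    def n_exc(self, N: int) -> int:
        """Number of excitatory rows: round(f_E * N); rows 0..n_exc-1 are E."""
        return int(round(self.f_E * N))

    def signs(self, N: int) -> np.ndarray:
        """Per-row sign constraints: +1 for E rows, -1 for I rows."""
        s = np.full(N, -1.0)
        s[: self.n_exc(N)] = 1.0
        return s

    def row_means(self, N: int) -> np.ndarray:
        m = np.full(N, self.xbar_I)
        m[: self.n_exc(N)] = self.xbar_E
        return m

    def row_stds(self, N: int) -> np.ndarray:
        s = np.full(N, self.sigma_I)
        s[: self.n_exc(N)] = self.sigma_E
        return s


@dataclass(frozen=True)
class TemporalCovariance:
    """Unit-diagonal symmetric Toeplitz covariance across the pattern index."""

    kind: str
    tau: float
    P: int
    C: np.ndarray = field(repr=False, compare=False)

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        if C.shape != (self.P, self.P):
            raise ValueError("covariance shape does not match P")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("covariance must have unit diagonal")
        object.__setattr__(self, "C", C)

    def sqrt_factor(self) -> np.ndarray:
        """A factor L with C = L L^T (eigen route, PSD-clipped)."""
        if self.kind in ("identity",):
            return np.eye(self.P)
        return _cached_sqrt_factor(self.kind, float(self.tau), self.P) \
            if self.kind in ("exponential", "rbf") else _sqrt_from_matrix(self.C)


def _sqrt_from_matrix(C: np.ndarray) -> np.ndarray:
    lam, E = np.linalg.eigh(C)
    if lam.min() < -_PSD_TOL:
        raise ValueError(
            f"covariance is not positive semidefinite: min eigenvalue {lam.min():.3e}"
        )
    lam = np.clip(lam, 0.0, None)
    return E * np.sqrt(lam)


@functools.lru_cache(maxsize=32)
def _cached_sqrt_factor(kind: str, tau: float, P: int) -> np.ndarray:
    return _sqrt_from_matrix(build_temporal_covariance(kind, tau, P).C)


def build_temporal_covariance(kind: str, tau: float | None, P: int) -> TemporalCovariance:
    """Construct the stationary covariance for the requested kernel.

    kind = "identity"     -> C = I (white patterns; tau ignored)
    kind = "exponential"  -> C_{mu nu} = exp(-|mu - nu| / tau)
    kind = "rbf"          -> C_{mu nu} = exp(-(mu - nu)^2 / (2 tau^2))
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if kind == "identity":
        return TemporalCovariance("identity", 0.0, P, np.eye(P))
    if tau is None or tau <= 0:
        raise ValueError("tau must be positive for correlated kernels")
    lags = np.arange(P, dtype=float)
    if kind == "exponential":
        row = np.exp(-lags / tau)
    elif kind == "rbf":
        row = np.exp(-(lags**2) / (2.0 * tau**2))
    else:
        raise ValueError(f"unknown covariance kind {kind!r}")
    return TemporalCovariance(kind, float(tau), P, toeplitz(row))


@dataclass
class SCSpectralModel:
    """Spectral data of the sample-covariance (rotationally invariant) ensemble.

    ``lam_x`` holds the full length-N eigenvalue multiset of ``xi xi^T / N``
    (zeros included when P < N); ``c`` holds the P output expansion
    coefficients on the right singular basis, with ``lam_y = c**2``.
    """

    kind: str  # orthogonal | gaussian_sv | iid | empirical
    N: int
    P: int
    lam_x: np.ndarray
    c: np.ndarray | None = None
    width_x: float | None = None
    width_y: float | str | None = None
    chi: float | None = None
    V: np.ndarray | None = field(default=None, repr=False)

    @property
    def alpha(self) -> float:
        return self.P / self.N

    def __post_init__(self):
        self.lam_x = np.asarray(self.lam_x, dtype=float)
        if self.lam_x.shape != (self.N,):
            raise ValueError("lam_x must have length N")
        if self.lam_x.min() < -1e-12:
            raise ValueError("lam_x must be nonnegative")
        if abs(self.lam_x.sum() / self.P - 1.0) > 1e-6:
            raise ValueError("eigenvalues of xi xi^T/N must average to 1 over P")

    def lam_y(self) -> np.ndarray:
        """Output component variances c_mu^2 (uniform 1 when c is unset)."""
        if self.c is None:
            return np.ones(self.P)
        return np.asarray(self.c, dtype=float) ** 2

    def paired_spectra(self) -> tuple[np.ndarray, np.ndarray]:
        """(lam_x, lam_y) paired by component over the P output slots.

        Components beyond min(N, P) pair with lam_x = 0.
        """
        m = min(self.N, self.P)
        lx = np.zeros(self.P)
        order = np.sort(self.lam_x)[::-1]
        lx[:m] = order[:m]
        return lx, self.lam_y()


@dataclass
class Dataset:
    """An input matrix, output vector and the metadata that regenerates them."""

    X: np.ndarray
    y: np.ndarray
    pop: PopulationSpec
    cov_x: TemporalCovariance | SCSpectralModel | None
    cov_y: TemporalCovariance | SCSpectralModel | None
    seed: int | None

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]

    @property
    def alpha(self) -> float:
        return self.P / self.N

    def xi(self) -> np.ndarray:
        """Normalized mean-removed fluctuations (x - xbar_i) / sigma_i."""
        N = self.N
        return (self.X - self.pop.row_means(N)[:, None]) / self.pop.row_stds(N)[:, None]


def sample_signals(
    pop: PopulationSpec,
    cov_x: TemporalCovariance,
    cov_y: TemporalCovariance,
    N: int,
    seed: int,
) -> Dataset:
    """Draw temporally correlated inputs and output.

    Row ``i`` of ``X`` is ``xbar_c + sigma_c * xi_i`` with population ``c``
    determined by ``i < round(f_E N)``; each ``xi_i`` is an independent
    Gaussian process with covariance ``cov_x``; ``y`` is a single process
    with covariance ``cov_y`` scaled to mean ``ybar`` and std ``sigma_y``.
    """
    if cov_x.P != cov_y.P:
        raise ValueError("cov_x and cov_y must share the pattern dimension P")
    if N < 2:
        raise ValueError("N must be >= 2")
    P = cov_x.P
    Lx = cov_x.sqrt_factor()
    Ly = cov_y.sqrt_factor()
    xi = _stream(seed, _STREAM_XI).standard_normal((N, P)) @ Lx.T
    dy = Ly @ _stream(seed, _STREAM_Y).standard_normal(P)
    X = pop.row_means(N)[:, None] + pop.row_stds(N)[:, None] * xi
    y = pop.ybar + pop.sigma_y * dy
    return Dataset(X, y, pop, cov_x, cov_y, seed)


def _haar_columns(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """m Haar-distributed orthonormal columns in R^n (QR with sign fix)."""
    Q, R = qr(rng.standard_normal((n, m)), mode="economic")
    return Q * np.sign(np.diag(R))


def make_orthogonal_inputs(
    N: int, P: int, pop: PopulationSpec, seed: int
) -> tuple[Dataset, SCSpectralModel]:
    """Inputs whose mean-removed patterns are exactly orthogonal.

    ``xi = sqrt(N) Q`` with Q an N x P Haar orthonormal frame, so
    ``xi^T xi / N = I_P`` and the spectrum of ``xi xi^T / N`` is P ones and
    N - P zeros.  The output is i.i.d. Gaussian (c_mu = 1 in the ensemble).
    """
    if P > N:
        raise ValueError("orthogonal patterns require P <= N")
    rng = _stream(seed, _STREAM_XI)
    xi = np.sqrt(N) * _haar_columns(rng, N, P)
    X = pop.row_means(N)[:, None] + pop.row_stds(N)[:, None] * xi
    y = pop.ybar + pop.sigma_y * _stream(seed, _STREAM_Y).standard_normal(P)
    lam = np.zeros(N)
    lam[:P] = 1.0
    model = SCSpectralModel("orthogonal", N, P, lam, V=np.eye(P))
    return Dataset(X, y, pop, model, None, seed), model


def make_spectrum_inputs(
    N: int, P: int, width_x: float, pop: PopulationSpec, seed: int
) -> tuple[Dataset, SCSpectralModel]:
    """Inputs with a prescribed Gaussian singular-value profile.

    ``xi = U S V^T`` with Haar U (N x m), V (P x m), m = min(N, P), and
    singular values ``s_k = chi exp(-a_k^2 / (2 width_x^2))`` on the
    normalized rank index ``a_k = k / N``; chi enforces unit entry variance
    ``(1/NP) sum s_k^2 = 1``.  Output i.i.d. Gaussian by default (use
    :func:`make_projected_output` for structured coefficients).
    """
    if width_x <= 0:
        raise ValueError("width_x must be positive")
    if N < 2 or P < 2:
        raise ValueError("N and P must be >= 2")
    m = min(N, P)
    a = np.arange(1, m + 1) / N
    prof = np.exp(-(a**2) / (2.0 * width_x**2))
    chi = np.sqrt(N * P / np.sum(prof**2))
    s = chi * prof
    rng = _stream(seed, _STREAM_XI)
    U = _haar_columns(rng, N, m)
    V = _haar_columns(rng, P, m)
    xi = (U * s) @ V.T
    X = pop.row_means(N)[:, None] + pop.row_stds(N)[:, None] * xi
    y = pop.ybar + pop.sigma_y * _stream(seed, _STREAM_Y).standard_normal(P)
    lam = np.zeros(N)
    lam[:m] = s**2 / N
    model = SCSpectralModel(
        "gaussian_sv", N, P, lam, width_x=width_x, chi=float(chi), V=V
    )
    return Dataset(X, y, pop, model, None, seed), model


def make_projected_output(
    V: np.ndarray,
    width_y: float | str,
    pop: PopulationSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Output built on the right singular basis: y = ybar + sigma_y V c.

    ``c_mu = exp(-a_mu^2 / (2 width_y^2))`` on the normalized component index
    ``a_mu = mu / P``; ``width_y = "uniform"`` sets c_mu = 1 for all mu
    (the i.i.d.-output case).  Returns (y, c).
    """
    V = np.asarray(V, dtype=float)
    P, m = V.shape
    if np.abs(V.T @ V - np.eye(m)).max() > 1e-8:
        raise ValueError("V must have orthonormal columns")
    if width_y == "uniform":
        c = np.ones(m)
    else:
        w = float(width_y)
        if w <= 0:
            raise ValueError("width_y must be positive or 'uniform'")
        a = np.arange(1, m + 1) / P
        c = np.exp(-(a**2) / (2.0 * w**2))
    y = pop.ybar + pop.sigma_y * V @ c
    return y, c


# ---------------------------------------------------------------------------
# delimited-text persistence


def save_dataset(ds: Dataset, prefix: str | Path) -> None:
    """Write X.csv, y.csv and a JSON sidecar with the generating metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}.X.csv", ds.X, delimiter=",")
    np.savetxt(f"{prefix}.y.csv", ds.y, delimiter=",")
    meta: dict = {"pop": dataclasses.asdict(ds.pop), "seed": ds.seed}
    for name, cov in (("cov_x", ds.cov_x), ("cov_y", ds.cov_y)):
        if isinstance(cov, TemporalCovariance):
            meta[name] = {"type": "temporal", "kind": cov.kind, "tau": cov.tau, "P": cov.P}
        elif isinstance(cov, SCSpectralModel):
            meta[name] = {
                "type": "spectral",
                "kind": cov.kind,
                "N": cov.N,
                "P": cov.P,
                "width_x": cov.width_x,
                "width_y": cov.width_y,
            }
        else:
            meta[name] = None
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_dataset(prefix: str | Path) -> Dataset:
    """Read a dataset written by :func:`save_dataset` (or user-supplied CSVs)."""
    prefix = Path(prefix)
    X = np.loadtxt(f"{prefix}.X.csv", delimiter=",", ndmin=2)
    y = np.loadtxt(f"{prefix}.y.csv", delimiter=",")
    meta_path = Path(f"{prefix}.meta.json")
    pop = PopulationSpec()
    seed = None
    cov = {"cov_x": None, "cov_y": None}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        pop = PopulationSpec(**meta["pop"])
        seed = meta.get("seed")
        for name in ("cov_x", "cov_y"):
            info = meta.get(name)
            if info and info["type"] == "temporal":
                cov[name] = build_temporal_covariance(info["kind"], info["tau"], info["P"])
    return Dataset(X, y, pop, cov["cov_x"], cov["cov_y"], seed)
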