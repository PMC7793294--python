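import numpy as np
import pytest

from dalereg.signals import Dataset, PopulationSpec


@pytest.fixture
def pop_default() -> PopulationSpec:
    """Unit population statistics, 80% excitatory."""
    return PopulationSpec()


@pytest.fixture
def pop_asym() -> PopulationSpec:
    """Heterogeneous input scales (inhibitory fluctuations twice as large)."""
    return PopulationSpec(f_E=0.8, sigma_E=0.2, sigma_I=0.4)


def random_small_dataset(rng: np.random.Generator, N: int, P: int,
                         pop: PopulationSpec) -> Dataset:
    """A tiny dense instance for oracle comparisons (no structure assumed)."""
    X = pop.row_means(N)[:, None] + pop.row_stds(N)[:, None] * rng.standard_normal((N, P))
    y = pop.ybar + pop.sigma_y * rng.standard_normal(P)
    return Dataset(X, y, pop, None, None, None)


def brute_force_min(dataset: Dataset, gamma: float, bias_mode: str = "learned",
                    bias_value: float = 0.0) -> tuple[np.ndarray, float, float]:
    """Exact global minimum of the sign-constrained loss by support enumeration.

    For a convex quadratic the minimizer's support F* yields the solution of
    the equality-restricted problem; enumerating all supports and keeping the
    best sign-feasible candidate therefore recovers the global optimum.
    Only viable for N <= ~14.
    """
    X, y, pop = dataset.X, dataset.y, dataset.pop
    N, P = X.shape
    s = pop.signs(N)
    Xs = X * s[:, None]

    def energy(w_tilde, b):
        r = Xs.T @ w_tilde + b - y
        return 0.5 * float(r @ r) + 0.5 * N * gamma * float(w_tilde @ w_tilde)

    best = (None, None, np.inf)
    for mask in range(2 ** N):
        idx = [i for i in range(N) if (mask >> i) & 1]
        k = len(idx)
        cols = [Xs[i] for i in idx]
        if bias_mode == "learned":
            cols.append(np.ones(P))
        if cols:
            A = np.vstack(cols).T
            reg = np.zeros((k + (bias_mode == "learned"),) * 2)
            reg[:k, :k] = N * gamma * np.eye(k)
            target = y if bias_mode == "learned" else y - bias_value
            sol = np.linalg.lstsq(A.T @ A + reg, A.T @ target, rcond=None)[0]
        else:
            sol = np.zeros(0)
        wt = np.zeros(N)
        wt[idx] = sol[:k]
        if np.any(wt[idx] < 0):
            continue
        b = (sol[k] if bias_mode == "learned" else bias_value)
        e = energy(wt, b)
        if e < best[2]:
            best = (s * wt, float(b), e)
    return best
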