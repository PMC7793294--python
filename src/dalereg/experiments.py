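"""Sweep harness reproducing the package's standard experiments at desk scale.

Every run writes a CSV table, a JSON manifest sufficient for bit-identical
replay, and a JSON-lines log with per-cell diagnostics.  Per-cell seeds are
derived deterministically from the master seed and the cell coordinates.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ec_theory, perceptron, sc_theory, signals, spectra

__all__ = [
    "ExperimentConfig",
    "cell_seed",
    "run_capacity_sweep",
    "run_balance_scaling",
    "run_figure",
]

_FLOAT_FMT = "%.10g"


@dataclass
class ExperimentConfig:
    """Parameters of one experiment; defaults mirror the standard settings
    (N = 1000, 50 samples, unit population statistics)."""

    name: str = "experiment"
    seed: int = 0
    outdir: str | Path | None = None
    N: int = 1000
    n_samples: int = 50
    gammas: tuple[float, ...] = (0.1,)
    alphas: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    cov_kind: str = "rbf"
    tau: float = 2.0
    cov_kind_y: str | None = None     # defaults to the input kernel
    taus_y: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)
    pop: signals.PopulationSpec = field(default_factory=signals.PopulationSpec)
    Ns: tuple[int, ...] = (500, 1000, 2000, 4000)
    I_fixed: float = -1.0
    width_x: tuple[float, ...] = (0.3, 1.0)
    widths_y: tuple[float, ...] = (0.2, 0.5, 1.0)
    spectrum_mode: str = "finite"     # finite-size-matched theory averages

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["pop"] = dataclasses.asdict(self.pop)
        d["outdir"] = str(self.outdir) if self.outdir else None
        return d


def cell_seed(master: int, *coords: int) -> int:
    """Deterministic per-cell dataset seed below 2**31."""
    ss = np.random.SeedSequence([int(master), *map(int, coords)])
    return int(ss.generate_state(1)[0] % (2**31))


class _Runner:
    def __init__(self, config: ExperimentConfig, tag: str):
        self.config = config
        self.tag = tag
        self.records: list[dict] = []
        self.outdir = Path(config.outdir) if config.outdir else None
        if self.outdir:
            self.outdir.mkdir(parents=True, exist_ok=True)

    def log(self, **rec):
        rec["experiment"] = self.tag
        self.records.append(rec)

    def finish(self, tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
        if self.outdir:
            manifest = {"tag": self.tag, "config": self.config.to_manifest()}
            (self.outdir / f"{self.tag}.manifest.json").write_text(
                json.dumps(manifest, indent=1, sort_keys=True)
            )
            with open(self.outdir / f"{self.tag}.log.jsonl", "w") as fh:
                for rec in self.records:
                    fh.write(json.dumps(rec, sort_keys=True) + "\n")
            for name, df in tables.items():
                df.to_csv(self.outdir / f"{self.tag}.{name}.csv",
                          index=False, float_format=_FLOAT_FMT)
        return tables


def _sim_cells(config, cov_x, cov_y, gamma, bias_mode="learned", bias_value=0.0,
               coords=(), N=None):
    """Fit config.n_samples independent datasets; return list of FitResults."""
    N = N or config.N
    cfg = perceptron.FitConfig(gamma=gamma, bias_mode=bias_mode,
                               bias_value=bias_value)
    out = []
    for k in range(config.n_samples):
        seed = cell_seed(config.seed, *coords, k)
        ds = signals.sample_signals(config.pop, cov_x, cov_y, N, seed)
        out.append(perceptron.fit(ds, cfg))
    return out


def _mean_se(vals):
    v = np.asarray(vals, dtype=float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0


def run_capacity_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Average loss versus load for i.i.d. signals, per regularization level.

    The simulated loss stays near zero below the sign-constrained capacity
    alpha_c = 1/2 at gamma = 0 and rises sharply beyond it; theory columns
    come from the ensemble-covariance saddle point (f_E-independent).
    """
    runner = _Runner(config, f"capacity_{config.name}")
    rows = []
    for gamma in config.gammas:
        for ia, alpha in enumerate(config.alphas):
            P = int(round(alpha * config.N))
            cov = signals.build_temporal_covariance("identity", None, P)
            t0 = time.time()
            fits = _sim_cells(config, cov, cov, gamma,
                              coords=(int(gamma * 1e6), ia))
            eps, eps_se = _mean_se([f.energy_density for f in fits])
            lam = np.ones(P)
            sol = ec_theory.solve_ec_optimal_bias(lam, lam, config.pop, gamma, alpha)
            th = (ec_theory.ec_predict(sol, lam, lam, config.pop, gamma, alpha).eps
                  if sol.phase == "error" else 0.0)
            rows.append(dict(alpha=alpha, gamma=gamma, eps_sim=eps,
                             eps_se=eps_se, eps_theory=th, phase=sol.phase))
            runner.log(alpha=alpha, gamma=gamma, runtime=time.time() - t0,
                       n_unconverged=sum(not f.converged for f in fits))
    df = pd.DataFrame(rows)
    runner.finish({"table": df})
    return df


def run_balance_scaling(config: ExperimentConfig) -> pd.DataFrame:
    """Mean-input component h-tilde and weight-input correlation c versus N.

    Two arms sharing input realizations at fixed seed: a learned bias
    (h-tilde -> ybar, c -> 0) and a bias fixed at b = I_fixed sqrt(N).
    """
    runner = _Runner(config, f"balance_{config.name}")
    gamma = config.gammas[0]
    alpha = config.alphas[0] if len(config.alphas) == 1 else 0.8
    rows = []
    for iN, N in enumerate(config.Ns):
        P = int(round(alpha * N))
        cov = signals.build_temporal_covariance(config.cov_kind, config.tau, P)
        for mode in ("learned", "fixed"):
            bias_value = config.I_fixed * np.sqrt(N) if mode == "fixed" else 0.0
            t0 = time.time()
            fits = _sim_cells(config, cov, cov, gamma, bias_mode=mode,
                              bias_value=bias_value, coords=(iN,), N=N)
            h, h_se = _mean_se([f.h_tilde for f in fits])
            c, c_se = _mean_se([f.c for f in fits])
            rows.append(dict(N=N, bias_mode=mode, h_tilde=h, h_tilde_se=h_se,
                             c=c, c_se=c_se))
            runner.log(N=N, bias_mode=mode, runtime=time.time() - t0)
    df = pd.DataFrame(rows)
    runner.finish({"table": df})
    return df


def _theory_temporal(config, kind, tau, kind_y, tau_y, alpha, gamma, N):
    P = int(round(alpha * N))
    lam_x = spectra.temporal_eigenvalues(kind, tau, P, mode=config.spectrum_mode)
    lam_y = (lam_x if (kind_y is None or (kind_y == kind and tau_y == tau))
             else spectra.temporal_eigenvalues(kind_y, tau_y, P,
                                               mode=config.spectrum_mode))
    sol = ec_theory.solve_ec_optimal_bias(lam_x, lam_y, config.pop, gamma, alpha)
    return sol, ec_theory.ec_predict(sol, lam_x, lam_y, config.pop, gamma,
                                     alpha, N=N), lam_x, lam_y


def _fig3(config, runner):
    """Closed-form spectra against dense eigenvalues and mean periodograms."""
    P = 1000
    n_proc = min(config.n_samples * 40, 2000)
    out = {}
    for ik, kind in enumerate(("rbf", "exponential")):
        phi = np.pi * (np.arange(P // 2) + 0.5) / (P // 2)
        lam_closed = (spectra.rbf_spectrum(phi, config.tau) if kind == "rbf"
                      else spectra.exponential_spectrum(phi, config.tau))
        cov = signals.build_temporal_covariance(kind, config.tau, P)
        pop = config.pop
        ds = signals.sample_signals(pop, cov, cov, n_proc,
                                    cell_seed(config.seed, 3, ik))
        xi = ds.xi()
        power = np.abs(np.fft.rfft(xi, axis=1)) ** 2 / P
        freqs = 2.0 * np.pi * np.arange(power.shape[1]) / P
        out[f"{kind}_spectrum"] = pd.DataFrame(
            {"phi": phi, "lambda_closed": lam_closed})
        out[f"{kind}_periodogram"] = pd.DataFrame(
            {"phi": freqs, "power_mean": power.mean(axis=0)})
        runner.log(kind=kind, n_processes=n_proc)
    return out


def _fig4(config, runner):
    """Loss, error, weight norm, optimal bias and weight histogram vs load."""
    gamma = config.gammas[0]
    rows = []
    for ia, alpha in enumerate(config.alphas):
        P = int(round(alpha * config.N))
        cov = signals.build_temporal_covariance(config.cov_kind, config.tau, P)
        t0 = time.time()
        fits = _sim_cells(config, cov, cov, gamma, coords=(4, ia))
        sol, pred, *_ = _theory_temporal(config, config.cov_kind, config.tau,
                                         None, None, alpha, gamma, config.N)
        eps, eps_se = _mean_se([f.energy_density for f in fits])
        err, err_se = _mean_se([f.error_density for f in fits])
        v, v_se = _mean_se([f.v for f in fits])
        b, b_se = _mean_se([f.b for f in fits])
        rows.append(dict(alpha=alpha, eps_sim=eps, eps_se=eps_se,
                         eps_theory=pred.eps, err_sim=err, err_se=err_se,
                         err_theory=pred.eps_err, v_sim=v, v_se=v_se,
                         v_theory=pred.v, b_sim=b, b_se=b_se, b_theory=pred.b))
        runner.log(alpha=alpha, runtime=time.time() - t0)
    return {"sweep": pd.DataFrame(rows)}


def _fig5(config, runner):
    """Weight variance vs correlation time; mixed input/output kernels."""
    gamma = config.gammas[0]
    rows_a = []
    for alpha in config.alphas[:3]:
        for tau in (1.0, 2.0, 5.0, 10.0, 20.0):
            sol, pred, *_ = _theory_temporal(config, config.cov_kind, tau,
                                             None, None, alpha, gamma, config.N)
            # variance of sqrt(N) w = second moment (zero mean at B = 0)
            rows_a.append(dict(alpha=alpha, tau=tau, var_theory=pred.v))
    rows_b = []
    for it, tau_y in enumerate(config.taus_y):
        alpha = config.alphas[0]
        P = int(round(alpha * config.N))
        cov_x = signals.build_temporal_covariance(config.cov_kind, 1.0, P)
        cov_y = signals.build_temporal_covariance(config.cov_kind, tau_y, P)
        t0 = time.time()
        fits = _sim_cells(config, cov_x, cov_y, gamma, coords=(5, it))
        sol, pred, *_ = _theory_temporal(config, config.cov_kind, 1.0,
                                         config.cov_kind, tau_y, alpha, gamma,
                                         config.N)
        err, err_se = _mean_se([f.error_density for f in fits])
        v, v_se = _mean_se([f.v for f in fits])
        rows_b.append(dict(tau_y=tau_y, err_sim=err, err_se=err_se,
                           err_theory=pred.eps_err, v_sim=v, v_se=v_se,
                           v_theory=pred.v))
        runner.log(tau_y=tau_y, runtime=time.time() - t0)
    return {"variance_vs_tau": pd.DataFrame(rows_a),
            "mixed_kernels": pd.DataFrame(rows_b)}


def _fig6(config, runner):
    """Sample-covariance models: error vs load and output dimensionality."""
    gamma = config.gammas[0]
    rows = []
    for ia, alpha in enumerate(config.alphas):
        P = int(round(alpha * config.N))
        for im, model_name in enumerate(
                ("orthogonal", *[f"gaussian_{w}" for w in config.width_x])):
            if model_name == "orthogonal" and P > config.N:
                continue
            t0 = time.time()
            errs = []
            model = None
            for k in range(config.n_samples):
                seed = cell_seed(config.seed, 6, ia, im, k)
                if model_name == "orthogonal":
                    ds, model = signals.make_orthogonal_inputs(
                        config.N, P, config.pop, seed)
                else:
                    wx = float(model_name.split("_")[1])
                    ds, model = signals.make_spectrum_inputs(
                        config.N, P, wx, config.pop, seed)
                errs.append(perceptron.fit(
                    ds, perceptron.FitConfig(gamma=gamma)).error_density)
            _, pred = sc_theory.solve_sc(model, config.pop, gamma)
            err, err_se = _mean_se(errs)
            rows.append(dict(model=model_name, alpha=alpha, err_sim=err,
                             err_se=err_se, err_theory=pred.eps_err))
            runner.log(model=model_name, alpha=alpha, runtime=time.time() - t0)
    rows_c = []
    alpha = config.alphas[0]
    P = int(round(alpha * config.N))
    for iw, wy in enumerate(config.widths_y):
        errs = []
        model = None
        for k in range(config.n_samples):
            seed = cell_seed(config.seed, 6, 99, iw, k)
            ds, model = signals.make_orthogonal_inputs(config.N, P, config.pop, seed)
            y, c = signals.make_projected_output(model.V, wy, config.pop)
            ds.y = y
            model.c = c
            errs.append(perceptron.fit(
                ds, perceptron.FitConfig(gamma=gamma)).error_density)
        _, pred = sc_theory.solve_sc(model, config.pop, gamma)
        err, err_se = _mean_se(errs)
        rows_c.append(dict(width_y=wy, err_sim=err, err_se=err_se,
                           err_theory=pred.eps_err))
    return {"models": pd.DataFrame(rows),
            "output_width": pd.DataFrame(rows_c)}


_FIGS = {"fig3": _fig3, "fig4": _fig4, "fig5": _fig5, "fig6": _fig6}


def run_figure(name: str, config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Recompute the tables behind one of the standard figures at desk scale."""
    if name not in _FIGS:
        raise ValueError(f"unknown figure {name!r}; choose from {sorted(_FIGS)}")
    runner = _Runner(config, f"{name}_{config.name}")
    tables = _FIGS[name](config, runner)
    return runner.finish(tables)
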