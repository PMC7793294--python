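import numpy as np
import pytest
from scipy.integrate import quad

from dalereg.ec_theory import (
    _A_of_dq,
    critical_capacity,
    critical_capacity_numeric,
    ec_predict,
    solve_ec_fixed_bias,
    solve_ec_optimal_bias,
    weight_distribution,
)
from dalereg.signals import PopulationSpec
from dalereg.spectra import temporal_eigenvalues


def _flat(P):
    return np.ones(P)


class TestOptimalBiasSaddle:
    def test_flat_spectrum_closed_form(self, pop_default):
        # lam = 1, gamma = 0: dq = 1 / (2 alpha - 1)
        for alpha in (0.6, 0.8, 1.0, 1.5):
            P = int(100 * alpha)
            lam = _flat(P)
            p = solve_ec_optimal_bias(lam, lam, pop_default, 0.0, alpha)
            assert p.dq_w == pytest.approx(1.0 / (2 * alpha - 1), rel=1e-10)
            assert p.B == 0.0
            assert p.residual < 1e-10

    def test_overlap_diverges_at_capacity(self, pop_default):
        # exponential spectrum: bounded away from zero, overlap representable
        lam = temporal_eigenvalues("exponential", 5.0, 400)
        dq_vals = [solve_ec_optimal_bias(lam, lam, pop_default, 0.0, a).dq_w
                   for a in (0.6, 0.55, 0.51)]
        assert dq_vals[0] < dq_vals[1] < dq_vals[2]
        assert dq_vals[2] > 20

    def test_zero_error_phase_below_capacity(self, pop_default):
        lam = _flat(40)
        p = solve_ec_optimal_bias(lam, lam, pop_default, 0.0, 0.4)
        assert p.phase == "zero_error"
        pred = ec_predict(p, lam, lam, pop_default, 0.0, 0.4)
        assert pred.eps == 0.0 and pred.eps_err == 0.0

    def test_symmetric_populations_have_zero_bias(self):
        pop = PopulationSpec(f_E=0.5, xbar_E=1.0, xbar_I=1.0,
                             sigma_E=0.5, sigma_I=0.5)
        lam = _flat(60)
        p = solve_ec_optimal_bias(lam, lam, pop, 0.2, 0.6)
        assert p.I == pytest.approx(0.0, abs=1e-14)

    def test_eq4_lhs_monotone_with_asymptote(self, pop_default):
        # alpha dq <lam/(1+dq lam)> is non-decreasing, saturating at alpha
        lam = temporal_eigenvalues("exponential", 10.0, 300)
        alpha = 0.7
        dqs = np.logspace(-3, 6, 40)
        lhs = np.array([dq * _A_of_dq(dq, lam, alpha) for dq in dqs])
        assert np.all(np.diff(lhs) > -1e-12)
        assert lhs[-1] == pytest.approx(alpha, rel=1e-4)
        assert np.all(lhs <= alpha + 1e-12)


class TestCapacity:
    def test_analytic_values(self):
        assert critical_capacity(constrained=True) == 0.5
        assert critical_capacity(constrained=False) == 1.0

    def test_numeric_capacity_spectrum_independent(self, pop_default):
        for kind, tau in (("identity", None), ("exponential", 5.0), ("rbf", 10.0)):
            ac = critical_capacity_numeric(
                lambda a: temporal_eigenvalues(kind, tau, max(int(400 * a), 4)),
                pop=pop_default, tol=1e-4)
            assert ac == pytest.approx(0.5, abs=1e-3)


class TestPredictions:
    def test_flat_spectrum_energy(self, pop_default):
        lam = _flat(100)
        p = solve_ec_optimal_bias(lam, lam, pop_default, 0.0, 1.0)
        pred = ec_predict(p, lam, lam, pop_default, 0.0, 1.0)
        assert pred.eps == pytest.approx(pop_default.sigma_y**2 / 4, rel=1e-12)

    def test_no_learning_limit(self, pop_default):
        # dq -> 0 (huge gamma): eps -> (alpha sigma_y^2 / 2) <lam_y>
        lam = temporal_eigenvalues("exponential", 4.0, 200)
        alpha = 0.5
        p = solve_ec_optimal_bias(lam, lam, pop_default, 1e8, alpha)
        pred = ec_predict(p, lam, lam, pop_default, 1e8, alpha)
        assert pred.eps == pytest.approx(0.5 * alpha * np.mean(lam), rel=1e-4)

    def test_error_identity_and_gamma_monotonicity(self, pop_asym):
        lam = temporal_eigenvalues("rbf", 2.0, 300)
        eps, vs = [], []
        for g in (0.01, 0.1, 0.5, 2.0):
            p = solve_ec_optimal_bias(lam, lam, pop_asym, g, 0.6)
            pred = ec_predict(p, lam, lam, pop_asym, g, 0.6)
            assert pred.eps_err == pytest.approx(pred.eps - 0.5 * g * pred.v,
                                                 abs=1e-12)
            eps.append(pred.eps)
            vs.append(pred.v)
        assert np.all(np.diff(eps) > 0)   # loss increases with regularization
        assert np.all(np.diff(vs) < 0)    # weights shrink

    def test_gauge_invariance_across_fE(self):
        # with optimal bias and sigma_E = sigma_I the predictions are
        # identical for any E/I split
        lam = temporal_eigenvalues("rbf", 2.0, 240)
        preds = []
        for f_E in (0.2, 0.5, 0.8, 1.0):
            pop = PopulationSpec(f_E=f_E)
            p = solve_ec_optimal_bias(lam, lam, pop, 0.1, 0.6)
            preds.append(ec_predict(p, lam, lam, pop, 0.1, 0.6))
        for pr in preds[1:]:
            assert pr.eps == pytest.approx(preds[0].eps, rel=1e-12)
            assert pr.v == pytest.approx(preds[0].v, rel=1e-12)
            assert pr.p0 == 0.5

    def test_bias_magnitude_minimal_at_symmetric_split(self):
        lam = _flat(120)
        Is = []
        for f_E in (0.2, 0.35, 0.5, 0.65, 0.8):
            pop = PopulationSpec(f_E=f_E)
            Is.append(abs(solve_ec_optimal_bias(lam, lam, pop, 0.1, 0.6).I))
        assert np.argmin(Is) == 2

    def test_weight_variance_grows_as_correlation_time_shrinks(self, pop_default):
        # faster inputs (smaller tau) broaden the synaptic distribution
        variances = []
        for tau in (20.0, 10.0, 5.0, 2.0, 1.0):
            lam = temporal_eigenvalues("rbf", tau, 300)
            p = solve_ec_optimal_bias(lam, lam, pop_default, 0.1, 0.6)
            variances.append(ec_predict(p, lam, lam, pop_default, 0.1, 0.6).v)
        assert np.all(np.diff(variances) > 0)


class TestFixedBias:
    def test_recovers_optimal_solution(self, pop_default):
        lam = temporal_eigenvalues("rbf", 2.0, 250)
        popt = solve_ec_optimal_bias(lam, lam, pop_default, 0.1, 0.5)
        pfix = solve_ec_fixed_bias(lam, lam, pop_default, 0.1, 0.5, popt.I)
        assert pfix.converged
        assert abs(pfix.B) < 1e-8
        assert pfix.dq_w == pytest.approx(popt.dq_w, abs=1e-8)

    def test_p0_formula_at_fixed_bias(self, pop_asym):
        from dalereg.ec_theory import H
        lam = temporal_eigenvalues("exponential", 5.0, 200)
        p = solve_ec_fixed_bias(lam, lam, pop_asym, 0.1, 0.5, -0.7)
        dist = weight_distribution(p, pop_asym, 0.1)
        expect = (pop_asym.f_E * H(-pop_asym.eta_E * p.B)
                  + pop_asym.f_I * H(pop_asym.eta_I * p.B))
        assert dist.p0 == pytest.approx(float(expect), abs=1e-12)

    def test_detuning_bias_raises_loss(self, pop_default):
        lam = temporal_eigenvalues("rbf", 2.0, 250)
        popt = solve_ec_optimal_bias(lam, lam, pop_default, 0.1, 0.5)
        e_opt = ec_predict(popt, lam, lam, pop_default, 0.1, 0.5).eps
        for dI in (-0.5, 0.5):
            pfix = solve_ec_fixed_bias(lam, lam, pop_default, 0.1, 0.5,
                                       popt.I + dI)
            e = ec_predict(pfix, lam, lam, pop_default, 0.1, 0.5).eps
            assert e > e_opt + 1e-6


class TestWeightDistribution:
    def test_optimal_bias_gives_half_silent_zero_means(self, pop_asym):
        lam = temporal_eigenvalues("exponential", 10.0, 300)
        p = solve_ec_optimal_bias(lam, lam, pop_asym, 0.1, 0.6)
        dist = weight_distribution(p, pop_asym, 0.1)
        assert dist.p0 == 0.5
        assert np.all(dist.means == 0.0)

    def test_mixture_mass_bookkeeping(self, pop_asym):
        lam = temporal_eigenvalues("exponential", 10.0, 200)
        for I_fixed in (None, -0.8):
            if I_fixed is None:
                p = solve_ec_optimal_bias(lam, lam, pop_asym, 0.1, 0.5)
            else:
                p = solve_ec_fixed_bias(lam, lam, pop_asym, 0.1, 0.5, I_fixed)
            dist = weight_distribution(p, pop_asym, 0.1)
            mass, _ = quad(dist.pdf, -np.inf, np.inf, limit=200)
            assert mass + dist.p0 == pytest.approx(1.0, abs=1e-8)

    def test_nonzero_weight_density_matches_trained_histogram(self, pop_asym):
        # trained perceptrons on exponentially correlated signals: the
        # pooled nonzero rescaled weights follow the truncated-Gaussian
        # mixture (two-sample KS on seeded subsamples)
        from scipy.stats import ks_2samp, truncnorm
        from dalereg.perceptron import FitConfig, fit
        from dalereg.signals import build_temporal_covariance, sample_signals

        N, P, gamma = 800, 480, 0.1
        cov = build_temporal_covariance("exponential", 10.0, P)
        pooled = []
        for seed in range(6):
            r = fit(sample_signals(pop_asym, cov, cov, N, seed),
                    FitConfig(gamma=gamma))
            wr = r.rescaled_weights()
            pooled.append(wr[wr != 0])
        pooled = np.concatenate(pooled)

        lam = temporal_eigenvalues("exponential", 10.0, P)
        p = solve_ec_optimal_bias(lam, lam, pop_asym, gamma, P / N)
        dist = weight_distribution(p, pop_asym, gamma)
        rng = np.random.default_rng(0)
        n_draw = 400
        comps = rng.random(n_draw) < pop_asym.f_E  # B = 0: masses f_E, f_I
        theory_draws = np.where(
            comps,
            truncnorm.rvs(0, np.inf, scale=dist.stds[0], size=n_draw,
                          random_state=rng),
            truncnorm.rvs(-np.inf, 0, scale=dist.stds[1], size=n_draw,
                          random_state=rng),
        )
        sample = rng.choice(pooled, size=n_draw, replace=False)
        assert ks_2samp(sample, theory_draws).pvalue > 0.01

    def test_second_moment_matches_norm_prediction_by_quadrature(self, pop_asym):
        # integral of (sqrt(N) w)^2 over the mixture equals the predicted v
        lam = temporal_eigenvalues("exponential", 10.0, 300)
        for solver_args in ((0.1, 0.6, None), (0.25, 0.5, -0.6)):
            g, a, I_fixed = solver_args
            if I_fixed is None:
                p = solve_ec_optimal_bias(lam, lam, pop_asym, g, a)
            else:
                p = solve_ec_fixed_bias(lam, lam, pop_asym, g, a, I_fixed)
            pred = ec_predict(p, lam, lam, pop_asym, g, a)
            dist = weight_distribution(p, pop_asym, g)
            m2, _ = quad(lambda x: x**2 * dist.pdf(np.array([x]))[0],
                         -np.inf, np.inf, limit=400)
            assert m2 == pytest.approx(pred.v, abs=1e-8)
            assert dist.second_moment() == pytest.approx(pred.v, rel=1e-10)
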