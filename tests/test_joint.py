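"""Joint likelihood: oracles, factorisation, quadrature, fitting, prediction."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

from fvcjoint import (
    JointModelSpec,
    JointParams,
    PiecewiseHazard,
    UnfittableEndpointError,
    empirical_bayes,
    fit_joint,
    joint_loglik,
    marginal_loglik,
)
from fvcjoint.hazard import survival_loglik
from fvcjoint.joint import JointModelFit, param_names, subject_survival_terms
from fvcjoint.lmm import design_row, posterior_moments, prepare_stats

from conftest import make_dataset, make_subject

CENTER = 72.5


def toy_params(alpha, n_pieces=2):
    log_h0 = np.log(np.linspace(0.2, 0.4, 2 * n_pieces)).reshape(2, n_pieces)
    return JointParams(
        beta=np.array([70.0, -1.5, 0.9, -2.6, 1.2]),
        D=np.array([[9.0, -1.2], [-1.2, 4.0]]),
        sigma2=4.0,
        log_h0=log_h0,
        alpha=alpha,
    )


TOY_KNOTS = np.array([0.5])


def toy_dataset():
    return make_dataset(
        [
            make_subject("a", arm=1, ata=0, baseline=75.0, event_time=0.8, event=1,
                         times=(0.1, 0.4), fvc=(73.0, 71.5)),
            make_subject("b", arm=0, ata=1, baseline=65.0, event_time=1.05, event=0,
                         times=(0.1, 0.5, 0.9), fvc=(64.0, 63.0, 60.5)),
            make_subject("c", arm=1, ata=1, baseline=80.0, event_time=0.3, event=1),
        ]
    )


def brute_force_loglik(params, dataset, knots, association, grid_n=161):
    """Dense-trapezoid integration of the joint integrand over (b0, b1)."""
    total = 0.0
    Dinv = np.linalg.inv(params.D)
    _, logdetD = np.linalg.slogdet(params.D)
    for s in dataset.subjects:
        stats = prepare_stats(make_dataset([s]), CENTER)
        if len(stats.n):
            mu, Sig, _, _ = posterior_moments(
                stats, params.beta, params.D, params.sigma2
            )
            mu, Sig = mu[0], Sig[0]
        else:
            mu, Sig = np.zeros(2), params.D
        sds = np.sqrt(np.diag(Sig))
        grids = [np.linspace(m - 12 * sd, m + 12 * sd, grid_n) for m, sd in zip(mu, sds)]
        B0, B1 = np.meshgrid(grids[0], grids[1], indexing="ij")
        cb = s.baseline_fvc_pct - CENTER
        X = np.array(
            [design_row(s.arm, s.ata_positive, s.baseline_fvc_pct, t, CENTER)[0]
             for t in s.times_years]
        ).reshape(-1, 5)
        resid = s.fvc - X @ params.beta if len(s.times_years) else np.empty(0)
        log_int = np.zeros_like(B0)
        for k, (t, r) in enumerate(zip(s.times_years, resid)):
            log_int += -0.5 * np.log(2 * np.pi * params.sigma2) - 0.5 * (
                (r - B0 - B1 * t) ** 2
            ) / params.sigma2
        for i in range(grid_n):
            for j in range(grid_n):
                b = np.array([B0[i, j], B1[i, j]])
                log_haz, neg_lam = subject_survival_terms(
                    params, knots, association, s.arm, s.ata_positive, cb,
                    s.event_time_years, s.event_indicator, b, center=CENTER,
                )
                log_int[i, j] += neg_lam + (log_haz if s.event_indicator else 0.0)
        quad_prior = (
            Dinv[0, 0] * B0**2 + 2 * Dinv[0, 1] * B0 * B1 + Dinv[1, 1] * B1**2
        )
        log_prior = -np.log(2 * np.pi) - 0.5 * logdetD - 0.5 * quad_prior
        integrand = np.exp(log_int + log_prior)
        val = np.trapezoid(
            np.trapezoid(integrand, grids[1], axis=1), grids[0], axis=0
        )
        total += np.log(val)
    return total


class TestJointLoglikOracle:
    @pytest.mark.parametrize("association", ["slope", "current_value"])
    def test_matches_dense_grid_integration(self, association):
        params = toy_params(alpha=-0.3)
        ds = toy_dataset()
        spec = JointModelSpec(association=association, gh_nodes=25)
        ours = joint_loglik(params, ds, spec, TOY_KNOTS, CENTER)
        brute = brute_force_loglik(params, ds, TOY_KNOTS, association)
        assert ours == pytest.approx(brute, abs=1e-6)

    @pytest.mark.parametrize("association", ["slope", "current_value"])
    def test_factorisation_at_alpha_zero(self, association, small_trial):
        _, ds, _ = small_trial
        params = toy_params(alpha=0.0)
        spec = JointModelSpec(association=association)
        joint = joint_loglik(params, ds, spec, TOY_KNOTS, CENTER)
        from fvcjoint.lmm import LmmParams

        lmm_part = marginal_loglik(
            LmmParams(beta=params.beta, D=params.D, sigma2=params.sigma2), ds, CENTER
        )
        pw = PiecewiseHazard(knots=TOY_KNOTS, log_h0=params.log_h0)
        surv_part = survival_loglik(pw, ds)
        assert joint == pytest.approx(lmm_part + surv_part, abs=1e-8)

    def test_quadrature_convergence_is_monotone_stabilising(self):
        params = toy_params(alpha=-0.3)
        ds = toy_dataset()
        lls = [
            joint_loglik(
                params, ds, JointModelSpec(association="current_value", gh_nodes=k),
                TOY_KNOTS, CENTER,
            )
            for k in (5, 9, 15, 25)
        ]
        gaps = np.abs(np.diff(lls))
        assert gaps[-1] <= gaps[0] + 1e-12
        assert abs(lls[-1] - lls[-2]) < 1e-5

    def test_loglik_value_invariant_to_subject_order(self):
        params = toy_params(alpha=-0.3)
        ds = toy_dataset()
        rev = make_dataset(list(reversed(ds.subjects)))
        spec = JointModelSpec()
        assert joint_loglik(params, ds, spec, TOY_KNOTS, CENTER) == pytest.approx(
            joint_loglik(params, rev, spec, TOY_KNOTS, CENTER), abs=1e-10
        )


class TestSurvivalTerms:
    def test_alpha_zero_reduces_to_baseline_for_both_associations(self):
        params = toy_params(alpha=0.0)
        pw = PiecewiseHazard(knots=TOY_KNOTS, log_h0=params.log_h0)
        from fvcjoint import cumulative_baseline_hazard

        for association in ("slope", "current_value"):
            _, neg_lam = subject_survival_terms(
                params, TOY_KNOTS, association, 1, 0, 2.5, 0.8, 0, np.array([3.0, -2.0])
            )
            assert -neg_lam == pytest.approx(
                cumulative_baseline_hazard(pw, 0, 0.8), abs=1e-12
            )

    def test_one_unit_slower_decline_scales_hazard_by_1_13(self):
        alpha = -np.log(1.13)
        params = toy_params(alpha=alpha)
        args = (TOY_KNOTS, "slope", 1, 0, 0.0, 0.8, 1)
        log_h_ref, neg_lam_ref = subject_survival_terms(
            params, *args, np.array([0.0, 0.0])
        )
        log_h_dec, neg_lam_dec = subject_survival_terms(
            params, *args, np.array([0.0, -1.0])
        )
        assert np.exp(log_h_dec - log_h_ref) == pytest.approx(1.13)
        assert neg_lam_dec / neg_lam_ref == pytest.approx(1.13)

    def test_current_value_piece_integral_matches_adaptive_quadrature(self):
        params = toy_params(alpha=-0.05)
        b = np.array([2.0, -1.5])
        arm, ata, cb, T = 1, 1, 4.0, 0.8
        _, neg_lam = subject_survival_terms(
            params, TOY_KNOTS, "current_value", arm, ata, cb, T, 0, b
        )
        A = params.beta[0] + params.beta[1] * ata + params.beta[2] * cb + b[0]
        C = params.beta[3] + params.beta[4] * arm + b[1]
        pw = PiecewiseHazard(knots=TOY_KNOTS, log_h0=params.log_h0)

        def hazard(t):
            return pw.hazard(ata, t) * np.exp(params.alpha * (A + C * t))

        expected, _ = quad(hazard, 0.0, T, points=[float(TOY_KNOTS[0])], epsabs=1e-13)
        assert -neg_lam == pytest.approx(expected, abs=1e-10)

    def test_degenerate_small_alpha_c_uses_midpoint_limit(self):
        params = toy_params(alpha=1e-12)
        _, neg_lam = subject_survival_terms(
            params, TOY_KNOTS, "current_value", 0, 0, 0.0, 1.0, 0, np.zeros(2)
        )
        assert np.isfinite(neg_lam)


class TestFitJoint:
    def test_recovers_simulation_regime(self, small_trial):
        cfg, ds, _ = small_trial
        fit = fit_joint(ds, JointModelSpec(min_events=10))
        assert fit.converged
        assert abs(fit.params.beta[3] - cfg.beta_t) < 3 * fit.se("time_years")
        assert abs(fit.alpha - cfg.alpha) < 3 * fit.alpha_se

    def test_estimates_invariant_to_subject_permutation(self, small_trial):
        _, ds, _ = small_trial
        spec = JointModelSpec(min_events=10)
        fit1 = fit_joint(ds, spec)
        fit2 = fit_joint(make_dataset(list(reversed(ds.subjects))), spec)
        # reordering perturbs floating-point summation, so the optimiser path
        # can differ within its own tolerance; the optimum itself is shared
        assert fit1.alpha == pytest.approx(fit2.alpha, abs=2e-3)
        # agreement well within a small fraction of each statistical SE
        ses = np.sqrt(np.diag(fit1.vcov)[:5])
        assert np.all(np.abs(fit1.params.beta - fit2.params.beta) < 0.05 * ses)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-3)

    def test_min_events_guard(self, small_trial):
        _, ds, _ = small_trial
        with pytest.raises(UnfittableEndpointError, match="unfittable"):
            fit_joint(ds, JointModelSpec(min_events=10_000))

    def test_alpha_zero_null_is_not_rejected_too_often(self, small_trial):
        # single-replicate smoke of the null: alpha = 0 truth
        from fvcjoint import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n_subjects=150, alpha=0.0)
        ds, _ = simulate_dataset(cfg, seed=5)
        fit = fit_joint(ds, JointModelSpec(min_events=10))
        assert abs(fit.alpha) < 3 * fit.alpha_se

    def test_fit_json_round_trips_key_quantities(self, small_trial):
        import json

        _, ds, _ = small_trial
        fit = fit_joint(ds, JointModelSpec(min_events=10))
        payload = json.loads(fit.to_json())
        assert payload["association"] == "slope"
        assert payload["n"] == ds.n
        assert payload["alpha"] == pytest.approx(fit.alpha)
        assert len(payload["coefficients"]) == len(param_names(fit.params.n_pieces))


class TestEmpiricalBayes:
    def _null_fit(self, ds):
        params = toy_params(alpha=0.0)
        spec = JointModelSpec()
        return JointModelFit(
            spec=spec, params=params, knots=TOY_KNOTS, center=CENTER,
            loglik=0.0, vcov=np.eye(14), names=param_names(2),
            converged=True, n_iter=0, grad_norm=0.0, n=ds.n, n_events=ds.n_events,
        )

    def test_no_data_returns_prior_mode(self):
        s = make_subject("empty", event_time=1.0, event=0)
        fit = self._null_fit(make_dataset([s]))
        mode, cov = empirical_bayes(fit, s)
        assert np.allclose(mode, [0.0, 0.0], atol=1e-6)
        assert np.allclose(cov, fit.params.D, atol=1e-4)

    def test_alpha_zero_mode_equals_lmm_blup(self):
        s = make_subject(
            "x", arm=1, ata=0, baseline=75.0, event_time=1.0, event=0,
            times=(0.2, 0.5, 0.9), fvc=(72.0, 70.0, 69.0),
        )
        fit = self._null_fit(make_dataset([s]))
        stats = prepare_stats(make_dataset([s]), CENTER)
        mu, _, _, _ = posterior_moments(
            stats, fit.params.beta, fit.params.D, fit.params.sigma2
        )
        mode, _ = empirical_bayes(fit, s)
        assert np.allclose(mode, mu[0], atol=1e-5)

    def test_rich_data_mode_approaches_least_squares_slope(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0.01, 1.0, 600)
        b0, b1 = 4.0, -2.0
        params = toy_params(alpha=0.0)
        fixed = (
            params.beta[0] + params.beta[2] * (75.0 - CENTER)
            + (params.beta[3] + params.beta[4]) * t
        )
        y = fixed + b0 + b1 * t + rng.normal(0, 0.5, len(t))
        s = make_subject("rich", arm=1, baseline=75.0, event_time=1.1, times=t, fvc=y)
        fit = self._null_fit(make_dataset([s]))
        mode, _ = empirical_bayes(fit, s)
        coef = np.polyfit(t, y - fixed, 1)
        # with this much data the prior shrinkage is < 1%
        assert mode[1] == pytest.approx(coef[0], abs=0.1)
        assert mode[0] == pytest.approx(coef[1], abs=0.2)
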