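"""Tests of the glottal-side adjoint estimator.

The defining oracle is agreement of the adjoint gradients with central
finite differences of the loss; parameter-recovery tests use the seeded
synthetic generator.
"""

import numpy as np
import pytest

from vfokit.adles import (OptimizerConfig, adles_loss_and_gradient,
                          fit_adles, glottal_residual_loss,
                          residual_and_forcing, solve_adjoint_glottal,
                          vfo_gradients)
from vfokit.exceptions import ConfigurationError
from vfokit.model import (GlottalFlow, VFOInitialConditions, VFOParams,
                          glottal_flow, simulate_vfo)
from vfokit.synth import synth_glottal_case


def _loss_of(params, ug, geom, ics, normalize):
    traj = simulate_vfo(params, ics, t_eval=ug.t)
    _, F, _ = residual_and_forcing(glottal_flow(traj, geom), ug,
                                   normalize=normalize)
    return F


class TestResidualLoss:
    def test_identical_flows_give_zero(self, short_reference_flow):
        R, F = glottal_residual_loss(short_reference_flow,
                                     short_reference_flow)
        assert np.all(R == 0) and F == 0

    def test_constant_offset_integrates_analytically(self):
        t = np.linspace(0.0, 4.0, 401)
        k = 3.5
        u0 = GlottalFlow(t, np.sin(t) + k)
        ug = GlottalFlow(t, np.sin(t))
        R, F = glottal_residual_loss(u0, ug, normalize=False)
        np.testing.assert_allclose(R, k)
        assert F == pytest.approx(k ** 2 * 4.0, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 100)
        _, F = glottal_residual_loss(GlottalFlow(t, rng.standard_normal(100)),
                                     GlottalFlow(t, rng.standard_normal(100)))
        assert F >= 0

    def test_reference_resampled_onto_model_grid(self):
        t = np.linspace(0.0, 2.0, 201)
        tc = np.linspace(0.0, 2.0, 401)
        u0 = GlottalFlow(t, np.cos(t))
        ug = GlottalFlow(tc, np.cos(tc))
        _, F = glottal_residual_loss(u0, ug, normalize=False)
        assert F < 1e-10


class TestAdjoint:
    def test_zero_forcing_gives_zero_adjoint(self, short_reference_flow, geom,
                                             ics):
        traj = simulate_vfo(VFOParams(0.5, 0.32, 0.2), ics,
                            t_eval=short_reference_flow.t)
        adj = solve_adjoint_glottal(traj, VFOParams(0.5, 0.32, 0.2),
                                    np.zeros(len(traj)), geom)
        assert np.max(np.abs(adj.lam)) == 0
        assert np.max(np.abs(adj.eta)) == 0
        grads = vfo_gradients(traj, adj)
        assert grads.as_array().tolist() == [0.0, 0.0, 0.0]

    def test_terminal_conditions_zero(self, short_reference_flow, geom, ics):
        p = VFOParams(0.6, 0.3, 0.4)
        traj = simulate_vfo(p, ics, t_eval=short_reference_flow.t)
        u0 = glottal_flow(traj, geom)
        _, _, r_hat = residual_and_forcing(u0, short_reference_flow)
        adj = solve_adjoint_glottal(traj, p, r_hat, geom)
        for v in (adj.lam, adj.lam_dot, adj.eta, adj.eta_dot):
            assert abs(v[-1]) < 1e-9

    def test_unknown_mode_rejected(self, short_reference_flow, geom, ics):
        traj = simulate_vfo(VFOParams(0.5, 0.32, 0.0), ics,
                            t_eval=short_reference_flow.t)
        with pytest.raises(ConfigurationError):
            solve_adjoint_glottal(traj, VFOParams(0.5, 0.32, 0.0),
                                  np.zeros(len(traj)), geom, mode="bogus")

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_gradients_match_finite_differences(self, seed, geom, ics):
        """The module's defining oracle: adjoint vs central differences."""
        rng = np.random.default_rng(seed)
        truth = VFOParams(0.4 + 0.15 * rng.random(),
                          0.25 + 0.1 * rng.random(),
                          0.4 * rng.random())
        t = np.linspace(0.0, 20.0, 1001)
        ug = glottal_flow(simulate_vfo(truth, ics, t_eval=t), geom)
        p = VFOParams(truth.alpha + 0.08, truth.beta + 0.03,
                      truth.delta + 0.15)
        _, grad, _, _ = adles_loss_and_gradient(p, ug, geom, ics)
        g = grad.as_array()
        eps = 1e-5
        fd = np.zeros(3)
        for i in range(3):
            up, dn = p.as_array(), p.as_array()
            up[i] += eps
            dn[i] -= eps
            fd[i] = (_loss_of(VFOParams(*up), ug, geom, ics, True)
                     - _loss_of(VFOParams(*dn), ug, geom, ics, True)) / (2 * eps)
        np.testing.assert_allclose(g, fd, rtol=1e-3)

    def test_gradient_quadrature_matches_independent_oracle(
            self, short_reference_flow, geom, ics):
        """Eq-form quadratures vs an elementwise loop implementation."""
        p = VFOParams(0.55, 0.3, 0.35)
        traj = simulate_vfo(p, ics, t_eval=short_reference_flow.t)
        u0 = glottal_flow(traj, geom)
        _, _, r_hat = residual_and_forcing(u0, short_reference_flow)
        adj = solve_adjoint_glottal(traj, p, r_hat, geom)
        grads = vfo_gradients(traj, adj)

        def loop_trapz(y, t):
            acc = 0.0
            for i in range(len(t) - 1):
                acc += 0.5 * (y[i] + y[i + 1]) * (t[i + 1] - t[i])
            return acc

        fa = loop_trapz(-(traj.v_r + traj.v_l) * (adj.lam + adj.eta), traj.t)
        fb = loop_trapz((1 + traj.xi_r ** 2) * traj.v_r * adj.lam
                        + (1 + traj.xi_l ** 2) * traj.v_l * adj.eta, traj.t)
        fd_ = loop_trapz(0.5 * (traj.xi_l * adj.eta - traj.xi_r * adj.lam),
                         traj.t)
        scale = max(abs(fa), abs(fb), abs(fd_), 1.0)
        assert abs(grads.F_alpha - fa) / scale < 1e-10
        assert abs(grads.F_beta - fb) / scale < 1e-10
        assert abs(grads.F_delta - fd_) / scale < 1e-10


class TestFit:
    def test_self_consistent_reference_needs_no_descent(self, geom, ics):
        init = VFOParams(0.8, 0.32, 1.0)
        t = np.linspace(0.0, 20.0, 1001)
        ug = glottal_flow(simulate_vfo(init, ics, t_eval=t), geom)
        res = fit_adles(ug, geom, ics, OptimizerConfig(max_iter=5))
        assert res.loss_history[0] < 1e-8
        assert res.n_iter == 0 and res.converged

    def test_descent_with_small_fixed_step(self, geom, ics):
        case = synth_glottal_case(VFOParams(0.5, 0.32, 0.2), ics, geom,
                                  duration=20.0, dt=0.02)
        opt = OptimizerConfig(init_params=VFOParams(0.55, 0.35, 0.3),
                              step_rule="fixed", step_scale=1e-4,
                              max_iter=12)
        res = fit_adles(case.ug, geom, ics, opt)
        assert np.all(np.diff(res.loss_history) <= 1e-12)

    def test_recovery_noiseless_within_5pct(self, geom, ics):
        truth = VFOParams(0.5, 0.32, 0.2)
        case = synth_glottal_case(truth, ics, geom, duration=30.0, dt=0.02)
        opt = OptimizerConfig(init_params=VFOParams(0.6, 0.28, 0.35),
                              max_iter=420)
        res = fit_adles(case.ug, geom, ics, opt, normalize=False)
        rel = np.abs(res.params.as_array() - truth.as_array()) \
            / truth.as_array()
        assert np.all(rel < 0.05), rel

    def test_recovery_1pct_noise_within_15pct(self, geom, ics):
        truth = VFOParams(0.5, 0.32, 0.2)
        case = synth_glottal_case(truth, ics, geom, noise_sd=0.01, seed=11,
                                  duration=30.0, dt=0.02)
        opt = OptimizerConfig(init_params=VFOParams(0.6, 0.28, 0.35),
                              max_iter=220)
        # the noisy forcing spline slows the adaptive adjoint solver; a
        # relaxed tolerance keeps gradients accurate enough for descent
        res = fit_adles(case.ug, geom, ics, opt, normalize=False,
                        adjoint_rtol=1e-6)
        rel = np.abs(res.params.as_array() - truth.as_array()) \
            / truth.as_array()
        assert np.all(rel < 0.15), rel

    def test_reproducible_loss_history(self, geom, ics):
        case = synth_glottal_case(VFOParams(0.5, 0.32, 0.2), ics, geom,
                                  duration=15.0, dt=0.02)
        opt = OptimizerConfig(init_params=VFOParams(0.55, 0.3, 0.3),
                              max_iter=8)
        a = fit_adles(case.ug, geom, ics, opt)
        b = fit_adles(case.ug, geom, ics, opt)
        assert np.array_equal(a.loss_history, b.loss_history)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            OptimizerConfig(max_iter=0)
        with pytest.raises(ConfigurationError):
            OptimizerConfig(step_rule="newton")
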