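"""Tests of the 1-D vocal-tract wave solver and its discrete adjoint."""

import numpy as np
import pytest

from vfokit.exceptions import ConfigurationError, GridMismatchError
from vfokit.wave import (AcousticField, TimeReversedField, VTConfig,
                         VTProfile, pressure_to_velocity, propagate_forward,
                         propagate_time_reversed, transpose_forward,
                         update_profile, velocity_to_pressure)


class TestForward:
    def test_zero_data_zero_field(self):
        cfg = VTConfig(nx=40)
        field = propagate_forward(np.zeros(300), None, cfg)
        assert np.all(field.u == 0)

    def test_dalembert_before_first_reflection(self):
        """With f = 0 the interior matches u0(t - x/c) within 2% RMS."""
        nx = 400
        cfg = VTConfig(nx=nx, dt=0.9 * (17.5 / nx) / 35000.0)
        dt = cfg.dt_eff
        T = 2 * cfg.L / cfg.c
        t = np.arange(0.0, T, dt)
        om = 2 * np.pi * 2000.0
        u0 = np.sin(om * t)
        field = propagate_forward(u0, None, cfg)
        x = np.linspace(0, cfg.L, nx + 1)
        worst = 0.0
        for i in range(20, nx, 40):
            mask = (t > x[i] / cfg.c) & (t < (2 * cfg.L - x[i]) / cfg.c)
            exact = np.sin(om * (t - x[i] / cfg.c))
            err = field.u[i][mask] - exact[mask]
            worst = max(worst, np.sqrt(np.mean(err ** 2))
                        / np.sqrt(np.mean(exact[mask] ** 2)))
        assert worst < 0.02

    def test_second_order_grid_convergence(self):
        """Refining dx and dt reduces the d'Alembert error by about 4x.

        A smooth (raised-cosine) onset keeps the travelling solution free of
        wavefront kinks that would otherwise degrade the observed order.
        """
        om = 2 * np.pi * 2000.0

        def max_err(nx):
            cfg = VTConfig(nx=nx, dt=0.8 * (17.5 / nx) / 35000.0)
            T = 1.5 * cfg.L / cfg.c
            t = np.arange(0.0, T, cfg.dt_eff)
            ramp_T = 0.3 * cfg.L / cfg.c

            def drive(tt):
                r = np.where(tt < ramp_T,
                             0.5 * (1 - np.cos(np.pi * np.clip(tt, 0, None)
                                               / ramp_T)), 1.0)
                return np.where(tt > 0, r * np.sin(om * tt), 0.0)

            field = propagate_forward(drive(t), None, cfg)
            i = nx // 2
            x_i = cfg.L / 2
            mask = (t > x_i / cfg.c + ramp_T) & (t < (2 * cfg.L - x_i) / cfg.c)
            err = field.u[i][mask] - drive(t - x_i / cfg.c)[mask]
            return np.sqrt(np.mean(err ** 2))

        ratio = max_err(100) / max_err(200)
        assert 2.5 < ratio < 6.0

    def test_affine_in_glottal_trace(self):
        cfg = VTConfig(nx=30)
        rng = np.random.default_rng(1)
        nt = 200
        f = VTProfile(rng.standard_normal((cfg.nx + 1, nt)))
        a = rng.standard_normal(nt)
        b = rng.standard_normal(nt)
        u_ab = propagate_forward(a + b, f, cfg).u
        u_a = propagate_forward(a, f, cfg).u
        u_b = propagate_forward(b, f, cfg).u
        u_0 = propagate_forward(np.zeros(nt), f, cfg).u
        np.testing.assert_allclose(u_ab, u_a + u_b - u_0, atol=1e-8)

    def test_stability_over_half_second(self):
        cfg = VTConfig(nx=50)  # Courant number 1
        nt = int(0.5 / cfg.dt_eff)
        t = cfg.dt_eff * np.arange(nt)
        field = propagate_forward(np.sin(2 * np.pi * 150 * t), None, cfg)
        assert np.max(np.abs(field.u)) < 100.0

    def test_cfl_violation_rejected(self):
        with pytest.raises(ConfigurationError):
            VTConfig(nx=50, dt=2 * (17.5 / 50) / 35000.0)

    def test_profile_shape_mismatch_rejected(self):
        cfg = VTConfig(nx=30)
        with pytest.raises(GridMismatchError):
            propagate_forward(np.zeros(100), VTProfile(np.zeros((10, 100))),
                              cfg)


class TestAdjoint:
    def test_dot_product_identity_glottal_trace(self):
        """<lip trace of forward(a), b> == <a, transpose(b)> to 1e-6."""
        cfg = VTConfig(nx=50)
        rng = np.random.default_rng(7)
        nt = 200
        a = rng.standard_normal(nt)
        b = rng.standard_normal(nt)
        lhs = propagate_forward(a, None, cfg).uL @ b
        dj_da, _ = transpose_forward(b, cfg)
        rhs = a @ dj_da
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_dot_product_identity_profile(self):
        cfg = VTConfig(nx=50)
        rng = np.random.default_rng(8)
        nt = 200
        f = rng.standard_normal((cfg.nx + 1, nt))
        b = rng.standard_normal(nt)
        lhs = propagate_forward(np.zeros(nt), VTProfile(f), cfg).uL @ b
        _, w_field = transpose_forward(b, cfg)
        rhs = np.sum(cfg.dt_eff ** 2 * w_field * f[1:, :])
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)


class TestTimeReversal:
    def test_zero_residual_zero_field(self):
        cfg = VTConfig(nx=40)
        z = propagate_time_reversed(np.zeros(300), None, cfg)
        assert np.all(z.z == 0)

    def test_terminal_conditions_exact_on_grid(self):
        cfg = VTConfig(nx=40)
        rng = np.random.default_rng(2)
        z = propagate_time_reversed(rng.standard_normal(300), None, cfg)
        assert np.all(z.z[:, -1] == 0)
        assert np.all(z.z[:, -2] == 0)  # discrete d/dt at t=T vanishes

    def test_residual_energy_reaches_glottis(self):
        cfg = VTConfig(nx=50)
        nt = 400
        r = np.zeros(nt)
        r[nt // 2] = 1.0
        z = propagate_time_reversed(r, None, cfg)
        assert np.max(np.abs(z.glottal_trace)) > 0


class TestProfileUpdate:
    def test_zero_increment_leaves_profile(self):
        cfg = VTConfig(nx=20)
        nt = 50
        f = VTProfile(np.ones((cfg.nx + 1, nt)))
        z = TimeReversedField(np.zeros((cfg.nx + 1, nt)), cfg.dt_eff, cfg.dx)
        u = AcousticField(np.zeros((cfg.nx + 1, nt)), cfg.dt_eff, cfg.dx)
        out = update_profile(f, z, u, iota=1.0, c=cfg.c)
        np.testing.assert_array_equal(out.f, f.f)

    def test_literal_combination_adds_field(self):
        cfg = VTConfig(nx=20)
        nt = 50
        f = VTProfile(np.zeros((cfg.nx + 1, nt)))
        z = TimeReversedField(np.full((cfg.nx + 1, nt), cfg.c ** 2),
                              cfg.dt_eff, cfg.dx)
        u = AcousticField(np.full((cfg.nx + 1, nt), 2.0), cfg.dt_eff, cfg.dx)
        out = update_profile(f, z, u, iota=1.0, c=cfg.c,
                             combination="literal")
        np.testing.assert_allclose(out.f, 3.0)

    def test_gradient_step_decreases_lip_misfit(self):
        """One exact-gradient profile step strictly reduces the misfit."""
        cfg = VTConfig(nx=30)
        nt = 400
        t = cfg.dt_eff * np.arange(nt)
        x = np.linspace(0, cfg.L, cfg.nx + 1)[:, None]
        truth = VTProfile(1e8 * np.sin(0.5 * np.pi * x / cfg.L)
                          * np.sin(2 * np.pi * 400 * t[None, :]))
        u0 = 1000 * np.sin(2 * np.pi * 200 * t)
        um = propagate_forward(u0, truth, cfg).uL

        f = VTProfile.zeros(cfg.nx, nt)
        field = propagate_forward(u0, f, cfg)
        R = field.uL - um
        loss0 = np.trapezoid(R ** 2, t)
        # descent direction from the exact transpose
        w = np.empty_like(t)
        w[1:-1] = 0.5 * (t[2:] - t[:-2])
        w[0] = w[-1] = 0.5 * (t[1] - t[0])
        _, wf = transpose_forward(2 * R * w, cfg)
        grad = np.zeros_like(f.f)
        grad[1:, :] = cfg.dt_eff ** 2 * wf
        gmax = np.abs(grad).max()
        f1 = VTProfile(f.f - (1e6 / gmax) * grad)
        R1 = propagate_forward(u0, f1, cfg).uL - um
        loss1 = np.trapezoid(R1 ** 2, t)
        assert loss1 < loss0


class TestPressureVelocity:
    def test_zero_maps_to_zero_and_linearity(self):
        cfg = VTConfig()
        assert np.all(pressure_to_velocity(np.zeros(5), cfg) == 0)
        p = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(pressure_to_velocity(2 * p, cfg),
                                   2 * pressure_to_velocity(p, cfg))

    def test_default_gain_value(self):
        # A_L/(rho c) = 2 / (0.00114 * 35000) ~= 0.05013
        cfg = VTConfig()
        gain = pressure_to_velocity(np.ones(1), cfg)[0]
        assert gain == pytest.approx(2.0 / (0.00114 * 35000.0), rel=1e-12)
        assert gain == pytest.approx(0.05013, rel=1e-3)

    def test_roundtrip(self):
        cfg = VTConfig()
        p = np.linspace(-1, 1, 11)
        np.testing.assert_allclose(
            velocity_to_pressure(pressure_to_velocity(p, cfg), cfg), p,
            rtol=1e-12)


class TestSerialization:
    def test_h5_roundtrip_preserves_field_and_grid(self, tmp_path):
        from vfokit.wave import load_field_h5, save_field_h5
        cfg = VTConfig(nx=20)
        nt = 60
        t = cfg.dt_eff * np.arange(nt)
        field = propagate_forward(np.sin(2 * np.pi * 300 * t), None, cfg)
        path = tmp_path / "field.h5"
        save_field_h5(path, field, cfg)
        back, meta = load_field_h5(path)
        np.testing.assert_array_equal(back.u, field.u)
        assert meta["dt"] == cfg.dt_eff and meta["L"] == cfg.L

    def test_h5_roundtrip_profile(self, tmp_path):
        from vfokit.wave import load_field_h5, save_field_h5
        cfg = VTConfig(nx=10)
        rng = np.random.default_rng(0)
        prof = VTProfile(rng.standard_normal((cfg.nx + 1, 30)))
        path = tmp_path / "prof.h5"
        save_field_h5(path, prof, cfg)
        back, _ = load_field_h5(path)
        np.testing.assert_array_equal(back.f, prof.f)
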