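"""ADLES-VFT: joint estimation of fold parameters and the tract profile.

The forward model chains the fold oscillator (model time) with 1-D acoustic
propagation through the vocal tract (physical time): the glottal flow
u0(t) = c~ d (2 xi0 + xi_l + xi_r) drives the wave equation and the lip
trace uL(t) is matched to the measured lip volume velocity um(t) (obtained
from the recorded pressure by um = A_L/(rho c) pm, with both sequences
normalized to zero mean and unit variance to absorb the unknown
transmission gain).  The building blocks of each iteration are

  1. fold ODE solve and forward wave propagation        (forward pass)
  2. a profile update along the time-reversed/adjoint
     field of the lip residual                          (f step)
  3. backprojection of the residual to the glottis,
     adjoint fold ODE solve, parameter gradients and a
     descent update of (alpha, beta, Delta)             (parameter step)

Because the unconstrained space-time profile can reproduce any lip trace by
itself, :func:`fit_adles_vft` schedules these blocks in two phases
(parameters first, then alternation) -- see its docstring.

The residual backprojection realizes the sensitivity of the lip trace to
the glottal trace as the exact transpose of the discrete wave solve, so the
parameter gradients satisfy the same adjoint structure as the glottal-side
estimator, with forcing 2 c~ d Rg in place of 2 c~ d R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adles import (AdjointTrajectory, GradientTriple, OptimizerConfig,
                    _normalize_weighted, _trapz_mean, solve_adjoint_glottal,
                    vfo_gradients)
from .exceptions import (GridMismatchError, IntegrationFailureError,
                         InvalidStateError)
from .model import (FoldGeometry, GlottalFlow, TimeScale,
                    VFOInitialConditions, VFOParams, VFOTrajectory,
                    glottal_flow, simulate_vfo)
from .wave import (AcousticField, VTConfig, VTProfile, propagate_forward,
                   propagate_time_reversed, transpose_forward, update_profile)

__all__ = [
    "LipResidual",
    "BackprojectedResidual",
    "JointFitResult",
    "lip_residual",
    "backproject_residual",
    "solve_adjoint_lip",
    "fit_adles_vft",
]


@dataclass
class LipResidual:
    """Residual at the lips: r = um - uL (drives the f update) and
    R = uL - um (enters the loss and the parameter adjoint); r == -R."""

    t: np.ndarray
    r: np.ndarray
    R: np.ndarray
    loss: float


@dataclass
class BackprojectedResidual:
    """Residual sensitivity mapped to the glottis (per unit physical time)."""

    t: np.ndarray
    Rg: np.ndarray


@dataclass
class JointFitResult:
    params: VFOParams
    profile: VTProfile
    loss_history: np.ndarray
    final_uL: np.ndarray
    final_u0: np.ndarray
    converged: bool
    n_iter: int
    param_history: np.ndarray | None = None


def _lip_residual_and_forcing(uL, um, t, normalize=True):
    """Residual R = uL - um, loss, and effective residual for the adjoint.

    With normalization, the effective residual carries the exact adjoint of
    the zero-mean unit-variance map applied to the model trace uL (the
    measured trace is a constant in the optimization).
    """
    if uL.size != um.size:
        raise GridMismatchError("uL and um must share a grid")
    if normalize:
        n_uL, _, s = _normalize_weighted(uL, t)
        n_um, _, _ = _normalize_weighted(um, t)
        R = n_uL - n_um
        loss = float(np.trapezoid(R ** 2, t))
        r_hat = (R - _trapz_mean(R, t) - n_uL * _trapz_mean(R * n_uL, t)) / s
    else:
        R = uL - um
        loss = float(np.trapezoid(R ** 2, t))
        r_hat = R
    return R, loss, r_hat


def lip_residual(uL, um, dt: float, normalize: bool = True) -> LipResidual:
    """Lip-plane residual between predicted and measured volume velocity."""
    uL = np.asarray(uL, dtype=float)
    um = np.asarray(um, dtype=float)
    t = dt * np.arange(uL.size)
    R, loss, _ = _lip_residual_and_forcing(uL, um, t, normalize=normalize)
    return LipResidual(t, -R, R, loss)


def backproject_residual(R, profile, cfg: VTConfig) -> BackprojectedResidual:
    """Map a lip residual to its sensitivity at the glottis.

    Uses the exact transpose of the discrete forward propagation (the wave
    operator is affine in the glottal trace, so the profile does not enter),
    returning a per-unit-time density: if J = int R(t) uL(t) dt then
    dJ/du0(t) = Rg(t) in the same density sense.
    """
    R = np.asarray(R, dtype=float)
    nt = R.size
    t = cfg.dt_eff * np.arange(nt)
    w = _trapz_weights(t)
    dj_da, _ = transpose_forward(R * w, cfg)
    return BackprojectedResidual(t, dj_da / w)


def _trapz_weights(t):
    w = np.empty_like(t)
    w[1:-1] = 0.5 * (t[2:] - t[:-2])
    w[0] = 0.5 * (t[1] - t[0])
    w[-1] = 0.5 * (t[-1] - t[-2])
    return w


def solve_adjoint_lip(traj: VFOTrajectory,
                      params: VFOParams,
                      Rg: BackprojectedResidual,
                      geom: FoldGeometry | None = None,
                      timescale: TimeScale | None = None,
                      mode: str = "euler_lagrange") -> AdjointTrajectory:
    """Adjoint fold ODEs forced by the backprojected lip residual.

    ``Rg`` is a density per unit physical time; the adjoint runs in model
    time, so the forcing is rescaled by dt_phys/dt_model = 1/(2 pi f0).
    Terminal conditions at t = T are zero, as on the glottal side.
    """
    if timescale is None:
        timescale = traj.timescale
    rg_model = Rg.Rg / (2.0 * np.pi * timescale.f0)
    if rg_model.size != traj.t.size:
        raise GridMismatchError("backprojected residual must be on the "
                                "trajectory grid")
    return solve_adjoint_glottal(traj, params, rg_model, geom, mode=mode)


def _forward_joint(params, ics, geom, cfg, profile, timescale, nt):
    """Fold ODE + wave propagation; returns (traj, u0, field)."""
    t_phys = cfg.dt_eff * np.arange(nt)
    t_model = timescale.to_model(t_phys)
    traj = simulate_vfo(params, ics, t_eval=t_model, timescale=timescale)
    u0 = glottal_flow(traj, geom)
    field = propagate_forward(u0.u0, profile, cfg)
    return traj, u0, field


def vft_loss_and_gradient(params: VFOParams,
                          um: np.ndarray,
                          geom: FoldGeometry,
                          ics: VFOInitialConditions,
                          cfg: VTConfig,
                          profile: VTProfile,
                          timescale: TimeScale,
                          normalize: bool = True,
                          mode: str = "euler_lagrange"):
    """One forward+adjoint sweep of the joint model.

    Returns (loss, GradientTriple, traj, u0, field, r_hat_lip).
    """
    nt = um.size
    traj, u0, field = _forward_joint(params, ics, geom, cfg, profile,
                                     timescale, nt)
    t_phys = cfg.dt_eff * np.arange(nt)
    _, loss, r_hat = _lip_residual_and_forcing(field.uL, um, t_phys,
                                               normalize=normalize)
    rg = backproject_residual(r_hat, profile, cfg)
    adj = solve_adjoint_lip(traj, params, rg, geom, timescale, mode=mode)
    grad = vfo_gradients(traj, adj)
    return loss, grad, traj, u0, field, r_hat


def _profile_gradient_step(cur_uL, profile, cfg, t_phys, r_hat, iota,
                           normalize):
    """One profile update along the exact loss gradient in f.

    The lip trace is affine in f, so along the descent direction d = -grad
    the raw quadratic loss is minimized at the closed-form step
    s* = -<r_hat, d_uL> / ||d_uL||^2 (trapezoid-weighted inner products,
    d_uL the lip response to d); ``iota`` scales this exact line-search
    step.  For the normalized loss the curvature term uses the response in
    normalized units, which is exact up to the slowly varying scale factor.
    """
    w = _trapz_weights(t_phys)
    _, wf = transpose_forward(2.0 * r_hat * w, cfg)
    grad = np.zeros_like(profile.f)
    grad[1:, :] = cfg.dt_eff ** 2 * wf
    d = -grad
    if not np.any(d):
        return profile
    d_uL = propagate_forward(np.zeros(t_phys.size), VTProfile(d), cfg).uL
    if normalize:
        m = _trapz_mean(cur_uL, t_phys)
        s_uL = np.sqrt(_trapz_mean((cur_uL - m) ** 2, t_phys))
        d_eff = d_uL / s_uL
    else:
        d_eff = d_uL
    denom = np.sum(w * d_eff * d_eff)
    if denom <= 0:
        return profile
    s = -iota * np.sum(w * r_hat * d_uL) / denom
    return VTProfile(profile.f + s * d)


def fit_adles_vft(um: np.ndarray,
                  geom: FoldGeometry | None = None,
                  ics: VFOInitialConditions | None = None,
                  cfg: VTConfig | None = None,
                  opt: OptimizerConfig | None = None,
                  timescale: TimeScale | None = None,
                  iota: float = 1.0,
                  f_iters: int = 100,
                  f_step: str = "gradient",
                  normalize: bool = True,
                  update_f: bool = True) -> JointFitResult:
    """Jointly estimate (alpha, beta, Delta) and f(x, t) from a lip trace.

    ``um`` is the measured lip volume velocity sampled at ``cfg.dt_eff``
    (convert recorded pressure with :func:`vfokit.wave.pressure_to_velocity`
    first, or rely on normalization to absorb the gain).  The profile starts
    at f = 0 (the Webster-horn tract).

    The full space-time profile can reproduce any lip trace on its own, so
    updating it from the first iteration lets it absorb the parameter
    mismatch and destroys identifiability.  The fit therefore runs in two
    phases: ``opt.max_iter`` parameter-only descent iterations against the
    current (initially rigid) tract, followed by ``f_iters`` alternating
    iterations, each one profile update then one parameter update (the
    algorithm's in-iteration order).  The best-loss iterate is returned.
    """
    if geom is None:
        geom = FoldGeometry()
    if ics is None:
        ics = VFOInitialConditions()
    if cfg is None:
        cfg = VTConfig()
    if opt is None:
        opt = OptimizerConfig()
    if timescale is None:
        timescale = TimeScale()
    um = np.asarray(um, dtype=float)
    if um.ndim != 1 or um.size < 8:
        raise InvalidStateError("um must be a 1-D series")
    nt = um.size
    t_phys = cfg.dt_eff * np.arange(nt)
    if not update_f:
        f_iters = 0

    params = opt.init_params
    profile = VTProfile.zeros(cfg.nx, nt)
    losses: list[float] = []
    phist: list[np.ndarray] = []
    best = None
    flat = 0
    step_scale = opt.step_scale
    accepts = 0
    prev = None  # (loss, params, grad) of the last accepted parameter iterate

    f_phase = False
    f_done = 0
    it = 0
    while True:
        try:
            traj, u0, field = _forward_joint(params, ics, geom, cfg, profile,
                                             timescale, nt)
        except IntegrationFailureError as err:
            if best is None:
                raise IntegrationFailureError("all iterations diverged",
                                              history=np.array(losses)) from err
            break
        _, loss, r_hat = _lip_residual_and_forcing(field.uL, um, t_phys,
                                                   normalize=normalize)
        losses.append(loss)
        phist.append(params.as_array())
        if best is None or loss < best[0]:
            best = (loss, params, profile, field.uL.copy(), u0.u0.copy())

        if loss < 1e-14:
            return JointFitResult(best[1], best[2], np.array(losses), best[3],
                                  best[4], True, it, np.array(phist))
        plateaued = False
        if len(losses) >= 2:
            rel = abs(losses[-1] - losses[-2]) / max(abs(losses[-2]), 1e-30)
            flat = flat + 1 if rel < opt.loss_tol else 0
            plateaued = flat >= 3
        if not f_phase:
            if plateaued or it >= opt.max_iter:
                if f_iters == 0:
                    return JointFitResult(best[1], best[2], np.array(losses),
                                          best[3], best[4], plateaued, it,
                                          np.array(phist))
                f_phase = True  # parameter phase done; start profile updates
                flat = 0
        else:
            if plateaued or f_done >= f_iters:
                return JointFitResult(best[1], best[2], np.array(losses),
                                      best[3], best[4], plateaued or
                                      f_done >= f_iters, it, np.array(phist))

        # f step first, then the parameter step (algorithm order)
        if f_phase:
            if f_step == "gradient":
                trial = _profile_gradient_step(field.uL, profile, cfg, t_phys,
                                               r_hat, iota, normalize)
            elif f_step == "time_reversal":
                # literal route: time-reverse r = um - uL and add z/c^2
                z = propagate_time_reversed(-r_hat, profile, cfg)
                trial = update_profile(profile, z, field, iota=iota, c=cfg.c)
            else:
                raise InvalidStateError(f"unknown f_step {f_step!r}")
            trial_field = propagate_forward(u0.u0, trial, cfg)
            _, trial_loss, trial_rhat = _lip_residual_and_forcing(
                trial_field.uL, um, t_phys, normalize=normalize)
            if trial_loss <= loss:  # accept only improving profile steps
                profile, field, r_hat = trial, trial_field, trial_rhat
                loss = trial_loss
                prev = None  # the parameter-loss baseline moved with f
            f_done += 1

        # parameter step
        rg = backproject_residual(r_hat, profile, cfg)
        adj = solve_adjoint_lip(traj, params, rg, geom, timescale)
        grad = vfo_gradients(traj, adj)
        gmax = grad.inf_norm()
        if gmax < opt.grad_tol:
            return JointFitResult(best[1], best[2], np.array(losses), best[3],
                                  best[4], True, it, np.array(phist))
        if prev is not None and loss > prev[0] \
                and step_scale > 1e-8 * opt.step_scale:
            # backtracking guard: retreat to the accepted iterate and retry
            # with half the step (profile updates are kept)
            step_scale *= 0.5
            accepts = 0
            loss, params, grad = prev
            gmax = grad.inf_norm()
        else:
            prev = (loss, params, grad)
            accepts += 1
            if accepts >= 8 and step_scale < opt.step_scale:
                step_scale = min(2.0 * step_scale, opt.step_scale)
                accepts = 0
        if opt.step_rule == "adaptive":
            tau = step_scale / gmax
        else:
            tau = step_scale
        new = params.as_array() - tau * grad.as_array()
        new[1] = max(new[1], 1e-3)
        params = VFOParams(*new)
        it += 1

    return JointFitResult(best[1], best[2], np.array(losses), best[3],
                          best[4], False, len(losses) - 1, np.array(phist))
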