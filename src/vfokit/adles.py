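"""ADLES: adjoint least-squares estimation of fold-oscillator parameters.

Given a reference glottal flow ug(t), the parameters (alpha, beta, Delta) of
the coupled fold oscillator are estimated by gradient descent on the squared
residual

    F(theta) = int_0^T (u0(t) - ug(t))^2 dt,

with the gradient obtained from an adjoint system integrated backward in time
from zero terminal conditions.  Stationarity of the Lagrangian with respect
to the fold displacements yields the adjoint equations

    lam'' - beta (1 + xi_r^2) lam' + alpha (lam' + eta') + (1 - Delta/2) lam
        + 2 c~ d R = 0
    eta'' - beta (1 + xi_l^2) eta' + alpha (lam' + eta') + (1 + Delta/2) eta
        + 2 c~ d R = 0

(the 2 beta xi xi' transport contributions cancel exactly when the first-order
terms are kept).  A "literal" mode without the first-order adjoint terms is
provided for comparison; gradient validity is adjudicated against central
finite differences of F, which the default mode satisfies.

The loss gradients are the quadratures

    F_alpha = int -(xi_r' + xi_l') (lam + eta) dt
    F_beta  = int (1 + xi_r^2) xi_r' lam + (1 + xi_l^2) xi_l' eta dt
    F_Delta = int (1/2) (xi_l eta - xi_r lam) dt

and the descent update is theta <- theta - tau * F_theta with the step tau
set adaptively to step_scale / max(|F_alpha|, |F_beta|, |F_Delta|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .exceptions import (ConfigurationError, GridMismatchError,
                         IntegrationFailureError, InvalidStateError)
from .model import (FoldGeometry, GlottalFlow, VFOInitialConditions,
                    VFOParams, VFOTrajectory, glottal_flow, simulate_vfo)

__all__ = [
    "AdjointTrajectory",
    "GradientTriple",
    "OptimizerConfig",
    "FitResult",
    "glottal_residual_loss",
    "solve_adjoint_glottal",
    "vfo_gradients",
    "fit_adles",
]

#: Default initialization of (alpha, beta, Delta) for the descent.
DEFAULT_INIT = (0.8, 0.32, 1.0)
#: Lower clip for beta during descent (avoids the degenerate undamped system).
BETA_FLOOR = 1e-3


@dataclass
class AdjointTrajectory:
    """Adjoint states lam(t), eta(t) with derivatives, on the forward grid.

    ``algebraic_residuals`` reports the pointwise values of the algebraic
    relations  beta (1 + xi^2) mult - alpha (lam + eta)  for each fold; they
    are diagnostics of the literal differential-algebraic transcription and
    are not enforced by the default adjoint mode.
    """

    t: np.ndarray
    lam: np.ndarray
    lam_dot: np.ndarray
    eta: np.ndarray
    eta_dot: np.ndarray
    algebraic_residuals: np.ndarray  # shape (2, n)


@dataclass
class GradientTriple:
    F_alpha: float
    F_beta: float
    F_delta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.F_alpha, self.F_beta, self.F_delta])

    def inf_norm(self) -> float:
        return float(np.max(np.abs(self.as_array())))


@dataclass
class OptimizerConfig:
    """Gradient-descent configuration.

    ``step_rule='adaptive'`` sets all three step sizes to
    ``step_scale / max(|F_alpha|, |F_beta|, |F_Delta|)`` each iteration
    (so the largest-gradient coordinate moves by ``step_scale``);
    ``'fixed'`` uses ``step_scale`` directly.
    """

    init_params: VFOParams = field(
        default_factory=lambda: VFOParams(*DEFAULT_INIT))
    step_rule: str = "adaptive"
    step_scale: float = 0.01
    max_iter: int = 200
    loss_tol: float = 1e-6
    grad_tol: float = 1e-12

    def __post_init__(self):
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.loss_tol <= 0 or self.grad_tol <= 0 or self.step_scale <= 0:
            raise ConfigurationError("tolerances and step_scale must be > 0")
        if self.step_rule not in ("adaptive", "fixed"):
            raise ConfigurationError(f"unknown step_rule {self.step_rule!r}")


@dataclass
class FitResult:
    params: VFOParams
    loss_history: np.ndarray
    final_trajectory: VFOTrajectory
    final_flow: GlottalFlow
    converged: bool
    n_iter: int
    param_history: np.ndarray | None = None


def _trapz_mean(y, t):
    return np.trapezoid(y, t) / (t[-1] - t[0])


def _normalize_weighted(y, t):
    """Zero-mean unit-variance normalization with trapezoid time weights.

    Returns (normalized, mean, std).  Weighted statistics keep the
    normalization consistent with the trapezoid quadrature used for the loss,
    so the adjoint gradient of the normalized loss is exact.
    """
    m = _trapz_mean(y, t)
    var = _trapz_mean((y - m) ** 2, t)
    s = np.sqrt(var)
    if s <= 0:
        raise InvalidStateError("cannot normalize a constant series")
    return (y - m) / s, m, s


def residual_and_forcing(u0: GlottalFlow, ug: GlottalFlow, normalize: bool = True):
    """Residual series, scalar loss and the adjoint forcing series.

    Returns ``(R, F, R_hat)`` where ``R`` is the (possibly normalized)
    pointwise residual, ``F = int R^2 dt`` by trapezoid quadrature and
    ``R_hat`` is the series such that the functional derivative of F with
    respect to the model flow is ``2 R_hat`` (for the raw loss
    ``R_hat == R``; for the normalized loss it carries the mean/variance
    adjoint corrections).
    """
    t = u0.t
    if u0.t.size != ug.t.size or not np.allclose(u0.t, ug.t):
        # resample reference onto the model grid
        if ug.t[0] > t[0] + 1e-12 or ug.t[-1] < t[-1] - 1e-12:
            raise GridMismatchError("reference flow does not cover the model grid")
        ug = GlottalFlow(t, np.interp(t, ug.t, ug.u0))
    if normalize:
        ny, _, s_y = _normalize_weighted(u0.u0, t)
        ng, _, _ = _normalize_weighted(ug.u0, t)
        R = ny - ng
        F = float(np.trapezoid(R ** 2, t))
        r_hat = (R - _trapz_mean(R, t) - ny * _trapz_mean(R * ny, t)) / s_y
    else:
        R = u0.u0 - ug.u0
        F = float(np.trapezoid(R ** 2, t))
        r_hat = R
    return R, F, r_hat


def glottal_residual_loss(u0: GlottalFlow, ug: GlottalFlow, normalize: bool = True):
    """Pointwise residual R(t) = u0 - ug (after optional normalization) and
    the scalar loss F = int R^2 dt."""
    R, F, _ = residual_and_forcing(u0, ug, normalize=normalize)
    return R, F


def solve_adjoint_glottal(traj: VFOTrajectory,
                          params: VFOParams,
                          R: np.ndarray,
                          geom: FoldGeometry | None = None,
                          mode: str = "euler_lagrange",
                          rtol: float = 1e-8,
                          atol: float = 1e-10) -> AdjointTrajectory:
    """Integrate the adjoint system backward from zero terminal conditions.

    ``R`` is the forcing series on the trajectory grid (the residual, or the
    effective residual of a normalized loss).  ``mode='euler_lagrange'``
    integrates the exact stationarity conditions of the Lagrangian;
    ``mode='literal'`` drops the first-order adjoint terms, reproducing the
    transcription in which the algebraic relations are assumed to hold.
    """
    if geom is None:
        geom = FoldGeometry()
    if mode not in ("euler_lagrange", "literal"):
        raise ConfigurationError(f"unknown adjoint mode {mode!r}")
    t = traj.t
    R = np.asarray(R, dtype=float)
    if R.size != t.size:
        raise GridMismatchError("forcing series must be on the trajectory grid")

    a, b, d = params.alpha, params.beta, params.delta
    cd2 = 2.0 * geom.c_tilde * geom.d
    T = t[-1]

    sp_xr = CubicSpline(t, traj.xi_r)
    sp_vr = CubicSpline(t, traj.v_r)
    sp_xl = CubicSpline(t, traj.xi_l)
    sp_vl = CubicSpline(t, traj.v_l)
    sp_R = CubicSpline(t, R)

    if mode == "euler_lagrange":
        def rhs(tau, y):
            # tau = T - t; d/dtau = -d/dt applied twice leaves the second-order
            # form invariant but flips the sign of first-order terms.
            s = T - tau
            lam, lam_p, eta, eta_p = y  # primes are d/dtau
            xr, xl = sp_xr(s), sp_xl(s)
            f = cd2 * sp_R(s)
            # in t: lam'' = b(1+xr^2) lam_t - a(lam_t+eta_t) - (1-d/2) lam - f
            # with lam_t = -lam_p:
            lam_pp = -b * (1 + xr * xr) * lam_p + a * (lam_p + eta_p) \
                - (1 - 0.5 * d) * lam - f
            eta_pp = -b * (1 + xl * xl) * eta_p + a * (lam_p + eta_p) \
                - (1 + 0.5 * d) * eta - f
            return (lam_p, lam_pp, eta_p, eta_pp)
    else:
        def rhs(tau, y):
            s = T - tau
            lam, lam_p, eta, eta_p = y
            xr, vr = sp_xr(s), sp_vr(s)
            xl, vl = sp_xl(s), sp_vl(s)
            f = cd2 * sp_R(s)
            lam_pp = -(2 * b * xr * vr + 1 - 0.5 * d) * lam - f
            eta_pp = -(2 * b * xl * vl + 1 + 0.5 * d) * eta - f
            return (lam_p, lam_pp, eta_p, eta_pp)

    tau_eval = T - t[::-1]
    sol = solve_ivp(rhs, (0.0, T), np.zeros(4), method="RK45",
                    t_eval=tau_eval, rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationFailureError(
            f"adjoint integration failed: {sol.message}",
            last_valid_time=(T - sol.t[-1]) if sol.t.size else None)

    lam = sol.y[0][::-1]
    lam_dot = -sol.y[1][::-1]  # convert d/dtau back to d/dt
    eta = sol.y[2][::-1]
    eta_dot = -sol.y[3][::-1]

    alg = np.vstack([
        b * (1 + traj.xi_r ** 2) * lam - a * (lam + eta),
        b * (1 + traj.xi_l ** 2) * eta - a * (lam + eta),
    ])
    return AdjointTrajectory(t, lam, lam_dot, eta, eta_dot, alg)


def vfo_gradients(traj: VFOTrajectory, adj: AdjointTrajectory) -> GradientTriple:
    """Loss gradients (F_alpha, F_beta, F_Delta) by trapezoid quadrature."""
    if traj.t.size != adj.t.size or not np.allclose(traj.t, adj.t):
        raise GridMismatchError("trajectory and adjoint must share a grid")
    t = traj.t
    lam, eta = adj.lam, adj.eta
    f_alpha = np.trapezoid(-(traj.v_r + traj.v_l) * (lam + eta), t)
    f_beta = np.trapezoid((1 + traj.xi_r ** 2) * traj.v_r * lam
                          + (1 + traj.xi_l ** 2) * traj.v_l * eta, t)
    f_delta = np.trapezoid(0.5 * (traj.xi_l * eta - traj.xi_r * lam), t)
    return GradientTriple(float(f_alpha), float(f_beta), float(f_delta))


def adles_loss_and_gradient(params: VFOParams,
                            ug: GlottalFlow,
                            geom: FoldGeometry,
                            ics: VFOInitialConditions,
                            normalize: bool = True,
                            mode: str = "euler_lagrange",
                            adjoint_rtol: float = 1e-8):
    """One forward+adjoint sweep: returns (loss, GradientTriple, traj, flow)."""
    traj = simulate_vfo(params, ics, t_eval=ug.t)
    u0 = glottal_flow(traj, geom)
    _, F, r_hat = residual_and_forcing(u0, ug, normalize=normalize)
    adj = solve_adjoint_glottal(traj, params, r_hat, geom, mode=mode,
                                rtol=adjoint_rtol, atol=adjoint_rtol * 1e-2)
    grad = vfo_gradients(traj, adj)
    return F, grad, traj, u0


def fit_adles(ug: GlottalFlow,
              geom: FoldGeometry | None = None,
              ics: VFOInitialConditions | None = None,
              opt: OptimizerConfig | None = None,
              normalize: bool = True,
              adjoint_mode: str = "euler_lagrange",
              adjoint_rtol: float = 1e-8) -> FitResult:
    """Estimate (alpha, beta, Delta) from a reference glottal flow.

    Iterates simulate -> adjoint -> gradients -> descent update until the
    relative loss change stays below ``loss_tol`` for 3 iterations, the
    gradient norm falls below ``grad_tol``, or ``max_iter`` is reached.
    Returns the best-loss iterate.
    """
    if geom is None:
        geom = FoldGeometry()
    if ics is None:
        ics = VFOInitialConditions()
    if opt is None:
        opt = OptimizerConfig()
    if len(ug) < 2:
        raise InvalidStateError("reference flow is empty or too short")

    params = opt.init_params
    losses: list[float] = []
    phist: list[np.ndarray] = []
    best = None
    flat_count = 0
    step_scale = opt.step_scale
    accepts = 0
    prev = None  # (loss, params, grad) of the last accepted iterate

    for it in range(opt.max_iter + 1):
        try:
            F, grad, traj, u0 = adles_loss_and_gradient(
                params, ug, geom, ics, normalize=normalize,
                mode=adjoint_mode, adjoint_rtol=adjoint_rtol)
        except IntegrationFailureError as err:
            if best is None:
                raise IntegrationFailureError(
                    "all iterations diverged", history=np.array(losses)) from err
            break
        losses.append(F)
        phist.append(params.as_array())
        if best is None or F < best[0]:
            best = (F, params, traj, u0)

        gmax = grad.inf_norm()
        if F < 1e-14 or gmax < opt.grad_tol:
            return FitResult(best[1], np.array(losses), best[2], best[3],
                             True, it, np.array(phist))
        if len(losses) >= 2:
            denom = max(abs(losses[-2]), 1e-30)
            rel = abs(losses[-1] - losses[-2]) / denom
            flat_count = flat_count + 1 if rel < opt.loss_tol else 0
            if flat_count >= 3:
                return FitResult(best[1], np.array(losses), best[2], best[3],
                                 True, it, np.array(phist))
        if it == opt.max_iter:
            break

        if prev is not None and F > prev[0] and step_scale > 1e-8 * opt.step_scale:
            # backtracking guard: the last step overshot -- retreat to the
            # accepted iterate and retry with half the step
            step_scale *= 0.5
            accepts = 0
            F, params, grad = prev
            gmax = grad.inf_norm()
        else:
            prev = (F, params, grad)
            accepts += 1
            if accepts >= 8 and step_scale < opt.step_scale:
                step_scale = min(2.0 * step_scale, opt.step_scale)
                accepts = 0
        if opt.step_rule == "adaptive":
            tau = step_scale / gmax
        else:
            tau = step_scale
        new = params.as_array() - tau * grad.as_array()
        new[1] = max(new[1], BETA_FLOOR)
        params = VFOParams(*new)

    return FitResult(best[1], np.array(losses), best[2], best[3],
                     False, len(losses) - 1, np.array(phist))
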