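"""Asymmetric one-mass vocal-fold oscillator.

The left and right vocal folds are modelled as a pair of coupled Van der Pol
oscillators in dimensionless form:

    xi_r'' + beta (1 + xi_r^2) xi_r' + xi_r - (Delta/2) xi_r = alpha (xi_r' + xi_l')
    xi_l'' + beta (1 + xi_l^2) xi_l' + xi_l + (Delta/2) xi_l = alpha (xi_r' + xi_l')

where ``beta`` lumps mass, spring and damping coefficients, ``alpha`` is the
glottal pressure coupling coefficient, and ``Delta`` detunes the restoring
forces of the two folds (the asymmetry coefficient).  For a normal adult male
voice the reference values are alpha = 0.5, beta = 0.32, Delta = 0.

The glottal volume velocity follows from the glottal opening as

    u0(t) = c~ * d * (2 xi0 + xi_l(t) + xi_r(t))

with ``xi0`` the half glottal width at rest, ``d`` the fold length and ``c~``
the mid-fold air particle velocity, all in cgs units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import ConfigurationError, IntegrationFailureError, InvalidStateError

__all__ = [
    "VFOParams",
    "VFOInitialConditions",
    "FoldGeometry",
    "TimeScale",
    "VFOTrajectory",
    "GlottalFlow",
    "vdp_rhs",
    "vdp_jacobian",
    "simulate_vfo",
    "glottal_flow",
]

#: Reference parameter values for a normal adult male voice.
NORMAL_ALPHA = 0.5
NORMAL_BETA = 0.32
NORMAL_DELTA = 0.0

#: Small symmetric perturbation used to leave the (unstable) rest equilibrium.
DEFAULT_IC = (0.01, 0.0, 0.01, 0.0)


@dataclass(frozen=True)
class VFOParams:
    """The estimable parameter triple (alpha, beta, Delta).

    ``delta >= 0`` is the sign convention for reporting: negating ``delta``
    and swapping the folds yields the mirrored system, so negative values are
    accepted (the optimizer may pass through them) but canonical results use
    the non-negative representative.
    """

    alpha: float
    beta: float
    delta: float

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.delta)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidStateError(f"non-finite VFO parameters: {vals}")
        if self.beta <= 0:
            raise InvalidStateError(f"beta must be > 0 (got {self.beta})")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.delta], dtype=float)


@dataclass(frozen=True)
class VFOInitialConditions:
    """Initial fold displacements (quiescent positions) and velocities."""

    xi_r0: float = DEFAULT_IC[0]
    v_r0: float = 0.0
    xi_l0: float = DEFAULT_IC[2]
    v_l0: float = 0.0

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise InvalidStateError(f"non-finite initial conditions: {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.xi_r0, self.v_r0, self.xi_l0, self.v_l0], dtype=float)

    def swapped(self) -> "VFOInitialConditions":
        """Swap left and right fold initial data."""
        return VFOInitialConditions(self.xi_l0, self.v_l0, self.xi_r0, self.v_r0)


@dataclass(frozen=True)
class FoldGeometry:
    """Glottal geometry constants (cgs units).

    Defaults are the standard values: half glottal width at rest
    xi0 = 0.1 cm, fold length d = 1.75 cm (17.5 mm) and mid-fold air particle
    velocity c~ = 5000 cm/s.
    """

    xi0: float = 0.1
    d: float = 1.75
    c_tilde: float = 5000.0

    def __post_init__(self):
        if not (self.xi0 > 0 and self.d > 0 and self.c_tilde > 0):
            raise InvalidStateError("fold geometry values must all be > 0")


@dataclass(frozen=True)
class TimeScale:
    """Mapping between dimensionless model time and physical seconds.

    The oscillator's natural angular frequency is ~1 in model units, so one
    oscillation cycle spans about 2*pi model-time units.  We identify the
    cycle with the fundamental period 1/f0, giving

        t_phys = t_model / (2 * pi * f0).

    ``mode`` records whether f0 was fixed a priori or estimated from audio.
    """

    f0: float = 150.0
    mode: str = "fixed"

    def __post_init__(self):
        if not (self.f0 > 0):
            raise InvalidStateError(f"f0 must be > 0 (got {self.f0})")
        if self.mode not in ("fixed", "estimated-from-audio"):
            raise ConfigurationError(f"unknown TimeScale mode {self.mode!r}")

    def to_seconds(self, t_model):
        return np.asarray(t_model) / (2.0 * np.pi * self.f0)

    def to_model(self, t_phys):
        return np.asarray(t_phys) * (2.0 * np.pi * self.f0)


@dataclass
class VFOTrajectory:
    """Time series of fold displacements and velocities in model time."""

    t: np.ndarray
    xi_r: np.ndarray
    v_r: np.ndarray
    xi_l: np.ndarray
    v_l: np.ndarray
    timescale: TimeScale = field(default_factory=TimeScale)

    def __post_init__(self):
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.t, self.xi_r, self.v_r, self.xi_l, self.v_l)]
        n = arrays[0].size
        if any(a.size != n for a in arrays):
            raise InvalidStateError("trajectory arrays must have equal length")
        if n >= 2 and not np.all(np.diff(arrays[0]) > 0):
            raise InvalidStateError("trajectory time grid must be strictly increasing")
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise InvalidStateError("trajectory contains non-finite values")
        self.t, self.xi_r, self.v_r, self.xi_l, self.v_l = arrays

    def __len__(self):
        return self.t.size

    def state_matrix(self) -> np.ndarray:
        """Return the (n, 4) state array in (xi_r, v_r, xi_l, v_l) order."""
        return np.column_stack([self.xi_r, self.v_r, self.xi_l, self.v_l])

    def swapped(self) -> "VFOTrajectory":
        return VFOTrajectory(self.t, self.xi_l, self.v_l, self.xi_r, self.v_r,
                             self.timescale)


@dataclass
class GlottalFlow:
    """Glottal volume velocity u0(t) (cm^3/s) on a model-time grid."""

    t: np.ndarray
    u0: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.u0 = np.asarray(self.u0, dtype=float)
        if self.t.size != self.u0.size:
            raise InvalidStateError("GlottalFlow t and u0 must have equal length")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.u0))):
            raise InvalidStateError("GlottalFlow contains non-finite values")

    def __len__(self):
        return self.t.size


def vdp_rhs(state, params: VFOParams) -> np.ndarray:
    """Time derivative of the coupled-oscillator state.

    Parameters
    ----------
    state : array-like, shape (4,) or (4, n)
        ``(xi_r, v_r, xi_l, v_l)``.
    params : VFOParams

    Returns
    -------
    ndarray with the same shape: ``(v_r, a_r, v_l, a_l)`` where

        a_r = -beta (1 + xi_r^2) v_r - xi_r + (Delta/2) xi_r + alpha (v_r + v_l)
        a_l = -beta (1 + xi_l^2) v_l - xi_l - (Delta/2) xi_l + alpha (v_r + v_l)
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise InvalidStateError("non-finite state passed to vdp_rhs")
    xi_r, v_r, xi_l, v_l = state
    a, b, d = params.alpha, params.beta, params.delta
    drive = a * (v_r + v_l)
    acc_r = -b * (1.0 + xi_r ** 2) * v_r - xi_r + 0.5 * d * xi_r + drive
    acc_l = -b * (1.0 + xi_l ** 2) * v_l - xi_l - 0.5 * d * xi_l + drive
    return np.array([v_r, acc_r, v_l, acc_l])


def vdp_jacobian(state, params: VFOParams) -> np.ndarray:
    """Jacobian of :func:`vdp_rhs` with respect to the state (4x4)."""
    xi_r, v_r, xi_l, v_l = np.asarray(state, dtype=float)
    a, b, d = params.alpha, params.beta, params.delta
    return np.array([
        [0.0, 1.0, 0.0, 0.0],
        [-2.0 * b * xi_r * v_r - 1.0 + 0.5 * d, -b * (1.0 + xi_r ** 2) + a, 0.0, a],
        [0.0, 0.0, 0.0, 1.0],
        [0.0, a, -2.0 * b * xi_l * v_l - 1.0 - 0.5 * d, -b * (1.0 + xi_l ** 2) + a],
    ])


def _rhs_for_solver(t, y, a, b, d):
    xi_r, v_r, xi_l, v_l = y
    drive = a * (v_r + v_l)
    return (
        v_r,
        -b * (1.0 + xi_r * xi_r) * v_r - xi_r + 0.5 * d * xi_r + drive,
        v_l,
        -b * (1.0 + xi_l * xi_l) * v_l - xi_l - 0.5 * d * xi_l + drive,
    )


def simulate_vfo(params: VFOParams,
                 ics: VFOInitialConditions | None = None,
                 duration: float = 200.0,
                 dt: float = 0.02,
                 timescale: TimeScale | None = None,
                 rtol: float = 1e-8,
                 atol: float = 1e-10,
                 method: str = "RK45",
                 t_eval: np.ndarray | None = None) -> VFOTrajectory:
    """Integrate the coupled fold oscillator on a uniform model-time grid.

    Uses an adaptive explicit Runge-Kutta scheme with dense output sampled on
    the requested grid; the system is non-stiff in the regimes of interest.

    Raises
    ------
    IntegrationFailureError
        If the solver diverges; carries the last valid time reached.
    """
    if ics is None:
        ics = VFOInitialConditions()
    if timescale is None:
        timescale = TimeScale()
    if t_eval is None:
        if duration <= 0 or dt <= 0:
            raise ConfigurationError("duration and dt must be > 0")
        n = int(round(duration / dt))
        t_eval = np.linspace(0.0, n * dt, n + 1)
    else:
        t_eval = np.asarray(t_eval, dtype=float)

    sol = solve_ivp(
        _rhs_for_solver, (t_eval[0], t_eval[-1]), ics.as_array(),
        method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        args=(params.alpha, params.beta, params.delta),
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        last = sol.t[-1] if sol.t.size else None
        raise IntegrationFailureError(
            f"VFO integration failed: {sol.message}", last_valid_time=last)
    xi_r, v_r, xi_l, v_l = sol.y
    return VFOTrajectory(sol.t, xi_r, v_r, xi_l, v_l, timescale)


def glottal_flow(traj: VFOTrajectory, geom: FoldGeometry | None = None) -> GlottalFlow:
    """Glottal volume velocity u0 = c~ d (2 xi0 + xi_l + xi_r) from a trajectory."""
    if geom is None:
        geom = FoldGeometry()
    if len(traj) == 0:
        raise InvalidStateError("empty trajectory")
    u0 = geom.c_tilde * geom.d * (2.0 * geom.xi0 + traj.xi_l + traj.xi_r)
    return GlottalFlow(traj.t, u0)
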