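"""1-D acoustic wave propagation through the vocal tract.

The tract is a tube of length L with axial coordinate x in [0, L] (glottis at
x = 0, lips at x = L).  The volume velocity u(x, t) obeys

    u_tt = c^2 u_xx + f(x, t)

where f(x, t) is the vocal-tract source profile absorbing wall yielding,
coupling and radiation effects; with f = 0 the equation is the (uniform-area)
Webster horn equation.  The forward problem carries a Dirichlet condition
u(0, t) = u0(t) at the glottis, a zero-normal-derivative condition at the lip
(open-end, reflection-free approximation; an absorbing Sommerfeld option is
available), and zero initial conditions.

Discretization: second-order central finite differences in space with
leapfrog time stepping at Courant number C = c dt / dx <= 1 (at C = 1 the
interior scheme is exact for the homogeneous equation).

``transpose_forward`` is the exact algebraic transpose of the discrete
forward map from (glottal trace, profile) to the lip trace; it is what makes
residual backprojection satisfy the discrete adjoint identity to machine
precision, which joint parameter/profile estimation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (ConfigurationError, GridMismatchError,
                         IntegrationFailureError)

__all__ = [
    "VTConfig",
    "VTProfile",
    "AcousticField",
    "TimeReversedField",
    "propagate_forward",
    "propagate_time_reversed",
    "transpose_forward",
    "update_profile",
    "pressure_to_velocity",
    "velocity_to_pressure",
    "save_field_h5",
    "load_field_h5",
]


@dataclass(frozen=True)
class VTConfig:
    """Vocal-tract solver configuration (cgs units).

    Defaults are standard adult-male values: L = 17.5 cm, c = 35000 cm/s,
    rho = 0.00114 g/cm^3, lip opening area A_L = 2 cm^2.  If ``dt`` is None
    the step is set to dx / c (Courant number 1).
    """

    L: float = 17.5
    c: float = 35000.0
    rho: float = 0.00114
    A_L: float = 2.0
    nx: int = 50
    dt: float | None = None
    lip_bc: str = "neumann_zero"

    def __post_init__(self):
        if not (self.L > 0 and self.c > 0 and self.rho > 0 and self.A_L > 0):
            raise ConfigurationError("L, c, rho, A_L must all be > 0")
        if self.nx < 2:
            raise ConfigurationError("nx must be >= 2")
        if self.lip_bc not in ("neumann_zero", "absorbing"):
            raise ConfigurationError(f"unknown lip_bc {self.lip_bc!r}")
        if self.courant > 1.0 + 1e-12:
            raise ConfigurationError(
                f"CFL violation: c*dt/dx = {self.courant:.4f} > 1")

    @property
    def dx(self) -> float:
        return self.L / self.nx

    @property
    def dt_eff(self) -> float:
        return self.dx / self.c if self.dt is None else self.dt

    @property
    def courant(self) -> float:
        return self.c * self.dt_eff / self.dx


@dataclass
class VTProfile:
    """Source profile f(x, t) on the solver grid, shape (nx+1, nt)."""

    f: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2:
            raise ConfigurationError("profile must be a 2-D (nx+1, nt) array")
        if not np.all(np.isfinite(self.f)):
            raise ConfigurationError("profile contains non-finite values")

    @classmethod
    def zeros(cls, nx: int, nt: int) -> "VTProfile":
        return cls(np.zeros((nx + 1, nt)))

    @property
    def shape(self):
        return self.f.shape


@dataclass
class AcousticField:
    """Forward solution u(x, t), shape (nx+1, nt); row 0 is the glottis."""

    u: np.ndarray
    dt: float
    dx: float

    @property
    def uL(self) -> np.ndarray:
        """Lip trace u(L, t)."""
        return self.u[-1]

    @property
    def u0(self) -> np.ndarray:
        """Glottal trace u(0, t)."""
        return self.u[0]


@dataclass
class TimeReversedField:
    """Time-reversed solution z(x, t) with zero conditions at t = T."""

    z: np.ndarray
    dt: float
    dx: float

    @property
    def glottal_trace(self) -> np.ndarray:
        return self.z[0]


def _profile_array(profile, nx, nt):
    if profile is None:
        return None
    f = profile.f if isinstance(profile, VTProfile) else np.asarray(profile, float)
    if f.shape != (nx + 1, nt):
        raise GridMismatchError(
            f"profile shape {f.shape} does not match grid {(nx + 1, nt)}")
    return f


def _apply_A(u, C2, lip_neumann):
    """Apply the interior update matrix A to the unknown nodes 1..nx."""
    out = np.empty_like(u)
    out[:-1] = (2 - 2 * C2) * u[:-1]
    out[1:-1] += C2 * (u[2:] + u[:-2])
    out[0] += C2 * u[1]
    if lip_neumann:
        out[-1] = (2 - 2 * C2) * u[-1] + 2 * C2 * u[-2]
    else:  # placeholder; absorbing lip handled outside the recursion
        out[-1] = (2 - 2 * C2) * u[-1] + 2 * C2 * u[-2]
    return out


def _apply_AT(w, C2):
    """Apply A^T (Neumann-lip A) to an adjoint vector over nodes 1..nx."""
    out = np.empty_like(w)
    out[:-1] = (2 - 2 * C2) * w[:-1]
    out[1:-1] += C2 * (w[2:] + w[:-2])
    out[0] += C2 * w[1]
    out[-2] += C2 * w[-1]  # A[nx, nx-1] = 2C^2 -> transpose adds the extra C2
    out[-1] = (2 - 2 * C2) * w[-1] + C2 * w[-2]
    return out


def propagate_forward(u0, profile, cfg: VTConfig) -> AcousticField:
    """Solve the forward wave problem driven by the glottal trace ``u0``.

    ``u0`` is sampled at ``cfg.dt_eff``; the returned field has the glottal
    trace as row 0 (enforced Dirichlet data) and the lip trace as the last
    row.
    """
    a = np.asarray(u0, dtype=float)
    if a.ndim != 1 or a.size < 3:
        raise ConfigurationError("u0 must be a 1-D series of length >= 3")
    nt = a.size
    nx = cfg.nx
    C2 = cfg.courant ** 2
    dt2 = cfg.dt_eff ** 2
    f = _profile_array(profile, nx, nt)

    u = np.zeros((nx + 1, nt))
    u[0] = a

    def source(n):
        s = np.zeros(nx)
        s[0] = C2 * a[n]
        if f is not None:
            s += dt2 * f[1:, n]
        return s

    u[1:, 1] = 0.5 * source(0)
    prev = u[1:, 0].copy()
    cur = u[1:, 1].copy()
    absorbing = cfg.lip_bc == "absorbing"
    Cn = cfg.courant
    for n in range(1, nt - 1):
        nxt = _apply_A(cur, C2, lip_neumann=True) - prev + source(n)
        if absorbing:
            # first-order upwind outflow at the lip
            nxt[-1] = cur[-1] - Cn * (cur[-1] - cur[-2])
            if f is not None:
                nxt[-1] += dt2 * f[-1, n]
        prev, cur = cur, nxt
        u[1:, n + 1] = cur
    if not np.all(np.isfinite(u)):
        raise IntegrationFailureError("forward wave solve became non-finite")
    return AcousticField(u, cfg.dt_eff, cfg.dx)


def transpose_forward(R, cfg: VTConfig):
    """Exact transpose of the discrete forward map.

    Given weights ``R`` applied to the lip trace (J = sum_n R_n * uL_n),
    returns ``(dJ_da, w_field)`` where ``dJ_da`` is the gradient of J with
    respect to the glottal Dirichlet samples and ``w_field`` (shape
    (nx, nt)) holds the adjoint layers such that dJ/df[i, n] =
    dt^2 * w_field[i-1, n+1] (with the half weight at n = 0 already folded
    in).  Machine-precision adjoint of :func:`propagate_forward` for the
    Neumann lip condition.
    """
    if cfg.lip_bc != "neumann_zero":
        raise ConfigurationError(
            "exact transpose is implemented for lip_bc='neumann_zero' only")
    R = np.asarray(R, dtype=float)
    nt = R.size
    nx = cfg.nx
    C2 = cfg.courant ** 2

    # w^m = A^T w^{m+1} - w^{m+2} + R_m e_lip, m = nt-1 .. 1
    w = np.zeros((nx, nt + 2))  # columns m = 0..nt+1; 0 unused
    for m in range(nt - 1, 0, -1):
        w[:, m] = _apply_AT(w[:, m + 1], C2) - w[:, m + 2]
        w[-1, m] += R[m]

    dJ_da = np.zeros(nt)
    dJ_da[1:nt - 1] = C2 * w[0, 2:nt]
    dJ_da[0] = 0.5 * C2 * w[0, 1]

    # dJ/df[:, n] = dt^2 w^{n+1} for 1 <= n <= nt-2, 0.5 dt^2 w^1 at n = 0
    w_field = np.zeros((nx, nt))
    w_field[:, 1:nt - 1] = w[:, 2:nt]
    w_field[:, 0] = 0.5 * w[:, 1]
    return dJ_da, w_field


def propagate_time_reversed(r, profile, cfg: VTConfig) -> TimeReversedField:
    """Solve the time-reversed wave problem driven by a lip residual.

    The residual ``r(t)`` enters as Neumann data dz/dn = r at the lip; the
    glottal end carries a zero-Neumann (free-end) condition so the residual
    energy arriving at the glottis is visible in ``glottal_trace``.  Zero
    conditions hold at t = T exactly on the grid (the last two time layers of
    z vanish), and the equation is integrated backward in time.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size < 3:
        raise ConfigurationError("r must be a 1-D series of length >= 3")
    nt = r.size
    nx = cfg.nx
    C2 = cfg.courant ** 2
    dt2 = cfg.dt_eff ** 2
    dx = cfg.dx
    f = _profile_array(profile, nx, nt)

    r_rev = r[::-1]
    f_rev = f[:, ::-1] if f is not None else None

    # unknowns: all nodes 0..nx; free (Neumann) ends with ghost-node closure,
    # lip forced by the reversed residual.
    v = np.zeros((nx + 1, nt))
    prev = v[:, 0].copy()
    cur = v[:, 1].copy()  # zero: makes z(.,T)=0 and dz/dt(.,T)=0 exact
    for m in range(1, nt - 1):
        nxt = np.empty(nx + 1)
        nxt[1:-1] = (2 - 2 * C2) * cur[1:-1] + C2 * (cur[2:] + cur[:-2]) - prev[1:-1]
        nxt[0] = (2 - 2 * C2) * cur[0] + 2 * C2 * cur[1] - prev[0]
        nxt[-1] = (2 - 2 * C2) * cur[-1] + 2 * C2 * cur[-2] - prev[-1] \
            + 2 * C2 * dx * r_rev[m]
        if f_rev is not None:
            nxt += dt2 * f_rev[:, m]
        prev, cur = cur, nxt
        v[:, m + 1] = cur
    if not np.all(np.isfinite(v)):
        raise IntegrationFailureError("time-reversed wave solve became non-finite")
    z = v[:, ::-1].copy()
    return TimeReversedField(z, cfg.dt_eff, cfg.dx)


def update_profile(f: VTProfile, z: TimeReversedField, u: AcousticField,
                   iota: float = 1.0, c: float = 35000.0,
                   combination: str = "gradient") -> VTProfile:
    """Profile update f <- f + iota * increment.

    ``combination='gradient'`` (default) uses the backprojected-field
    direction z / c^2, which is proportional to the negative loss gradient
    and yields a descent step for small iota.  ``'literal'`` adds the forward
    field as well: z / c^2 + u.
    """
    if combination not in ("gradient", "literal"):
        raise ConfigurationError(f"unknown combination {combination!r}")
    if f.f.shape != z.z.shape:
        raise GridMismatchError("profile and reversed field shapes differ")
    inc = z.z / c ** 2
    if combination == "literal":
        if u.u.shape != f.f.shape:
            raise GridMismatchError("profile and field shapes differ")
        inc = inc + u.u
    return VTProfile(f.f + iota * inc)


def pressure_to_velocity(p, cfg: VTConfig) -> np.ndarray:
    """Convert lip pressure (dyn/cm^2) to volume velocity: u = A_L/(rho c) p."""
    return (cfg.A_L / (cfg.rho * cfg.c)) * np.asarray(p, dtype=float)


def velocity_to_pressure(u, cfg: VTConfig) -> np.ndarray:
    """Inverse of :func:`pressure_to_velocity`."""
    return (cfg.rho * cfg.c / cfg.A_L) * np.asarray(u, dtype=float)


def save_field_h5(path, obj, cfg: VTConfig, name: str = "data") -> None:
    """Store a field/profile array with its grid metadata in HDF5.

    Accepts an :class:`AcousticField`, :class:`TimeReversedField` or
    :class:`VTProfile`; the dataset carries dt, dx, L and c as attributes so
    a saved array can be re-aligned to a solver grid on load.
    """
    import h5py

    if isinstance(obj, AcousticField):
        arr, kind = obj.u, "acoustic_field"
    elif isinstance(obj, TimeReversedField):
        arr, kind = obj.z, "time_reversed_field"
    elif isinstance(obj, VTProfile):
        arr, kind = obj.f, "profile"
    else:
        raise ConfigurationError(f"cannot serialize {type(obj).__name__}")
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(name, data=arr)
        ds.attrs["kind"] = kind
        ds.attrs["dt"] = cfg.dt_eff
        ds.attrs["dx"] = cfg.dx
        ds.attrs["L"] = cfg.L
        ds.attrs["c"] = cfg.c


def load_field_h5(path, name: str = "data"):
    """Load an array saved by :func:`save_field_h5`.

    Returns ``(object, metadata)`` where the object type follows the stored
    kind and metadata is a dict of the grid attributes.
    """
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh[name]
        arr = ds[()]
        meta = {k: ds.attrs[k] for k in ("dt", "dx", "L", "c")}
        kind = ds.attrs["kind"]
    if kind == "acoustic_field":
        return AcousticField(arr, float(meta["dt"]), float(meta["dx"])), meta
    if kind == "time_reversed_field":
        return TimeReversedField(arr, float(meta["dt"]),
                                 float(meta["dx"])), meta
    return VTProfile(arr), meta
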