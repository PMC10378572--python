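"""Dynamical-systems characterization of fold-oscillator solutions.

The steady orbit of the coupled fold oscillator is probed on the Poincare
section xi' = 0 of a chosen fold: crossing values of the displacement are
clustered to count the orbit's period (1 cluster = simple limit cycle,
2 = period-doubled orbit, many = torus), the ratio of right- to left-fold
crossing counts over a common window gives the n:m entrainment, and scans
over (alpha, Delta) produce a bifurcation map.  Largest-Lyapunov and Hurst
exponents supply additional features for pathology discrimination, and a
rule-based classifier maps parameter/behavior combinations to the voice
pathology regimes associated with regions of the bifurcation diagram:

    Delta < 0.5, alpha > 0.25, period 1          -> Normal
    Delta ~ 0.6, alpha ~ 0.35, period 1          -> Neoplasm
    Delta ~ 0.6, alpha ~ 0.3, period 2           -> Phonotrauma
    Delta ~ 0.85, alpha ~ 0.4, toroidal orbit    -> Vocal palsy

("~" means within a configurable tolerance, default 0.05.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (ConfigurationError, DegenerateSignalError,
                         IntegrationFailureError, UndefinedRatioError)
from .model import (VFOInitialConditions, VFOParams, VFOTrajectory,
                    simulate_vfo, vdp_jacobian, vdp_rhs)

__all__ = [
    "PoincareConfig",
    "CrossingSet",
    "EntrainmentRatio",
    "PathologyLabel",
    "DynamicsSummary",
    "BifurcationGrid",
    "poincare_crossings",
    "entrainment_ratio",
    "summarize_dynamics",
    "characterize",
    "bifurcation_scan",
    "largest_lyapunov",
    "largest_lyapunov_vfo",
    "hurst_exponent",
    "classify_regime",
]

#: Default simulation length (model-time units) for steady-state analysis.
DEFAULT_DURATION = 2000.0
DEFAULT_DT = 0.02


class PathologyLabel(Enum):
    NORMAL = "Normal"
    NEOPLASM = "Neoplasm"
    PHONOTRAUMA = "Phonotrauma"
    VOCAL_PALSY = "VocalPalsy"
    UNKNOWN = "Unknown"


@dataclass(frozen=True)
class PoincareConfig:
    """Section and clustering settings for crossing analysis.

    The section is the zero-velocity surface of one fold; ``pos_to_neg``
    crossings pick out displacement maxima.  ``cluster_tol`` is relative to
    the steady oscillation amplitude; more than ``torus_cluster_cap``
    distinct clusters declares a torus (quasi-periodic orbit).
    """

    fold: str = "r"
    direction: str = "pos_to_neg"
    transient_fraction: float = 0.75
    cluster_tol: float = 1e-2
    torus_cluster_cap: int = 12
    amplitude_floor: float = 1e-3

    def __post_init__(self):
        if not (0 <= self.transient_fraction < 1):
            raise ConfigurationError("transient_fraction must be in [0, 1)")
        if self.cluster_tol <= 0:
            raise ConfigurationError("cluster_tol must be > 0")
        if self.fold not in ("r", "l"):
            raise ConfigurationError("fold must be 'r' or 'l'")
        if self.direction not in ("pos_to_neg", "neg_to_pos"):
            raise ConfigurationError("direction must be pos_to_neg or neg_to_pos")


@dataclass
class CrossingSet:
    """Section crossings: times, displacement values, cluster count.

    ``oscillatory`` is False when the post-transient segment has no
    crossings or its amplitude is below the detection floor.
    """

    times: np.ndarray
    values: np.ndarray
    n_clusters: int
    amplitude: float
    oscillatory: bool


@dataclass(frozen=True)
class EntrainmentRatio:
    """Reduced n:m locking ratio of right to left crossing counts."""

    n: int
    m: int

    def __post_init__(self):
        if self.n <= 0 or self.m <= 0:
            raise ConfigurationError("entrainment integers must be positive")
        if math.gcd(self.n, self.m) != 1:
            raise ConfigurationError("entrainment ratio must be in lowest terms")

    @property
    def value(self) -> float:
        return self.n / self.m

    def swapped(self) -> "EntrainmentRatio":
        return EntrainmentRatio(self.m, self.n)

    def __str__(self):
        return f"{self.n}:{self.m}"


@dataclass
class DynamicsSummary:
    period_count_r: int
    period_count_l: int
    entrainment: EntrainmentRatio | None
    torus: bool
    oscillatory: bool
    lyap1: float | None = None
    hurst: float | None = None
    label: PathologyLabel = PathologyLabel.UNKNOWN


@dataclass
class BifurcationGrid:
    alpha_axis: np.ndarray
    delta_axis: np.ndarray
    beta: float
    ratio: np.ndarray        # n/m as float, NaN where undefined/failed
    torus: np.ndarray        # bool grid
    period_count: np.ndarray  # right-fold cluster counts

    def __post_init__(self):
        shape = (len(self.delta_axis), len(self.alpha_axis))
        for g in (self.ratio, self.torus, self.period_count):
            if g.shape != shape:
                raise ConfigurationError("bifurcation grids must be (n_delta, n_alpha)")


def _post_transient(traj: VFOTrajectory, cfg: PoincareConfig):
    n0 = int(cfg.transient_fraction * len(traj))
    xi = traj.xi_r if cfg.fold == "r" else traj.xi_l
    v = traj.v_r if cfg.fold == "r" else traj.v_l
    return traj.t[n0:], xi[n0:], v[n0:]


def _section_crossings(t, xi, v, direction):
    """Sub-sample crossing times/values by linear interpolation of v."""
    s = v if direction == "pos_to_neg" else -v
    sign = np.sign(s)
    idx = np.where((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    if idx.size == 0:
        return np.array([]), np.array([])
    denom = s[idx] - s[idx + 1]
    frac = np.where(denom != 0, s[idx] / np.where(denom == 0, 1.0, denom), 0.0)
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    values = xi[idx] + frac * (xi[idx + 1] - xi[idx])
    return times, values


def _cluster_count(values, amplitude, tol):
    if values.size == 0:
        return 0
    sv = np.sort(values)
    return 1 + int(np.sum(np.diff(sv) > tol * amplitude))


def poincare_crossings(traj: VFOTrajectory,
                       cfg: PoincareConfig | None = None) -> CrossingSet:
    """Section crossings of the chosen fold, with value clustering.

    Crossing times and displacement values are located to sub-sample accuracy
    by linear interpolation of the velocity sign change; values within
    ``cluster_tol`` x amplitude of each other (single-linkage on the sorted
    values) form one cluster.
    """
    if cfg is None:
        cfg = PoincareConfig()
    t, xi, v = _post_transient(traj, cfg)
    if t.size < 2:
        return CrossingSet(np.array([]), np.array([]), 0, 0.0, False)
    amplitude = 0.5 * (xi.max() - xi.min())
    times, values = _section_crossings(t, xi, v, cfg.direction)
    oscillatory = times.size > 0 and amplitude > cfg.amplitude_floor
    if not oscillatory:
        return CrossingSet(times, values, 0, float(amplitude), False)
    n_clusters = _cluster_count(values, amplitude, cfg.cluster_tol)
    return CrossingSet(times, values, n_clusters, float(amplitude), True)


def entrainment_ratio(traj: VFOTrajectory,
                      cfg: PoincareConfig | None = None,
                      max_order: int = 12) -> EntrainmentRatio:
    """Reduced right:left crossing-count ratio over the steady window.

    Counts the section crossings of each fold over the same post-transient
    window, reduces the pair by their greatest common divisor, and snaps to
    the nearest low-order rational (denominator <= ``max_order``) when the
    raw counts differ from it by at most one crossing -- raw counts over a
    finite window can be off by one partial cycle.
    """
    if cfg is None:
        cfg = PoincareConfig()
    counts = {}
    for fold in ("r", "l"):
        sub = PoincareConfig(fold=fold, direction=cfg.direction,
                             transient_fraction=cfg.transient_fraction,
                             cluster_tol=cfg.cluster_tol,
                             torus_cluster_cap=cfg.torus_cluster_cap,
                             amplitude_floor=cfg.amplitude_floor)
        cs = poincare_crossings(traj, sub)
        if not cs.oscillatory:
            raise UndefinedRatioError(f"fold {fold!r} has no section crossings")
        counts[fold] = cs.times.size
    n_raw, m_raw = counts["r"], counts["l"]
    g = math.gcd(n_raw, m_raw)
    n, m = n_raw // g, m_raw // g
    if max(n, m) > max_order:
        snap = Fraction(n_raw, m_raw).limit_denominator(max_order)
        # accept the snap only if consistent with +/-1 crossing miscount
        if abs(snap.numerator * m_raw - snap.denominator * n_raw) <= max(
                snap.numerator, snap.denominator):
            n, m = snap.numerator, snap.denominator
    return EntrainmentRatio(n, m)


def phase_entrainment_check(traj: VFOTrajectory, ratio: EntrainmentRatio,
                            cfg: PoincareConfig | None = None,
                            C: float = np.pi) -> bool:
    """Optional phase-locking criterion |n*theta_r - m*theta_l| < C.

    Phases are linearly interpolated cycle counts (2*pi per section
    crossing); the criterion is evaluated over the post-transient window
    after removing the initial phase offset.
    """
    if cfg is None:
        cfg = PoincareConfig()
    phases = {}
    for fold in ("r", "l"):
        sub = PoincareConfig(fold=fold, direction=cfg.direction,
                             transient_fraction=cfg.transient_fraction)
        cs = poincare_crossings(traj, sub)
        if cs.times.size < 3:
            raise UndefinedRatioError("too few crossings for phase check")
        phases[fold] = cs.times
    t0 = max(phases["r"][0], phases["l"][0])
    t1 = min(phases["r"][-1], phases["l"][-1])
    grid = np.linspace(t0, t1, 200)
    th_r = np.interp(grid, phases["r"], 2 * np.pi * np.arange(phases["r"].size))
    th_l = np.interp(grid, phases["l"], 2 * np.pi * np.arange(phases["l"].size))
    drift = ratio.n * th_l - ratio.m * th_r  # n:m = right:left crossing counts
    drift = drift - drift[0]
    return bool(np.max(np.abs(drift)) < C)


def summarize_dynamics(traj: VFOTrajectory,
                       cfg: PoincareConfig | None = None,
                       params: VFOParams | None = None) -> DynamicsSummary:
    """Period counts, entrainment and torus flag for a steady trajectory."""
    if cfg is None:
        cfg = PoincareConfig()
    sets = {}
    for fold in ("r", "l"):
        sub = PoincareConfig(fold=fold, direction=cfg.direction,
                             transient_fraction=cfg.transient_fraction,
                             cluster_tol=cfg.cluster_tol,
                             torus_cluster_cap=cfg.torus_cluster_cap,
                             amplitude_floor=cfg.amplitude_floor)
        sets[fold] = poincare_crossings(traj, sub)
    oscillatory = sets["r"].oscillatory and sets["l"].oscillatory
    torus = oscillatory and (
        sets["r"].n_clusters > cfg.torus_cluster_cap
        or sets["l"].n_clusters > cfg.torus_cluster_cap)
    ent = None
    if oscillatory:
        try:
            ent = entrainment_ratio(traj, cfg)
        except UndefinedRatioError:
            ent = None
    summary = DynamicsSummary(sets["r"].n_clusters, sets["l"].n_clusters,
                              ent, torus, oscillatory)
    if params is not None:
        summary.label = classify_regime(params, summary)
    return summary


def characterize(params: VFOParams,
                 ics: VFOInitialConditions | None = None,
                 duration: float = DEFAULT_DURATION,
                 dt: float = DEFAULT_DT,
                 cfg: PoincareConfig | None = None,
                 with_lyapunov: bool = False,
                 with_hurst: bool = False) -> DynamicsSummary:
    """Simulate at ``params`` and summarize the steady-state dynamics."""
    traj = simulate_vfo(params, ics, duration=duration, dt=dt)
    summary = summarize_dynamics(traj, cfg, params=params)
    if with_lyapunov:
        summary.lyap1 = largest_lyapunov_vfo(params, ics, duration=min(duration, 1000.0))
    if with_hurst:
        n0 = int((cfg.transient_fraction if cfg else 0.75) * len(traj))
        summary.hurst = hurst_exponent(traj.xi_r[n0:])
    summary.label = classify_regime(params, summary)
    return summary


def bifurcation_scan(alpha_axis, delta_axis, beta: float = 0.32,
                     ics: VFOInitialConditions | None = None,
                     duration: float = DEFAULT_DURATION,
                     dt: float = DEFAULT_DT,
                     cfg: PoincareConfig | None = None) -> BifurcationGrid:
    """Entrainment/period map over an (alpha, Delta) grid at fixed beta.

    Integration failures at individual grid points are recorded as NaN
    ratios, not raised.
    """
    alpha_axis = np.asarray(alpha_axis, dtype=float)
    delta_axis = np.asarray(delta_axis, dtype=float)
    if alpha_axis.size == 0 or delta_axis.size == 0:
        raise ConfigurationError("bifurcation axes must be non-empty")
    shape = (delta_axis.size, alpha_axis.size)
    ratio = np.full(shape, np.nan)
    torus = np.zeros(shape, dtype=bool)
    period = np.zeros(shape, dtype=int)
    for i, de in enumerate(delta_axis):
        for j, al in enumerate(alpha_axis):
            try:
                traj = simulate_vfo(VFOParams(al, beta, de), ics,
                                    duration=duration, dt=dt)
                s = summarize_dynamics(traj, cfg)
            except IntegrationFailureError:
                continue
            period[i, j] = s.period_count_r
            torus[i, j] = s.torus
            if s.entrainment is not None:
                ratio[i, j] = s.entrainment.value
    return BifurcationGrid(alpha_axis, delta_axis, beta, ratio, torus, period)


def largest_lyapunov(rhs, jac, x0,
                     duration: float = 500.0,
                     dt: float = 0.5,
                     transient: float = 50.0,
                     rtol: float = 1e-9,
                     atol: float = 1e-11,
                     seed: int = 0) -> float:
    """Largest Lyapunov exponent by the Benettin tangent-space method.

    Integrates the flow together with one tangent vector propagated by the
    variational equation v' = J(x) v, renormalizing the vector every ``dt``
    time units and averaging the log stretch factors after an initial
    ``transient`` (which aligns the vector with the leading direction).

    ``rhs(x)`` and ``jac(x)`` evaluate the vector field and its Jacobian.
    """
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(dim)
    v /= np.linalg.norm(v)

    def aug(t, y):
        x, w = y[:dim], y[dim:]
        return np.concatenate([np.asarray(rhs(x)), np.asarray(jac(x)) @ w])

    logs = []
    times = []
    x = x0.copy()
    t = 0.0
    n_steps = int(round(duration / dt))
    for _ in range(n_steps):
        sol = solve_ivp(aug, (t, t + dt), np.concatenate([x, v]),
                        method="RK45", rtol=rtol, atol=atol)
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise IntegrationFailureError("Lyapunov integration diverged",
                                          last_valid_time=t)
        x = sol.y[:dim, -1]
        v = sol.y[dim:, -1]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise IntegrationFailureError("tangent vector collapsed to zero")
        t += dt
        if t > transient:
            logs.append(np.log(norm))
            times.append(dt)
        v /= norm
    return float(np.sum(logs) / np.sum(times))


def largest_lyapunov_vfo(params: VFOParams,
                         ics: VFOInitialConditions | None = None,
                         duration: float = 500.0,
                         **kwargs) -> float:
    """Largest Lyapunov exponent of the fold oscillator (per model-time unit)."""
    if ics is None:
        ics = VFOInitialConditions()
    return largest_lyapunov(
        lambda x: vdp_rhs(x, params),
        lambda x: vdp_jacobian(x, params),
        ics.as_array(), duration=duration, **kwargs)


def _expected_rs(n: int) -> float:
    """Anis-Lloyd-Peters expected value of R/S for i.i.d. data of length n."""
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        g = math.gamma(0.5 * (n - 1)) / (math.sqrt(math.pi) * math.gamma(0.5 * n))
        return (n - 0.5) / n * g * s
    return (n - 0.5) / n * s / math.sqrt(n * math.pi / 2)


def hurst_exponent(series, min_window: int = 32) -> float:
    """Hurst exponent by bias-corrected rescaled-range (R/S) analysis.

    The series is treated as an increment (noise) process; windows of dyadic
    sizes are scanned, the rescaled range R/S is averaged over disjoint
    windows of each size, and H is 0.5 plus the log-log slope of the
    deviation of R/S from its expected value under independence
    (Anis-Lloyd-Peters correction, which removes the small-sample bias of
    the classical estimator).
    """
    x = np.asarray(series, dtype=float)
    if x.size < min_window * 16:
        raise DegenerateSignalError("series too short for R/S analysis")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant series has undefined Hurst exponent")

    sizes = []
    w = min_window
    while w <= x.size // 4:
        sizes.append(w)
        w *= 2
    log_rs, log_exp, log_n = [], [], []
    for n in sizes:
        k = x.size // n
        segs = x[: k * n].reshape(k, n)
        means = segs.mean(axis=1, keepdims=True)
        z = np.cumsum(segs - means, axis=1)
        R = z.max(axis=1) - z.min(axis=1)
        S = segs.std(axis=1)
        ok = S > 0
        if not np.any(ok):
            continue
        rs = np.mean(R[ok] / S[ok])
        log_rs.append(np.log(rs))
        log_exp.append(np.log(_expected_rs(n)))
        log_n.append(np.log(n))
    if len(log_n) < 3:
        raise DegenerateSignalError("too few valid window sizes for R/S fit")
    slope = np.polyfit(log_n, np.asarray(log_rs) - np.asarray(log_exp), 1)[0]
    return float(0.5 + slope)


def classify_regime(params: VFOParams, summary: DynamicsSummary,
                    tol: float = 0.05) -> PathologyLabel:
    """Map (alpha, Delta) and phase-space behavior to a pathology regime.

    Rule order: toroidal palsy region first, then the narrow neoplasm /
    phonotrauma bands around Delta ~ 0.6, then the broad normal region
    Delta < 0.5, alpha > 0.25 with a simple limit cycle; anything else is
    Unknown.
    """
    a, d = params.alpha, abs(params.delta)
    period = summary.period_count_r

    def near(x, center):
        # strict band; rounding keeps exact band edges out despite binary
        # floating-point representation of the 0.05-spaced centers
        return abs(round(x - center, 9)) < tol

    if summary.torus and near(d, 0.85):
        return PathologyLabel.VOCAL_PALSY
    if near(d, 0.6) and near(a, 0.3) and period == 2:
        return PathologyLabel.PHONOTRAUMA
    if near(d, 0.6) and near(a, 0.35) and period == 1:
        return PathologyLabel.NEOPLASM
    if d < 0.5 and a > 0.25 and period == 1 and summary.oscillatory \
            and not summary.torus:
        return PathologyLabel.NORMAL
    return PathologyLabel.UNKNOWN
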