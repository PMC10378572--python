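# Methods

## The model

vfokit treats phonation as the interplay of two components.

**Fold oscillator.** The left and right vocal folds are one-mass body-cover
oscillators coupled through the glottal pressure, written in dimensionless
form as a pair of coupled Van der Pol equations

    xi_r'' + beta (1 + xi_r^2) xi_r' + xi_r - (Delta/2) xi_r = alpha (xi_r' + xi_l')
    xi_l'' + beta (1 + xi_l^2) xi_l' + xi_l + (Delta/2) xi_l = alpha (xi_r' + xi_l')

with three estimable parameters: `alpha`, the glottal pressure coupling;
`beta`, a lumped mass/spring/damping coefficient; and `Delta`, the left-right
asymmetry.  Reference values for a normal adult male voice are
(0.5, 0.32, 0).  The nonlinear damping enters as `beta (1 + xi^2) xi'`
(dissipative for all xi); energy input arrives only through the alpha
coupling.  We keep this form exactly as the model family defines it.  The
glottal volume velocity follows from the opening as
`u0 = c~ d (2 xi0 + xi_l + xi_r)` with cgs geometry defaults xi0 = 0.1 cm,
d = 1.75 cm, c~ = 5000 cm/s; the dimensionless displacements are used
directly as cm, matching the model family's mixing of dimensionless xi with
cgs constants.

**Vocal tract.** The tract is a 1-D tube of length L = 17.5 cm carrying a
volume-velocity wave `u_tt = c^2 u_xx + f(x, t)` with Dirichlet data
u(0, t) = u0(t) at the glottis and a zero-normal-derivative (open-end)
condition at the lip; f(x, t) is a distributed source profile absorbing
wall-yielding, coupling and radiation effects (f = 0 reduces to the
uniform-area Webster horn tube).  Defaults: c = 35000 cm/s,
rho = 0.00114 g/cm^3, lip area A_L = 2 cm^2.  Recorded lip pressure converts
to volume velocity by `um = A_L / (rho c) pm`.

**Time scales.** Model time is dimensionless with natural angular frequency
near 1, so one glottal cycle spans about 2 pi model units.  We map model
time to seconds by `t_phys = t_model / (2 pi f0)` with f0 = 150 Hz by
default, or estimated from audio by autocorrelation.  The model family
leaves this mapping unstated; some mapping is required whenever model output
is compared against sampled signals, and identifying the oscillator cycle
with the fundamental period is the natural choice.

## Estimation

**Glottal side (backward).**  Given a reference glottal flow ug(t), the
parameters minimize `F = int (u0 - ug)^2 dt` by gradient descent.  The
gradient comes from an adjoint system integrated backward in time from zero
terminal conditions.  Deriving the stationarity conditions of the Lagrangian
carefully yields

    lam'' - beta (1 + xi_r^2) lam' + alpha (lam' + eta') + (1 - Delta/2) lam + 2 c~ d R = 0

(and the mirrored eta equation): the `2 beta xi xi'` terms produced by
differentiating the damping cancel exactly against the transport term, but
the first-order `lam'` terms survive.  A "literal" mode that drops them (the
transcription in which the algebraic relations
`beta (1 + xi^2) lam = alpha (lam + eta)` are assumed) is available for
comparison; correctness is adjudicated by agreement with central finite
differences of F, which the default mode satisfies to ~1e-4 relative on
smooth synthetic cases (tested at 1e-3).

**Lip side (forward-backward).**  When only the recorded voice is available,
the model flow is propagated through the tract and the loss is the lip-plane
misfit between uL and um.  The sensitivity of the lip trace to the glottal
trace is realized by backprojection: the exact algebraic transpose of the
discrete forward wave recursion, which satisfies the discrete adjoint
dot-product identity to machine precision.  The backprojected residual then
forces the same adjoint fold ODEs (rescaled by 1/(2 pi f0) for the change of
time variable), and the parameter gradients keep their closed quadrature
forms.  End-to-end gradients agree with finite differences through both
solvers to ~1e-6 relative on a 50-cell grid (tested at 5e-3).

**Normalization.** Both residuals optionally normalize the traces to zero
mean and unit variance before differencing, absorbing unknown gains and
transmission loss.  The normalization is folded into the adjoint exactly:
the effective residual carries the mean/variance correction terms, computed
with trapezoid time weights so that the discrete loss and its gradient are
mutually consistent.  For calibrated synthetic references (known units) the
raw, unnormalized loss is better conditioned -- amplitude then carries
information about beta -- and the recovery studies use it.

**Descent rule.**  All three parameters share the adaptive step
`0.01 / max(|F_alpha|, |F_beta|, |F_Delta|)` (the largest-gradient
coordinate moves 0.01 per iteration).  A fixed scale oscillates once the
iterate reaches the valley floor, so the step scale is halved whenever a
step increases the loss (the iterate retreats to the last accepted point)
and regrown after eight consecutive accepted steps, capped at the initial
scale.  This is still plain gradient descent; it just makes the prescribed
rule robust near the optimum.  Stopping: relative loss change below 1e-6
over three iterations, a vanishing gradient, or the iteration cap; the
best-loss iterate is returned.  beta is clipped below at 1e-3 to avoid the
undamped degenerate system.

**Joint schedule and identifiability.**  The space-time profile f(x, t) has
(nx+1) x nt degrees of freedom and its lip response spans the whole trace
space: f alone can reproduce any measured signal.  Alternating f updates
with parameter updates from the first iteration therefore lets f absorb the
parameter-error residual and the parameters converge to wrong values
(measured on inverse-crime cases).  The joint fit instead runs two phases:
a parameter-only descent against the current (initially rigid) tract, then
a bounded alternating phase in which each outer iteration performs one
profile update followed by one parameter update.  The f update uses the
exact gradient direction with a closed-form line search (the lip response
is affine in f, so the 1-D minimizer is analytic; iota scales this exact
step, default 1); the literal time-reversal update `f <- f + iota z / c^2`,
with z the time-reversed field driven by the lip residual, is available as
`f_step="time_reversal"`.  The printed combination including `+ u` is kept
in `update_profile(combination="literal")` but is not a descent direction
in general, so the gradient form is the default.

Even with the phased schedule, what the f phase recovers is the component
of the true profile visible in the residual at that point.  When the
parameters are known to a percent or so, the residual is dominated by the
profile's own lip signature and inverse-crime recovery reaches correlation
~0.97 with the true field; from a distant initialization the parameter
error still dominates the residual floor, and the recovered field fits that
error signature instead (correlation near zero) even though the parameters
themselves and the glottal flow are recovered well.  This is an honest
identifiability limit of the full space-time profile, not a solver defect,
and is why the profile-recovery test conditions on near-truth parameters.

## Wave solver numerics

Second-order central differences in space, leapfrog in time, Courant number
c dt/dx <= 1 (default exactly 1, where the interior scheme is exact for the
homogeneous equation).  The Dirichlet glottal sample enters the first
interior node's update; the Neumann lip condition uses the ghost-node
closure (doubled inner coupling).  The first time step uses the half-step
Taylor start consistent with zero initial data.  The time-reversed solve
mirrors this scheme backward with Neumann residual injection
(2 C^2 dx r) at the lip, a free (zero-Neumann) glottal end so the
backpropagated residual is visible at the glottis, and two zero terminal
layers so that both terminal conditions hold exactly on the grid.
Backprojection does not reuse this physical solve: it applies the exact
transpose of the forward recursion, which is what the gradient identities
require.  The absorbing (Sommerfeld) lip option uses a first-order upwind
outflow; the exact transpose is implemented for the default Neumann lip
only, so gradient-based fitting requires that setting.

On a travelling-wave test the solver matches the d'Alembert solution to
0.8% RMS at nx = 400 before the first reflection; observed convergence on a
smooth-onset pulse is ~3.3x error reduction per grid doubling (kinked
wavefronts degrade the formal second order, as expected for non-smooth
data).

## Dynamics characterization

Steady orbits are probed on the Poincare section xi' = 0 of one fold:
positive-to-negative velocity crossings (displacement maxima) located by
linear interpolation of the velocity sign change.  Defaults: 2000
model-time units, the first 75% discarded as transient, crossing values
clustered by single-linkage with relative tolerance 1e-2 of the steady
amplitude, and more than 12 clusters declaring a torus.  The cluster count
is the period count ("number of limit cycles" in the phase-portrait sense);
the reduced ratio of right to left crossing counts over the same window is
the n:m entrainment, snapped to a low-order rational only when within one
crossing of the raw counts.  An optional phase-locking check
|n theta_r - m theta_l| < C (C = pi) is provided.  Amplitudes below 1e-3
are flagged non-oscillatory rather than clustered.

The largest Lyapunov exponent uses the Benettin tangent-space method (one
tangent vector propagated by the variational equation, renormalized every
0.5 time units, log stretch factors averaged after a transient).  The Hurst
exponent uses rescaled-range analysis over dyadic windows (minimum 32)
with the Anis-Lloyd-Peters small-sample correction; the estimator is
applied to increment-like series (white noise ~0.52, fractional Gaussian
noise with H = 0.7 ~0.64-0.69, a monotone ramp ~0.96 on the test sizes).

**Regime classification.**  Rule-based mapping from (alpha, Delta) and
phase-space behavior to pathology regions of the bifurcation diagram, with
"~" meaning within +/-0.05 (configurable): toroidal orbits near
Delta ~ 0.85 -> vocal palsy; Delta ~ 0.6, alpha ~ 0.3, period 2 ->
phonotrauma; Delta ~ 0.6, alpha ~ 0.35, period 1 -> neoplasm;
Delta < 0.5, alpha > 0.25 with a simple limit cycle -> normal; otherwise
unknown.  beta is fixed at 0.32 for regime verification since the
classification table does not state it.

**A dynamics caveat found during verification.**  At the phonotrauma table
point (alpha = 0.3, beta = 0.32, Delta = 0.6) the rest state of the
oscillator as printed is linearly stable (largest eigenvalue real part
-8e-4): trajectories decay and no period-2 orbit exists there.  A scan of
the (alpha, Delta) plane at beta = 0.32 finds period-doubled orbits only
near Delta ~ 0.8, alpha ~ 0.42-0.44, with tori above.  The package reports
what the model actually does: the period count measured at that point is 1
(a decaying spiral's crossings cluster together), and the synthetic-case
generator flags the regime as non-oscillatory.  Plausible sources of the
discrepancy: the "2 limit cycles" label may describe the two folds tracing
visibly distinct cycles in the left-right coupling portrait for estimated
(not tabulated) parameters, or a beta other than 0.32.

## Synthetic data

The generator fixes ground truth (parameters, initial conditions, geometry,
f0 = 150 Hz, optional tract profile) and produces the resulting signals
with seeded Gaussian noise.  Glottal cases: 50 model-time units (~8 cycles)
at dt = 0.02, noise relative to the flow's AC amplitude (noise_sd = 0.01 is
40 dB SNR).  Speech cases: 20 ms of lip signal on the wave grid
(nx = 50, dt = dx/c = 10 us), profile
`A sin(pi x / 2L) sin(2 pi 300 t)` with A = 5e8 -- a separable smooth field
growing toward the lip so it is observable in the lip trace, scaled so its
lip signature is a sub-percent perturbation of the rigid-tube response
(wall and radiation corrections are perturbative).  Initial conditions
default to (0.01, 0, 0.01, 0): the quiescent positions C_r = C_l = 0 with
zero velocities are an exact equilibrium of the oscillator, so a small
symmetric displacement is used to reach the limit cycle; a strict mode with
exactly zero initial data would never leave rest.

What the generator does not emulate: jitter/shimmer and aspiration noise of
real phonation, room and microphone coloration, clinical recording conditions,
fold collision (the model assumes no glottal closure), and time-varying
tract area.  Passing recovery tests on these cases demonstrates correctness
of the estimation machinery under the model's own assumptions (the
inverse-crime setting), not clinical performance on real voices.

## Problem sizes and budgets

Recovery studies use 30 model-time units (1501 samples) for glottal fits
and 20 ms (2001 samples, nx = 50) for lip fits; these sizes keep each
estimator's descent (several hundred iterations) to a few minutes while
leaving gradient checks at ~1e-6 accuracy.  The dynamics battery integrates
2000 model units per parameter point.  All defaults are package choices
made once for these studies.

## Known limitations

* The full space-time profile is not identifiable jointly with the
  parameters from a single lip trace (see above); a parametrized or
  time-constant profile would trade expressiveness for identifiability.
* The adaptive-step gradient descent is first-order; hundreds of iterations
  are typical.  Curvature methods would converge faster but the descent rule
  is kept deliberately simple.
* The inverse-filter utility is a standard IAIF recipe (LPC order
  fs/1000 + 2, two refinement passes, pre-emphasis 0.97) and is a utility,
  not a contribution; exact reproduction of any particular published
  inverse-filter output is out of scope.
* R/S Hurst estimation carries a known downward bias for strongly
  persistent series even after the small-sample correction.
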