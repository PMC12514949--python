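# Methods

## The model

`vfadesign` works with a two-pool hybrid dynamical system describing a
hyperpolarized substrate S converting irreversibly into a product P (the
motivating system is the carboxyl-esterase hydrolysis of ethyl acetoacetate,
but nothing is specific to it).  Between excitations the longitudinal
magnetization `x = (S, P)` relaxes and converts,

    dx/dt = A x,   A = [[-(k + R1S), 0], [k, -R1P]],

with conversion rate `k` (1/s) and longitudinal relaxation rates `R1S`,
`R1P` (1/s).  Sampling every `TR` seconds discretizes this to the
propagator `G = expm(TR A)`, evaluated in closed form:

    G11 = e^{-(k+R1S) TR},  G22 = e^{-R1P TR},
    G21 = k (G11 - G22) / (R1P - k - R1S),

with the series limit `G21 = k TR G11` at the eigenvalue degeneracy
`R1P = k + R1S`.  The quotient is computed through `expm1` so it is
cancellation-free arbitrarily close to the degeneracy; the exact-limit
branch engages below `|R1P - k - R1S| < 1e-8` 1/s.

Each RF excitation with prescribed flip angle `alpha_t` (degrees at every
interface, radians internally) converts `sin(B1S alpha_t) x_t` into measured
transverse signal `y_t` and leaves `cos(B1S alpha_t) x_t` to continue
evolving.  The dimensionless transmit scale `B1S` models the gap between
prescribed and delivered flip angles; with a constant-angle scheme it is
completely correlated with `S0, P0, R1S, R1P` and therefore only a free
parameter under variable-flip-angle (VFA) sampling.  Pulses are treated as
instantaneous, transverse magnetization is assumed fully spoiled between
excitations, and both metabolites receive the same flip angle (broadband
excitation).

Data are the signals plus i.i.d. Gaussian noise of equal sd on every point.
Points excited with exactly 0 degrees carry no signal and are excluded from
all fitting.

## Noise scale and normalization

Experimental practice divides all signals by the first substrate
measurement (`~ S0 sin(B1S alpha_0)`).  The package records that divisor in
each `Dataset` and divides the noise sd alongside the signals, which makes
the Fisher information and every fit invariant to the convention.  The
Monte Carlo harness interprets its `sigma` argument on the **raw** signal
scale (the same physical noise level for every scheme); on
first-point-normalized data this is exactly the "divide the added noise by
sin(alpha_0)" convention that makes semi-synthetic noise comparable across
schemes with different first angles.  The default raw sd of 5e-3 with
`S0 = 5` yields a ~2.4% relative sd of the fitted `k` under the optimized
CFA, and the same sd applied to unit-normalized backbones yields ~12% —
the two SNR regimes of the in-silico and semi-synthetic studies.

Sensitivities are derivatives of the unnormalized model divided by the
(fixed) normalization constant; differentiating *through* a model-based
`S0 sin(alpha_0)` factor is available behind a flag
(`differentiate_normalization`) but off by default, since the divisor is a
measured calibration constant once data exist.

## Information, bounds and the design criterion

Signal sensitivities to every parameter follow from the tangent recursion
(product rule applied to the state update); they are analytic and verified
against central finite differences at 1e-5 relative tolerance — the
package's primary oracle.  The Fisher information matrix is the
noise-weighted sum of sensitivity outer products over both metabolites and
all time points; its inverse is the Cramér–Rao covariance bound.  A FIM
with 2-norm condition number above 1e12 is flagged non-invertible (double
precision safety margin) and the bound refuses to evaluate.

The design criterion is L-optimality, `tr(W I^-1)` with diagonal weights.
Targeted designs use `w_i = 1/theta_i^2` on the parameter(s) of interest so
each weighted term is a squared relative uncertainty; this makes the
criterion invariant under the natural non-dimensionalization (rates scaled
by TR, magnetizations by the t = 0 substrate signal), and it is therefore
computed in physical units.  `W = I` recovers A-optimality.

Robustness to transmit miscalibration comes from marginalizing the
criterion over a discrete B1S prior: 11 equidistant points on [0.5, 1.5]
weighted by the N(1, 0.15) density (normalized to unit mass — an
unnormalized density would only rescale the objective).  Each grid point
evaluates the criterion at the effective angles `B1S_g * alpha`.  A
single-point prior reproduces the fixed-B1 design path exactly, which is
the variant used for stable-transmit settings.

A weak shrinkage penalty `n sigma^2 lambda sum_t sin^2(alpha_t)` (with `n`
the number of actively weighted parameters and `lambda = 0.1`) is added for
VFA optimization only.  It tidies the flat tail of the schedule — once the
hyperpolarization is spent, late angles have essentially no gradient — and
changes the attainable unregularized objective by well under 1%.

## Scheme optimization

Optimization is bounded L-BFGS-B (tolerance 1e-9 on a sigma-free objective
of order 1–100, max 10000 iterations, 100 line-search steps, 100000
function evaluations) with forward-difference gradients at step 1e-4
degrees.  The gradient is evaluated through a batched engine: because the
tangent map of the joint state/sensitivity system is angle-independent, the
per-candidate FIM factorizes into a batch-independent `K^t z0` sequence and
a per-candidate running product of cosines, reducing a full
finite-difference gradient to one small matrix product.  This is what makes
the 25-start protocol affordable on one CPU.

- CFA: one scalar angle, bounds [0.1, 90] degrees, initialized from
  10, 20, ..., 80 degrees, no regularization.
- VFA: all angles jointly, bounds [0, 90] (first angle >= 0.1 degrees for
  the normalization), 25 random initializations drawn uniformly from
  [10, 80] degrees with per-start seed `seed + index`.
- A singular FIM anywhere contributes a finite penalty (1e6 times the best
  feasible initialization value) so line searches can retreat; starts
  ending at the penalty level or failing to converge are recorded as
  outliers.  After optimization all objectives are recomputed without the
  penalty term's regularization and the best start by unregularized value
  is reported (ties break to the lowest start index).  Roughly half of the
  random starts land within 1% of the best value; the remainder converge
  to genuine local minima that burn the polarization early.
- The TR-and-angle CFA optimization sweeps TR at 0.5 s resolution (0.05 s
  refinement around the incumbent) with `floor(window/TR) + 1` excitations
  filling a fixed acquisition window, optimizing the angle per TR.

The default schedule length is 76 excitations (t = 0...150 s at TR = 2 s).
The criterion's optimum drifts slowly with record length: the optimized CFA
is 13.8 degrees at 76 excitations and 13.5 at ~96; comparisons between
schemes are insensitive to this choice, absolute optima shift by a few
tenths of a degree.  `n_excitations` is configurable everywhere.

Optionally (off by default) angles after the point where 99.9% of the
extractable signal has been spent can be snapped to 90 degrees for
reporting, mirroring the practice of appending terminal 90-degree pulses to
detect residual magnetization; this is cosmetic and not used in any
computation here.

## Fitting

Maximum likelihood under the equal-sd Gaussian noise model is bounded
nonlinear least squares over the included points.  The fit runs in the
non-dimensionalized parameterization with the analytic residual Jacobian,
trust-region-reflective steps, and generous physical bounds
(`k` in [0, 1] 1/s, rates in [1e-3, 1] 1/s, `S0` in (0, 100], `P0` in
[0, 100], `B1S` in [0.3, 2]).  Initialization is data-driven: initial
magnetizations from the first measured point, rates from their typical
values (1/35, 1/54 1/s), `k` from the early product growth slope over the
mean substrate level, clipped to [1e-4, 1].  Non-convergence triggers up to
three deterministically perturbed restarts and is flagged, never raised.
The with-B1S variant refuses constant-angle schemes (structural
non-identifiability).  Noiseless data are recovered to better than 1e-6
relative error in every parameter.

## Monte Carlo validation

All analyses share common random numbers: a seeded standard-normal matrix
`(n_reps, 2, T)` that depends only on its dimensions and seed, so every
scheme of equal length sees identical noise realizations and comparisons
are paired.  Per replicate: simulate at the ground truth, add raw-scale
noise, first-point-normalize, fit.  Non-converged replicates are excluded
from summaries and reported as a count (in practice none occur at the
default noise level).  Summaries report per-parameter mean, sd, bias and
RMSE (`RMSE^2 = bias^2 + sd^2 (n-1)/n` by construction).

- The robustness sweep perturbs one ground-truth parameter at a time to
  50–150% of nominal and reports log10 RMSE(k) differences against a
  reference scheme.
- The transmit-variation analysis draws a fresh `B1S ~ N(1, 0.15)` per
  replicate, truncated to (0.3, 2.0) so every truth lies inside the fit
  bounds (the untruncated distribution essentially never leaves that
  range); draws come from a stream separated from the noise stream.  It
  reports the Pearson correlation between fitted and drawn B1S.
- Semi-synthetic runs add noise to any fixed normalized backbone (measured
  data or a fixture); with a noiseless simulated backbone they reduce
  bit-exactly to the plain recovery analysis.

The study-scale configuration is 25 multistarts per designed scheme and
n = 1000 replicates per Monte Carlo condition; at these sizes the sampling
sd of a cross-scheme sd-ratio is roughly 3 percentage points, which is the
right yardstick for the reduction figures the harness prints.

## What the synthetic data do and do not emulate

The generator reproduces the in-silico study conditions: exact model
dynamics, i.i.d. Gaussian noise of scheme-independent raw amplitude, stable
or normally distributed transmit scale, and (optionally) a backbone whose
conversion rate decays 5% over the record to imitate substrate-depletion
model mismatch.  It does not emulate Rician magnitude noise, spectral
processing artifacts (phasing, baseline, peak integration), bolus-arrival
input functions, time-varying B1 within an experiment, or back-conversion.
Passing tests therefore demonstrate correctness of the estimator and the
design machinery under the stated noise model, not robustness to every
feature of real spectrometer data.

## Known limitations

Unidirectional conversion with constant `k`; a single broadband flip angle
for both metabolites (no metabolite-specific excitation); Gaussian-noise
Fisher information (no Rician variant); no priors over the kinetic
parameters themselves (the transmit scale is the only marginalized
quantity); design optimization is local-multistart, not certified global —
the exhaustive-grid cross-checks in the test suite bound how much that can
matter for the constant-angle cases.
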