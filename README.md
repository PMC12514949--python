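# vfadesign

Optimal flip-angle scheme design and kinetic parameter estimation for
hyperpolarized magnetic-resonance experiments.

## The problem

Hyperpolarization boosts nuclear spin polarization by orders of magnitude,
making it possible to watch a ¹³C-labeled substrate convert into its
metabolic product in real time.  The polarization is a non-renewable
resource: it decays with the longitudinal relaxation times T1 and every RF
excitation of flip angle α converts a fraction sin α of it into signal,
leaving cos α behind.  The experimenter chooses when and how hard to pulse —
and that schedule determines how precisely the kinetic parameters (above
all the conversion rate k, a disease marker) can be estimated from the
resulting time series.

`vfadesign` is for experimenters and methods developers who want to design
those schedules deliberately.  It

- simulates a two-pool unidirectional conversion model
  (`dx/dt = [[-(k+R1S), 0], [k, -R1P]] x` between pulses, discrete
  excitation losses at each pulse) under arbitrary flip-angle schedules;
- computes analytic signal sensitivities, the Fisher information matrix
  (FIM) and Cramér–Rao lower bounds (CRLB);
- optimizes constant (CFA) and variable (VFA) flip-angle schedules by
  minimizing the L-optimality criterion `tr(W · FIM⁻¹)` — with diagonal
  weights `wᵢ = 1/θᵢ²` each weighted term is a squared relative
  uncertainty — marginalized over a prior on the transmit-field scale B1S
  so the design stays efficient under RF miscalibration;
- fits the kinetic model (with or without B1S as a free parameter) to
  dynamic data by bounded least squares with analytic Jacobians; and
- validates designs by seeded Monte Carlo parameter-recovery studies with
  common random numbers across schemes.

The optimizers and the fitter are scikit-learn-style estimators
(`ConstantFlipAngleDesign`, `VariableFlipAngleDesign`,
`ConstantFlipAngleTRDesign`, `KineticLeastSquares`) with plain-function
wrappers (`optimize_cfa`, `optimize_vfa`, `fit`, ...) for scripting.

## Worked example

```python
import numpy as np
from vfadesign import (
    DesignConfig, KineticParameters, WeightSpec, add_noise, crlb, ernst_angle,
    fim, fit, make_b1_prior, normalize, optimize_cfa, optimize_vfa, simulate,
)

params = KineticParameters(k=0.0135, R1S=1 / 35, R1P=1 / 54, S0=5.0, P0=0.1)
prior = make_b1_prior()                      # 11-point N(1, 0.15) on [0.5, 1.5]
config = DesignConfig(n_starts=25, seed=1)   # 76 excitations at TR = 2 s
weights = WeightSpec.relative(params, "k")   # weight 1/k^2: target the rate

print(f"Ernst angle of the product (TR=2 s, T1P=54 s): "
      f"{ernst_angle(2.0, 1 / 54):.1f} deg")

cfa = optimize_cfa(params, weights, prior, config)
print(f"optimized CFA: {cfa.scheme.angles_deg[0]:.1f} deg, "
      f"objective {cfa.objective_unregularized:.3e}")

vfa = optimize_vfa(params, weights, prior, config)
active = vfa.scheme.angles_deg > 5.0
print(f"optimized VFA-k: {int(active.sum())} active pulses at "
      f"t = {np.array2string(vfa.scheme.times[active], precision=0)} s, "
      f"objective {vfa.objective_unregularized:.3e} "
      f"({vfa.best_within_1pct}/25 starts within 1%)")

ratio = np.sqrt(crlb(fim(params, vfa.scheme, 5e-3))[0, 0]
                / crlb(fim(params, cfa.scheme, 5e-3))[0, 0])
print(f"predicted sd(k) reduction VFA vs CFA: {100 * (1 - ratio):.0f}%")

traj = normalize(simulate(params, vfa.scheme), "s0-sin-alpha0")
data = add_noise(traj, sigma=5e-3, seed=42, on="raw")
est = fit(data, vfa.scheme, variant="with-b1s").estimates
print(f"fit:  k={est.k:.5f} /s  T1S={1 / est.R1S:.1f} s  T1P={1 / est.R1P:.1f} s  "
      f"B1S={est.B1S:.3f}  (truth: k=0.01350, T1S=35.0 s, T1P=54.0 s, B1S=1)")
```

prints (exactly; everything is seeded)

```
Ernst angle of the product (TR=2 s, T1P=54 s): 15.5 deg
optimized CFA: 13.8 deg, objective 5.768e-04
optimized VFA-k: 7 active pulses at t = [  0.  22.  24.  26.  28. 122. 136.] s, objective 2.640e-04 (13/25 starts within 1%)
predicted sd(k) reduction VFA vs CFA: 33%
fit:  k=0.01357 /s  T1S=35.2 s  T1P=54.1 s  B1S=0.997  (truth: k=0.01350, T1S=35.0 s, T1P=54.0 s, B1S=1)
```

Reading the numbers: the optimized constant
angle sits just below the product's Ernst angle, as it must — that is the
steady-state-efficiency sweet spot.  The optimized VFA concentrates the
polarization into a handful of pulses — one at bolus arrival, a cluster
~25 s in where the product signal is most informative about k, and large
terminal pulses that cash in the leftover magnetization — and is predicted
(and verified by Monte Carlo) to cut the standard deviation of k̂ by about
a third relative to the best possible constant angle.  The six-parameter
fit recovers the transmit scale B1S to 0.3% alongside the kinetics.

A command-line interface mirrors the library:
`vfadesign optimize --mode vfa --params params.json --weights k --seed 1
--out scheme.csv`, plus `simulate`, `fit`, `mc`, `fixtures` and `ernst`
subcommands (`vfadesign --help`).

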