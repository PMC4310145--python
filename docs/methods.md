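# Methods

## Model class and estimation

`plsdesign` works with ODE models

    dx/dt = f(x, u(t), theta_x),        y(t) = g(x, theta_y) + eps,

where `u(t)` is an external stimulus (constant or a rectangular pulse),
`theta_x` are kinetic parameters, `theta_y` readout parameters (gains,
pool sizes), and `eps ~ N(0, sigma_exp^2)` is additive white observation
noise. Initial conditions may depend on parameters (the plastoquinone
pool of the fluorescence model starts at its own estimated size), so
models carry a callable initial state that is re-evaluated at every
simulation.

All parameters are stored, optimized and reported on the log10 scale:
rate constants of the bundled models span eight orders of magnitude, and
log-space boxes turn multiplicative uncertainty into additive intervals.
Conversion to linear scale happens only inside the right-hand side.

Under the Gaussian noise model, maximum-likelihood estimation is
weighted least squares:

    chi2(theta) = sum_i (y_exp(t_i) - y_sim(t_i, theta))^2 / sigma_exp(t_i)^2,

minimized by bounded trust-region least squares (`scipy.optimize.least_squares`,
TRF) with multi-start initialization from a Latin hypercube over the
parameter box (default +/-3 decades around the starting guess). The
first start is always the user's guess verbatim. Jacobians are forward
differences with a fixed **absolute** step of 1e-4 decades: relative
steps collapse for log-parameters near zero and then sit below the ODE
solver's truncation error, turning the Jacobian into noise. Simulation
failures during optimization count as an infinite objective (the step is
rejected); a start that exhausts its evaluation budget on a flat
objective still contributes its best point.

## Simulation

Stiff integration uses LSODA through `scipy.integrate.odeint` with
analytic state Jacobians where available, splitting the time span at
stimulus discontinuities; default tolerances are rtol 1e-7 / atol 1e-9
(configurable; the identifiability analyses below use 1e-6 / 1e-8, at
which point the solution differs from the tight-tolerance one by ~1e-5
on states of order 1 — far below every noise scale used). Two special
paths exist:

- linear mass-action networks declare `dx/dt = M x + b u` and are solved
  in closed form by eigendecomposition of `M` (exact; automatic fallback
  to the integrator when the eigenbasis is ill-conditioned);
- the fluorescence model ships a numba-compiled right-hand side and
  Jacobian (~0.9 ms per 200-point simulation versus ~16 ms through the
  generic path).

## Profile likelihood and identifiability

The profile likelihood of parameter `theta_i` is

    chi2_PL(theta_i) = min over theta_{j != i} of chi2(theta),

traced by stepping `theta_i` away from the MLE in both directions and
re-optimizing all other parameters at each step, warm-started from the
neighboring point. Confidence regions follow the likelihood-ratio rule:
`chi2_PL - chi2_min < delta_alpha`, with `delta_alpha` the (1 - alpha)
quantile of chi2 with df = 1 (pointwise, the default) or df = n_theta
(simultaneous). The implementation uses the exact quantile
(3.841 at alpha = 0.05, df = 1). A branch that never crosses the
threshold within the explored range (default +/-3 decades) yields an
infinite bound: the parameter is practically non-identifiable on that
side.

Numerical policies that matter:

- **Adaptive stepping** targets a chi2 increase of about `delta/10` per
  step, bounded between 1e-3 and 0.1 decades (0.25 for the 13-parameter
  fluorescence analyses), so sharp profiles are resolved finely while
  flat branches advance quickly.
- **Threshold crossings are interpolated** through a local quadratic
  (exact for parabolic profiles, linear fallback).
- **Rescue restarts.** A warm-started local optimizer can lose the
  curved compensation ridge of a non-identifiable model and report a
  spurious threshold crossing. When a point first crosses the threshold
  (or would terminate the branch), the re-optimization is repeated from
  jittered and from uniformly drawn restarts inside the box (up to
  `n_rescue`, deterministic seeds); the lowest value wins. Any point
  found below the threshold is a certificate that chi2_PL is below it —
  rescue can only flatten profiles toward the truth, never sharpen them.
- **Re-anchoring.** Profiling explores parameter space far more
  thoroughly than the original fit; if any profile point undercuts the
  fitted chi2_min by more than 0.05, the MLE is moved there and all
  profiles are recomputed (at most twice). For the 13-parameter
  fluorescence analyses re-anchoring is disabled: on a flat compensation
  manifold profiling almost always finds points 1-2 chi2 units below
  the fit (overfitting wiggle), which would re-trigger recomputation
  indefinitely; intervals referenced to the fitted optimum are then
  conservative (wider) by at most that slack.
- **Nuisance box.** Re-optimization at each profile point uses the same
  +/- range box around the MLE as the profiled parameter itself.

Parameter vectors along each profile inside the confidence region are
kept as *profile samples*. For an unbounded side, samples extend to a
configurable range (default 3 decades) beyond the MLE, flagged
extended-range — this is what makes the uncertainty of non-identifiable
parameters visible in predictions.

## PLS index and entropy

Each parameter's profile samples are propagated through the model to an
ensemble of trajectories for any prediction `p` (a state or readout).
The profile likelihood sensitivity (PLS) index of `theta_i` for `p` at
time `t_k` is the squared normalized ensemble spread

    s_i(t_k) = ((max_j p_ij(t_k) - min_j p_ij(t_k)) / <p_hat(t)>_t)^2,

with `<p_hat>_t` the trapezoidal time average of the MLE trajectory
(robust to non-uniform grids). Summing over parameters and times gives
`s_tot`; the Shannon entropy of the per-time normalized indices
(natural log, `0 log 0 := 0`) gives `J_k in [0, ln n_theta]` and
`J_tot = sum_k J_k`. `s_tot` measures how much prediction uncertainty
the parameters induce; `J_tot` how evenly they share it. Entropy
rankings are invariant to the log base; a flag normalizes by
`ln n_theta` for comparisons across models of different size.

Candidate experiments (new readouts from the unmeasured states,
single-rate inhibitions emulated by scaling a rate constant by 1e-4,
or combinations) are ranked in the `(s_tot, J_tot)` plane by Pareto
nondomination — both coordinates are maximized and genuinely conflict,
so no scalarization is applied. Anticipatory evaluation generates
synthetic data for a candidate at the current MLE, merges it with the
real data, refits and re-profiles.

## Bundled systems and synthetic data

**In-silico network** (`insilico4`): four species A, B, C, D with mass
action kinetics; a stimulus pulse feeds A, two parallel routes
(A→B→D via k11, k12; A⇌C→D via k21, k22, k23) activate the readout
state D, and D decays through a first-order sink d. The structure is a
reconstruction consistent with the reported description of the network
(parallel compensating routes plus a sink). The baseline experiment
observes only D at 16 uniform times on [0, 2.5] with a unit pulse on
[0, 1]; noise is 10% of the time-averaged signal, floored at 0.01. The
pulse (rather than sustained drive) matters: under a constant stimulus
the stationary influx into the terminal state equals the input rate, so
the plateau level pins the sink rate from below, whereas after a finite
pulse the network relaxes and only an *upper* bound on d is data-
constrained — the reported baseline pattern. With this setup all six
rate constants are practically non-identifiable and only d has a finite
(upper) bound; state B carries the largest total PLS index, D (already
measured) the smallest, and A and C have larger PLS entropy than B.

**Fluorescence induction** (`dsalina`): the five-state photosystem-II
model of chlorophyll fluorescence induction in *Dunaliella salina* —
excited antennae A\*, reduced quinone acceptors Q_A^-, Q_B^-, Q_B^2-,
and the plastoquinone pool PQ, driven by a 166 µE m⁻² s⁻¹, 1 s light
pulse; readout F = G·k2·x1 on the normalized fluorescence scale; fixed
antenna pool A0 = 290; 13 free parameters. The one typographically
ambiguous term in the source ẋ2 equation is implemented as
−k7·x2·x3, the only reading consistent with its companion terms in the
ẋ3/ẋ4 equations. The baseline fixture observes F at 200 log-spaced
times on [1e-4, 1] s (induction phases spread over decades) with noise
SD 1e-3 on the normalized scale — the precision of a replicate-averaged
PAM trace. This value is deliberate: at substantially larger noise even
the plastoquinone replenishment rate k10 loses its finite upper bound,
while much smaller noise would bound k10's lower branch too; 1e-3
preserves the reported signature (k10 unbounded below, bounded above).
The augmented fixture adds an in-silico Q_B^- (x3) readout at 2% of its
own time-averaged scale (~2e-4 absolute; the x3 signal lives at ~1e-2,
so noise quoted on the fluorescence scale would bury it).

What the synthetic data do **not** emulate: PAM instrument artifacts
(detector saturation, measuring-light contribution — the 3 µE measuring
light is treated as non-actinic), replicate-to-replicate gain drift, and
the original experiment's 1e-4 s uniform sampling (10 001 points, which
weight the late plateau ~45× more heavily than the log grid does).
Passing the bundled checks therefore demonstrates the machinery and the
qualitative design logic, not instrument-level reproduction.

## Honest findings on the fluorescence model

With global re-optimization at every profile point, the fluorescence-
only dataset leaves most of the 13 parameters practically
non-identifiable at *any* noise level: the fast-equilibration rates k3,
k5, k7 can be raised by 2+ decades with joint compensation at
delta-chi2 < 1 (once equilibration is effectively instantaneous, making
it faster changes nothing observable), and an approximate scaling
symmetry in x1 (x1 << A0 over much of the trace) lets k1 fall freely
with G and k3 compensating. These flat directions scale with noise
exactly like k10's flat lower branch, so no noise choice yields
"everything identifiable except k10". What is robust, and what the
package's checks assert separately: k10's one-sided pattern (no lower
bound, finite upper bound close to the reported value), and the design
conclusion that adding the Q_B^- readout supplies k10's missing lower
bound and shrinks its interval to a two-sided one containing the truth.
The blanket identifiable-counts reported in the original analysis are
consistent with locally-explored profiles that do not find the joint
compensation ridges; the corresponding check in `tests/test_acceptance.py`
asserts them anyway and documents the discrepancy by failing.

## Problem sizes

The bundled analyses are sized for a single CPU: in-silico baseline
16×1 data points, 20 fit starts, 6 profiles (≈2 min including PLS and
design scoring); fluorescence baseline and augmented 200 and 400 points,
2 fit starts, 13 profiles each (≈5 min per scenario); the coverage study
uses 100 replications of a 2-parameter relaxation model solved in closed
form (≈1 min). Profile sampling density is ≥10 points per decade on
unbounded branches for the in-silico analyses and 4 per decade for the
13-parameter fluorescence analyses (whose PLS sampling no headline
quantity depends on).

## Known limitations

- Profile tracing is a local-continuation heuristic with global rescue;
  a sufficiently pathological likelihood can still defeat it (flagged,
  when detected, by the monotone-wing check).
- The declarative YAML model interface evaluates rate expressions in
  pure Python and is ~50× slower than the registered models; it is meant
  for prototyping, not production profiling.
- Only rectangular single-pulse or constant stimuli are supported;
  stimulus-shape and sampling-schedule optimization are out of scope.
- Noise is additive Gaussian with known per-point SD; no error-model
  estimation.
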