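# Methods

## Model

The decision process is a Wiener diffusion with drift *v* and diffusion
constant *s* on the interval [0, *a*], started at *z = z_r·a* and
stopped at the first passage of either boundary.  Response time is
first-passage time plus a non-decision component; with the
response-execution difference *d*, the upper-threshold response adds
*t₀ − d/2* and the lower one *t₀ + d/2*, so the mean over both is *t₀*.
Trial-to-trial variability: drift ~ Normal(*v*, *s_v*²), relative start
~ Uniform(*z_r* ± *s_zr*/2), non-decision time ~ Uniform(*t₀* ± *s_t0*/2).

*s* is a pure scale: multiplying *v*, *a*, *s_v* by *s_new/s_old* leaves
every predicted distribution unchanged.  All engines rescale to *s* = 1
on entry; results are reported on the scale of the input parameter set.
Relative quantities (*z_r*, *s_zr*) and all times never rescale.

Hard parameter constraints: *a* > 0, 0 < *z_r* < 1, *t₀* ≥ 0, all
variabilities ≥ 0, the starting-point distribution inside the corridor
(*z_r* ± *s_zr*/2 strictly within (0, 1)), and
*t₀ − s_t0/2 − |d|/2 ≥ 0.  The last constraint is our own addition: it
rules out parameter sets that predict responses before stimulus onset.
Constraint violations are never clamped; they are penalized during the
search (below).

## Density engine

The upper-threshold first-passage density of the basic model has a
small-time representation (sum over mirror images of the starting
point) and a large-time eigenfunction expansion.  For each evaluation
point the number of terms each series needs for truncation error ε is
bounded (the standard bounds on the scaled time axis *t/a²*), and the
representation needing fewer terms is evaluated.  ε = 10^−min(precision, 6),
so the single `precision` knob also governs series truncation.  The
lower threshold is the reflection *v → −v*, *z → a − z*.  Densities at
*t* ≤ 0 are defined as 0, avoiding the *t*^−3/2 singularity.  Both
representations factor the drift dependence as
exp[(a−z)v − v²t/2]·M(t, z, a); evaluation combines the two factors in
log space so extreme drifts visited by the optimizer can neither
overflow nor spuriously underflow.

The same factorization makes the normal drift mixture a Gaussian
integral with the closed form

    g'(t) = M(t,z,a) / sqrt(1 + s_v² t)
            · exp[((a−z)² s_v² + 2v(a−z) − v² t) / (2 (1 + s_v² t))]

which reduces exactly to the basic density at *s_v* = 0 (a 64-node
Gauss–Hermite quadrature of the mixture is kept in the test suite as an
independent oracle).  The uniform starting-point and non-decision-time
mixtures are midpoint averages with max(4, ⌈10^(precision/2)⌉) steps
each — 32 steps at the default precision 3, chosen so the refinement
error against a 2000-step reference sits near 10^−precision.

## CDF engine

The probability F₊(t, z) of upper absorption by time *t* solves the
backward Kolmogorov equation ∂F/∂t = ½∂²F/∂z² + v∂F/∂z with boundary
values F₊(t, 0) = 0, F₊(t, a) = 1 and a discontinuous initial condition.
We discretize z with second-order central differences
(max(8, ⌈a·30·10^((precision−3)/2)⌉) steps) and step in time with
Crank–Nicolson at dt = 0.1·a·dz.  The discontinuous initial data would
excite non-decaying Crank–Nicolson oscillations, so the first output
step is taken as damped backward-Euler substeps and the next three as
refined Crank–Nicolson substeps before full steps take over.  Stepping
stops when the probability mass still inside the corridor is below
0.5·10^−precision at every starting point (a hard cap raises a
diagnostic error with the achieved residual).  The lower-threshold CDF
solves the same equation with swapped boundary values, so one pass
yields both.

Because one grid carries every starting point, the uniform
starting-point mixture is a column average; the drift mixture uses
max(4, 2·precision) Gauss–Hermite nodes (one PDE pass per node, cached);
the non-decision window is a midpoint average of time shifts.  The
combined CDF over signed response times (lower RTs negated) is
assembled from both thresholds on a 2000-point grid and evaluated by
linear interpolation; beyond the grid it plateaus at the captured mass.

Accuracy at the default precision 3 is ≈10⁻³–10⁻⁴ absolute in the CDF
and ≈10⁻³ in its time derivative against the series density, for
parameters in the typical ranges (|v| ≤ 4, 0.6 ≤ a ≤ 2).  Strong drift
in a narrow corridor (e.g. v = 2 with a = 0.8) concentrates the density
early and the spatial error in the *slope* can reach a few 10⁻³;
precision 4 restores ≈2·10⁻⁴ there.  The CDF values themselves stay
within ≈10⁻³ in all tested configurations.

## Fit criteria

* **ML**: LL = Σ ln max(g, 10⁻⁶).  The fixed floor keeps single
  unexplained responses from producing −∞ and is itself the exact
  contribution of such a trial.
* **CS**: per condition and response, the 0.1/0.3/0.5/0.7/0.9 empirical
  quantiles define six bins (edges by linear interpolation between
  order statistics, numpy's default).  Predicted counts are joint
  masses — total condition trials × P(response ∧ bin) — so response
  frequencies are part of the fit.  Responses with fewer than 12 trials
  in a condition contribute no bins; conditions add.  df = K(N−1) − P
  with N = 12.
* **KS**: D = max |eCDF − pCDF| on the signed axis, with the empirical
  step function evaluated on both sides of each jump;
  p = Q_KS((√n + 0.12 + 0.11/√n)·D) via the asymptotic Kolmogorov tail
  with the usual small-sample correction, n the number of responses in
  the condition.  Per-condition p-values multiply.

The reported index is −LL, summed CS, or the p product.  BIC is
available as −2·LL + P·ln M.

## Optimization

Candidates are compared lexicographically: any constraint-violating
vector is *penalized* and ranks worse than every valid vector;
penalized vectors rank among themselves by the summed violation
magnitude, which gives the simplex a slope back into the valid region.
Valid vectors rank by the criterion (KS internally as −Σ ln p for
numerical stability).

The start vector uses the EZ closed-form moment estimates of (v, a, t₀)
from the upper-response accuracy and the upper-response RT mean and
variance, with z_r = 0.5 and variabilities 0.  Boundary accuracies are
edge-corrected by Pc → (n·Pc + 0.5)/(n + 1); exactly chance-level data
use Pc → 0.5 + 1/(2(n+1)) since the symmetric correction is the
identity there and would leave the EZ drift undefined.  Estimates are
clamped into the typical ranges (a ∈ [0.3, 4], |v| ≤ 5, t₀ ≥ 0 and
below the fastest response) and degenerate inputs fall back to neutral
defaults, so the start is always valid.

The Nelder–Mead simplex (reflection/expansion/contraction/shrink under
the lexicographic order) is hand-written because the two-criterion
comparison cannot be expressed through a scalar objective.  Initial
displacements: 0.1 for a, v, s_v, s_t0; 0.05 for z_r, s_zr; 0.02 s for
t₀, d.  Three consecutive runs use objective-spread tolerances
10⁻², 10⁻³, 10⁻⁴ with iteration caps 400/600/800; each restart
re-inflates a fresh simplex around the incumbent, which remains a
vertex, so the three reported fit values never worsen.  The whole fit
is deterministic given the data.

## Simulation tools

`sample_dataset` draws per-trial drift/start/non-decision values from
their inter-trial distributions and then inverts the conditional
basic-model CDF at a uniform deviate (the PDE grid carries all starting
points, so only distinct drifts require extra solves; with s_v > 0 each
trial's drift is its own solve, which is exact but slow for very large
samples).  `deterministic_dataset` places n trials at the
(i − 0.5)/n quantiles of the predicted combined distribution — the
plotting-position convention — giving noise-free samples whose refit
recovers the generating parameters to a few percent at n = 500.

The Monte-Carlo fit threshold draws parameter vectors from the
multivariate normal defined by the across-participant mean and
covariance of the estimates (singular covariances are
ridge-regularized with a warning; invalid draws are rejected and
redrawn), simulates one dataset per draw — condition cells separately,
then concatenated — refits each with the identical specification, and
returns the 5% worst quantile of the fit indices (5th percentile of the
p product for KS, 95th of CS or −LL).

## What the simulations do and do not show

The generator emulates the model's own data-generating process,
including all three inter-trial variabilities, but none of the
contaminants of real experiments: fast guesses, attention lapses,
post-error slowing, or drifts that change within a trial.  Passing
recovery and calibration tests therefore demonstrates the correctness
and internal consistency of the estimation machinery, not the adequacy
of the diffusion model for any particular task.  The test suite's
problem sizes (e.g. 50 replicates of 500 trials for ML recovery, 200
replicates of 1000 trials for Chi-Square calibration, 100 seeds for
simulation self-consistency) were chosen as the smallest runs at which
the statistical tolerances are meaningful.

## Known limitations

* The explicit closed-form CDF series is not implemented; the PDE
  solution is the single CDF route, cross-checked against the density
  engine.
* Random sampling with s_v > 0 solves one PDE per trial; for very large
  simulated samples this is the dominant cost.
* No hierarchical or Bayesian estimation, no standard errors or
  confidence intervals, no GUI; time-varying drift and collapsing
  thresholds are outside the model class.
* Output files are plain text with six significant digits.
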