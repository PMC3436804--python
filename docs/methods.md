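# Methods

`trajoed` implements sequential optimal experiment design for ODE models
with two competing selection rules — trajectory-oriented Bayesian design
and modified A-optimal Fisher design — and benchmarks them in silico on a
bundled model of secretion control at the trans-Golgi network.

## System and measurement model

The system is a positive ODE

    dx/dt = f(x, u, θ),   y = h(x),   x(0) = x0(u, θ),

with states x ∈ ℝ₊^{n_x}, perturbation input u, outputs y ∈ ℝ₊^{n_y} and
rate parameters θ handled throughout on the log10 scale.  An experiment
ℰ^i is an input vector u^i (per-species multipliers on basal synthesis
rates, applied at t = 0), a set of measurable outputs and an admissible
grid of measurement times.  Initial conditions are obtained by
pre-equilibration: the unperturbed system is integrated to steady state at
the simulated θ, then the input is applied at t = 0.  Consequently
x0 depends on θ (as the likelihood requires) but not on u.

Measurements are log-normally corrupted: a replicate of output y is
z = y·10^ε with ε ~ N(0, σ²), i.e. σ is the standard deviation of log10 z.
One σ is shared by all outputs and experiments.  The data unit is the
triplet: three replicates of one output at one time.  σ² is estimated from
the data by the replicate-pooled unbiased variance of log10 replicates and
is profiled (held fixed) within each inference run.

The likelihood is Gaussian on the log10 scale,
log L(θ) = Σ log N(log10 z | log10 y(t; θ, u), σ²), with failed
integrations mapped to −∞.

## Trajectory-oriented Bayesian design

After each new dataset the posterior P(θ|D) ∝ L(θ) P(θ) is sampled under a
bounded log-uniform prior box (four decades per coordinate by default).
From N posterior draws every candidate experiment is simulated on its full
grid, giving per-(experiment, output) trajectory ensembles in log10 space.
The design statistic is the per-time unbiased sample variance v̂ᵢⱼ(t)
across draws:

1. per (i, j), pick the time t*ᵢⱼ maximizing v̂ᵢⱼ(t) (earliest on ties);
2. zero out every maximum at or below the noise floor σ̂² (the pooled
   measurement-variance estimate): measuring there cannot beat the
   measurement process itself;
3. choose the experiment î maximizing Σⱼ ṽᵢⱼ (lowest index on ties) and
   request one triplet per surviving output at its t*;
4. stop the campaign when every ṽᵢⱼ is zero.

Variances are computed on log10 trajectories so they are commensurable
with σ̂² (≈ 0.0225 at σ = 0.15).  Ensemble draw indices are refreshed with
a round-specific seed each round.  Re-measuring a time already measured
for the same output remains admissible (an exclusion flag is not provided;
in practice the argmax moves once a point has been measured).

## A-optimal Fisher comparator

Sensitivities ∂log10 y/∂θ come from central finite differences (step 0.01
log10 units; one-sided at a prior-box face).  The Fisher information
matrix of a point set is F = Σ n_repl·g gᵀ/σ̂², which superposes over
experiments, outputs and times.  Because inverting near-singular FIMs of
sloppy models is ill-posed, the selection criterion is the inversion-free
modified A-optimality: maximize trace(F).  Trace additivity makes the
selection decouple exactly — best time per (i, j) by trace, best m-output
subset per experiment by top-m traces, successor experiment by the summed
trace — so the implementation's greedy selection equals exhaustive subset
enumeration (verified against it in the tests).  The per-round measurement
count m is fairness-coupled to the Bayesian arm's pick count.  The FIM is
evaluated at a fresh multi-start MLE each round; the comparator inherits
the MLE's instability on sloppy problems, which is part of what the
benchmark measures.

## Posterior sampling

Haario-style adaptive Metropolis with parallel chains run in lockstep:
the Gaussian random-walk covariance is re-estimated every 100 steps
(after step 200) from the *pooled* history of all chains, scaled by
2.38²/d with a small diagonal jitter; proposals outside the prior box are
rejected.  Pooling means the spread between chains feeds back into the
shared proposal, which carries chains across the flat (sloppy) directions
far faster than per-chain adaptation.  On this box-constrained sloppy
target the resulting acceptance rate runs well below the 0.234 Gaussian
optimum; steering the scale toward 0.234 was tried and measurably
worsened between-chain mixing (the over-dispersed proposals are what
perform the long jumps), so no acceptance steering is applied.

Chains start from jittered multi-start MLE points by default
(prior-uniform starts take far longer to burn in; with no data the
sampler starts from the prior).  The first half of each chain is
discarded as burn-in.  Convergence screening uses the split potential
scale reduction R̂: chains are dropped (most-outlying first, at least two
retained) until max R̂ falls under the threshold; failing that, sampling
continues warm in further blocks of the same length (up to two
extensions) before giving up.  The library default threshold is 1.1 and
a final failure raises; the campaign configuration uses 1.5 (matching
its deliberately short chains) and proceeds on the best chain subset
with the non-convergence recorded in the round diagnostics, because the
study protocol requires completing all rounds.  Metrics from such
partial posteriors are flagged; a stuck sampler under-disperses, so
entropy and variance from those rounds read low.

## Entropy estimation

Posterior spread is summarized by differential Shannon entropy in nats,
estimated from the merged sample with a Gaussian-product KDE (diagonal
bandwidth, per-dimension Silverman rule).  Two corrections matter in
practice and are part of the estimator:

- **leave-one-out evaluation** (Ahmad–Lin): the evaluation point's own
  kernel is excluded.  Keeping it biases the estimate low by the
  self-contribution — at d = 12, n = 10⁵ the self term exceeds the true
  box density and costs ≈ 2 nats.
- **boundary reflection**: every posterior here is supported on the prior
  box, and an unbounded kernel loses mass across the faces, biasing the
  estimate high (≈ +1.7 nats on the 12-D prior itself).  The kernel is
  therefore reflected at the known support faces.

With both corrections the estimator is within 0.26 nats of the exact
12·ln 4 on the four-decade prior box and within 0.01 nats of ln(2πe) on a
standard 2-D Gaussian at n = 10⁵ (asserted in the tests).  Zero-variance
dimensions get a bandwidth floor.

## The reference model

The bundled trans-Golgi model follows the experimentally established
interaction topology of the secretion-control circuit; quantitative rate
constants for it are not published, so the model is a documented
structural reconstruction: 9 species (PKD, CERT, PI4KIIIβ in
inactive/active forms, PI4P, DAG, ceramide), bilinear mass-action
activation fluxes, linear degradation self-loops, 12 free interaction
parameters and 17 fixed basal parameters (5 productions, 9 degradations,
3 constant substrate pools).  Observables: PKD*, PI4KIIIβ*, CERT*, total
DAG, total ceramide; PKD, CERT, PI4KIIIβ and PI4P are latent.  Basal rates
are fixed so nominal steady states are O(1)–O(10) a.u. and perturbations
produce clear transients over the 72 h horizon.  The true parameters
default to the centre of the prior box.  The catalogue contains the 27
perturbation permutations of PKD, CERT and PI4KIIIβ at multipliers
(0.1, 1, 10) — siRNA knockdown, untouched, vector overexpression — each
with a 105-point equidistant grid over (0, 72 h] (≈ 41 min spacing).
Each DAG/ceramide pool is modelled as a single state.

Because the reconstruction is structural, quantitative campaign outcomes
are order-of-magnitude results of *this* model, not reproductions of any
particular parametrization; trends (uncertainty reduction, stopping, the
Bayes-vs-Fisher ordering) are the meaningful surface.

## Study protocol and problem sizes

A campaign starts from a joint algorithm-neutral initial experiment — the
unperturbed catalogue entry with all five outputs measured in triplicate
at 24, 48 and 72 h — then alternates posterior update → metrics → design →
virtual measurement until the stopping criterion fires or a round cap is
reached.  Metrics per round: the grand unweighted mean of v̂ᵢⱼ(t) over all
27 experiments, outputs and grid times, and the posterior entropy.  All
randomness derives from a master seed via deterministic sub-seed
derivation, making campaigns bit-reproducible.  Every ODE solve is counted
and attributed to inference or design in the round records.

Default problem sizes are a desk-scale rendition of the study: virtual
noise σ* = 0.15, triplets, N = 1000 prediction draws (the bundled
benchmark runs use 300), 4 adaptive-Metropolis chains in 5 000–10 000
step blocks (extended warm until screening passes) rather than
multi-million-point merged posteriors, up to three designed experiments
after the initial one (four experiments in total), and solver tolerances
1e−6/1e−8 in campaigns (1e−8/1e−10
library default) — integration error remains orders of magnitude below
measurement noise.  At these sizes the sampler explores an MLE-anchored
region of the sloppy 12-D posterior, so absolute entropies and variances
are smaller than an exhaustive posterior would give; round-over-round
trends and the paired comparison between arms (identical budgets in
both) are the meaningful readout.

Re-measurement of an already measured (experiment, output, time) point is
admissible in later rounds; its new replicates are pooled into the
existing record.

## What the synthetic generator does and does not emulate

The generator *is* the study's "true system": model trajectories at the
true θ corrupted by i.i.d. log-normal noise.  It emulates replicate
scatter, triplet acquisition and perturbation inputs.  It does not emulate
model error (data come from the same equations that are fitted), input
uncertainty, heteroscedastic or output-specific noise, missing values, or
between-day batch effects.  Passing campaign tests therefore demonstrate
the design machinery under a correctly specified model — the idealization
every in silico benchmark makes — and say nothing about robustness to
model misspecification.

## Numerical choices and degenerate inputs

- LSODA through scipy's low-overhead ``odeint`` loop, with an analytic
  Jacobian and numba-compiled right-hand-side kernels for the reference
  model (a pure-numpy fallback is kept and cross-checked in the tests);
  integration failures raise immediately (diverging or non-finite states
  abort the stepper) and are mapped to −∞ likelihood or
  skipped-and-counted draws.
- Pre-equilibration integrates up to 3 200 h until the relative residual
  falls below 1e−8; steady states are cached per parameter vector.
- Ties: earliest time, lowest experiment index, catalogue output order.
- Ensembles with fewer than 2 rows have no variance and raise; > 10%
  failed draws in an ensemble raise (posterior inconsistent with model).
- Pooled variance requires at least one multi-replicate measurement.
- MLE: L-BFGS-B multi-start inside the prior box with −∞ mapped to a
  large finite penalty.

## Known limitations

- The reconstruction's rate constants are plausible defaults, not fitted
  values; only the interaction structure, dimensions and protocol
  constants are grounded in the literature.
- Adaptive Metropolis at desk scale under-disperses on sloppy posteriors;
  absolute entropy/variance levels shift accordingly (see above).
- The campaign checkpoint on failure writes datasets, metrics and the log,
  but resuming restarts the failed round's posterior update from scratch.
- Model-discrimination design, posterior-predictive design criteria,
  SBML import and D-/E-optimality are out of scope.
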