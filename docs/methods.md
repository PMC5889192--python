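# Methods

This note documents the models, the synthetic-task generator, the
numerics, and the design choices the package makes where the problem is
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The task being emulated

A two-alternative color-discrimination task.  Dots (red/green, dominant
fraction q drawn from a 57:43 urn by default) appear one every 50 ms
(20 Hz) starting at t = 0 and each remains visible for 2.0 s, so the
display fills to 40 dots at t = 2.0 s and holds that count.  Time
pressure comes in three forms:

* **Deadline sessions** ("exp1"): six hard deadlines, 0.7 k s for levels
  k = 1..6; 10 blocks x 36 trials with every level six times per block.
  Correct/incorrect responses gain/lose 60 points; a missed deadline
  loses 60 points.
* **Reward-decay sessions** ("exp2"): the stake (50 or 100 points) decays
  linearly at one of six rates b, starting at onset t0, floored at zero:
  `G(t, correct) = max(0, Gs - b (t - t0)+)`, `G(t, error) = -G(t,
  correct)`.  10 blocks x 36 trials, each (stake, rate) pair three times
  per block.
* **Gamble sessions** ("exp3"): mathematically equivalent to exp2 without
  dots; accepting the gamble at time t wins with probability SAT(t).
* **Pre-test**: 3 dot ratios x 3 windows, 9 blocks x 36 = 324 trials, the
  ratio fixed within a block and cycling 60:40, 57:43, 54:46.

Choices the generator makes where the protocol leaves room: the first dot
appears exactly at t = 0 (this is what makes the 40-dot plateau start at
2.0 s); the dominant color is re-randomized red/green per trial with
probability 1/2; the missed-deadline penalty (stated for the pre-test) is
reused for deadline sessions; exp2's decay onset t0 is the fitted SAT
rise point δ; exp2/exp3 losses decay toward zero symmetrically with
gains.  Reproducibility: one integer seed spawns independent per-(block,
trial) RNG substreams, so adding analyses never perturbs stimulus draws.
What the generator does **not** emulate: screen rendering, luminance,
motor/keyboard jitter, learning or fatigue across blocks, and any
between-subject variability beyond what the caller scripts — so passing
tests show internal consistency of models and analyses, not claims about
human data.

## Speed-accuracy tradeoff

`P(t̄) = c + (1-c) β [1 - exp(-(t̄-δ)/λ)]`, clamped at c for t̄ < δ
(probabilities below chance are meaningless here and δ is by definition
where P leaves chance).  c is fixed at 0.5; β = 1 in the per-schedule
variant and free in [0, 1] for the pooled ten-bin variant, where it
captures the sub-unit plateau produced by leaky integration.  Fitting
maximizes the binomial log-likelihood of per-bin correct counts (the
natural likelihood for count data), with the constraints δ > 0.2 s and
λ > 0.001 s, by bounded L-BFGS-B from eight deterministic starts on a
log-spaced (δ, λ) grid; exact ties prefer the smaller δ.  A fit whose λ
lands on its upper bound (no SAT signal in the data) is flagged, not
silently returned.

## Optimal expected-gain response time

With delta dispersion (the default) `EG(t̄) = G(t̄,1) P(t̄) + G(t̄,0)
(1-P(t̄))`; with Gaussian dispersion the integral over the response-time
distribution is evaluated by 61-node Gauss-Legendre quadrature over
±4σ (σ, if used, should be the subject's pooled RT SD).  The model is
parameter-free given the SAT and the schedule.  Because reward clipping
makes EG only piecewise smooth, the argmax is located by 1 ms grid search
(first maximum wins ties) plus a bounded scalar polish between the
neighboring grid points.  The grid is capped at ~50 rise constants past
the decay onset, where the SAT is flat to machine precision; beyond that
cap EG strictly decreases for any positive decay rate, so the cap never
moves the argmax.

**Rate design.**  Targets a_k are `linspace(acc_lo, acc_hi, n)` (a single
level degenerates to {acc_lo}); for each target, Brent root-finding on b
exploits that accuracy at the optimum decreases monotonically in b, and
the result is verified to reproduce its target within 1e-3.  acc_hi
defaults to the SAT evaluated at the longest deadline (4.2 s) capped at
0.95; targets at or above the SAT plateau raise an error naming the
level.  Rates are designed at a reference stake of 100 points: for fixed
b the optimum shifts slightly with the stake, and the published design
procedure treats the rates as stake-independent, so one reference is
needed — 100 is the procedure's own worked-example value.

## The seven decision models

All models integrate by Euler-Maruyama at dt = 1 ms with Gaussian
increments of variance c² dt.  Conventions that the equations leave open:

* **Urgency** U(t) = u·t exactly (zero intercept); u is shared across
  schedules.  The urgency readout `|x(t)|·u t ≥ B` is implemented as the
  equivalent moving bound `B/(u t)` on x, which a test verifies
  trial-for-trial on shared noise.  In the leak+urgency model the leak
  filter applies first, then the multiplication.
* **Leak** follows `τ dx = -x dt + A dt + c dW` literally, so the
  effective noise scale on x is c/τ and the integrator equilibrates at A
  with stationary SD c/√(2τ).
* **Attractor**: the effective potential `G(x) = b(x² - βx⁴ + γx⁶)` is
  tri-stable iff β² > 3γ (defaults β = 2, γ = 1).  As printed, the
  attractor dynamics contain no stimulus term and would perform at
  chance; the evidence input enters as a linear tilt,
  `dx/dt = A - G'(x) + [U(t)+F(t)]x + noise`, matching the convention
  that every family carries a drift A whose sign is set by the dominant
  color.  Commitment occurs when |x| passes the inner inflection point of
  the outer wells (for β=2, γ=1: x ≈ 0.840) — the point where the outer
  basin's curvature takes over; the forcing term F steps on 50 ms before
  the deadline with amplitude 10x the maximum potential slope, forcing
  escape from the central state.
* **Per-schedule freedom**: decision bounds B_k are free per schedule in
  every family; the collapsing family also frees its collapse constant
  λ_k per schedule; the attractor frees its barrier b_k.
* **Boundary correction**: discrete-time crossing detection misses
  within-step excursions, biasing first passages late by 0.5826·σ√dt to
  leading order.  Simulators subtract that amount from the bound by
  default (`boundary_correction=False` restores plain Euler).
* **Stimulus coupling**: by default drift is constant within a trial (the
  fitting setup).  In stimulus-driven mode the momentary drift is
  gain·(n_dom - n_other)/D with D the current visible count ("fraction",
  the color-strength convention) or the steady-state count 40 ("fixed").
  Under "fraction" early dots carry mechanically larger leverage (each is
  1/n_vis of the display); "fixed" makes per-dot leverage time-invariant
  and is the mode used for kernel analyses, where the integrator's
  temporal weighting is the object of interest.

## Fokker-Planck solver

`∂p/∂t = -∂(μ(x,t) p)/∂x + (c_eff²/2) ∂²p/∂x²` on a fixed symmetric
grid, Crank-Nicolson in time (unconditionally stable), central
differences in space, absorbing edges.  Moving bounds (collapsing,
urgency) shrink the active cell range per step; excluded cells are zeroed
and their mass booked as boundary flux.  Mass accounting is exact by
construction: each step's lost mass is split between the two boundaries
in proportion to the discrete boundary currents (diffusive + advective),
so remaining + absorbed = 1 to machine precision, and a conservation
check (1e-4) guards against grid pathologies.  The delta initial
condition is replaced by its analytic one-step propagation (a Gaussian of
SD c_eff√dt, floored at 0.4 dx) to avoid Crank-Nicolson ringing.
Variant drift is a Gaussian mixture over A, integrated by Gauss-Hermite
quadrature (11 nodes; 5-7 during fitting).  For urgency-type bounds
(infinite at t = 0) the grid extent is capped where the moving bound
meets a 6-SD envelope of the free process.  Verified accuracy at the
settings the tests use: absorption probabilities within ~1e-3 of the
two-boundary Wiener closed forms, mean decision times within 1%, and
first-passage CDFs within 0.01 sup-norm of 10^5-trial simulations for
all seven families.

## Summary likelihood, fitting, and AIC

The fitting target per (schedule, RT-quantile bin k = 1..5) is the
proportion correct and the RT mean and SD of responded trials —
non-crossing probability mass is discarded and the remainder
renormalized, matching the analysis of trials that beat the deadline.
Quantile bins (outer edges pinned to 0 and the deadline) avoid empty
cells.  The likelihood is Gaussian with the standard summary-statistic
variances, evaluated from the observed table: p(1-p)/n (floored at
1e-3/n), sd²/n, and sd²/(2n) (delta method).  During optimization a
predicted-empty bin is charged a fixed penalty of -50 log-units (pure
exclusion would reward parameters that empty bins); the standalone
`summary_loglik` excludes flagged bins, as a likelihood of given
summaries should.

Identifiability: the diffusion scale c is fixed at 1 in every family
(the classic DDM scale degeneracy), and the urgency slope u is fixed at
1 while fitting the urgency families, where only B_k/u is identified;
parameter counts k reflect both.  Optimization is bounded L-BFGS-B in
log-parameter space from ≥10 deterministic, data-driven starts (drift
and bound scales seeded by basic-DDM moment inversion of the observed
accuracy and mean RT); all starts are scored and the best are polished,
with value-then-parameter tie-breaks so the outcome is invariant to
start order.  AIC = 2k - 2 logL; `compare_models` sorts ascending.

## Problem sizes in the test suite

Chosen so each check is decisive at desk scale: stimulus-law checks pool
10^4 streams; closed-form and Monte-Carlo comparisons use 10^5 trials
(simulation dt 0.5 ms, solver dt 0.2-0.5 ms); SAT recovery uses 10^4
trials/bin (and 25 refits per sample size for the error-shrinkage
property); model recovery uses 50 replicates of 1000 trials/schedule
fitted by all seven families at a coarsened solver resolution (dt
7.5 ms, 101 grid points) that preserves AIC rankings; signature and
kernel analyses use 10^4 trials per schedule.

## Known limitations

* The attractor fit uses fixed potential shape (β, γ) and fits only the
  per-schedule barrier, tilt and urgency slope; shape parameters are
  weakly identified from summary data.
* Kernel analyses assume tiled (non-overlapping) 200 ms windows counted
  back from the response, pooling trials within a schedule.
* The greedy RT-matching stops at the first locally non-improving
  removal on either side; on adversarial inputs this is within ~10% of
  the exhaustively optimal prefix-removal, not exactly optimal.
* Exp2/exp3 sessions are simulated with the same first-passage models as
  exp1; no reward-sensitive stopping rule is modelled inside a trial
  (the expected-gain model addresses that question at the level of mean
  response times).
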