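# Methods

## Model class

`pmjp` works with population Markov jump processes (pMJPs, also called
population CTMCs or stochastic kinetic models): the state is a vector
`s = (n_1, …, n_M)` of nonnegative species counts, and `R` reaction
channels fire with kinetic-law rates

    f_i(s) = θ_i · ρ_i(s),

where `ρ_i` is a fixed function of the state and `θ_i` the unknown kinetic
parameter — one parameter per reaction. Firing reaction `i` shifts the
state by its net stoichiometry vector `δ_i`. Because each reaction carries
a single parameter, models are required to have pairwise-distinct
stoichiometries so the reaction fired between two states can be read off
their difference; probabilistic disambiguation of tied stoichiometries is
out of scope (none of the benchmark systems needs it).

Kinetic laws are declarative: a mass-action part (product of falling
factorials of reactant counts), indicator factors (a reaction gated on an
exact species level, e.g. a gene being active) and exponential factors
(rates of the form `θ e^{r P}`, used for repression). An arbitrary Python
callable is also accepted but cannot be serialized to config files.

On a finite state space the rates assemble into the generator `A`;
transient probabilities are `p(t) = p(0) e^{At}`, computed with scipy's
matrix exponential (dense below ~500 states) or its sparse action
(`expm_multiply`) above. The generator is linear in θ, so a
θ-independent sparsity template is cached per (model, space, mode) and
re-scaled at each evaluation; this matters because the samplers rebuild
`A` at a fresh θ every sweep.

Two diagonal conventions exist. *Closed* mode drops reactions that would
leave the space (row sums zero — the static-truncation baseline and the
input to uniformisation). *Substochastic* mode charges out-of-space
rates to the diagonal, so the surviving mass is exactly the probability of
never leaving the box — the semantics the series expansion below needs.

## Series expansion of the transition likelihood

With noiseless snapshots, the likelihood factorizes over consecutive
observation pairs `(s, s′, dt)`. Writing `s^u = max(s, s′)` componentwise,
define

    f^(N) = P(state = s′ at dt, path never exceeds s^u + N in any dimension),

computed as one entry of the substochastic matrix exponential on the box
`[0, s^u + N]` (lower bound 0 in all dimensions; a single scalar `N`
inflates every dimension). The events are nested, so

    p(s′ | s, θ) = Σ_N p^(N),   p^(0) = f^(0),  p^(N) = f^(N) − f^(N−1),

and every term is itself a probability, hence nonnegative. Subtraction can
produce round-off slightly below zero; terms within 1e−12 of zero are
clamped to exactly zero so the estimator can never go negative.

## Russian-Roulette truncation

The infinite series is estimated unbiasedly by keeping a random number of
leading terms. Term 0 is always kept; the sum continues past term `n−1`
with probability `q̄_n = a^n`, `a ∈ (0, 1)`. Term `N` is therefore
included with probability `p_N = a^{N(N+1)/2}`, and the estimator is the
partial sum of `p^(N)/p_N` over the retained terms. Weighting by the
*inclusion* probability is what makes the estimator unbiased; the
implementation fixes the weights to `a^{N(N+1)/2}` and verifies them
against the analytic expected term counts (5.6, 2.4, 1.2 and 12.5 at
a = 0.95, 0.75, 0.2, 0.99), which an off-by-one in the weight product
would break. The expected number of retained terms,
`1 + Σ_{n≥1} a^{n(n+1)/2}`, is summed to absolute tolerance 1e−12.

Per-interval `f^(N)` sequences are computed incrementally and cached
(`_IntervalKernel`), so repeated draws at the same θ reuse every matrix
exponential. Products over intervals are accumulated in the log domain; a
zero estimate for any interval flags the whole likelihood estimate as zero
(log −inf).

The estimator's variance is assessed empirically (unbiasedness and
coefficient-of-variation tests); no analytic variance bound is computed.

## Uniformisation and FFBS

A closed-mode generator is uniformised with common exit rate
`γ = multiplier × max_i |a_ii|` and transition matrix `B = A/γ + I`. The
default multiplier is 2: any value ≥ 1 preserves the marginals (Jensen's
construction), but a strict surplus of self-jump probability is what lets
the auxiliary-variable sampler move jump times, so 1 would be degenerate.
If every rate is zero, γ falls back to a tiny floor so `B = I` is still
defined. `B` is kept sparse (CSR) on large spaces — it has only ~R+1
nonzeros per row — and dense on small ones.

Path sampling follows the auxiliary-variable scheme: given the current
trajectory, candidate jump times are resampled as a Poisson process of
intensity `γ − exit(state)` on each holding interval, unioned with the
current jump times; discrete forward filtering–backward sampling then
redraws the state sequence on that grid, and removing self-jumps yields a
new trajectory. Observations attach to the last grid point at or before
their time (right-continuous paths; an observation at a jump time reads
the post-jump state). Emissions are indicators by default; an observation
may mark some species as unobserved (partial observation), which turns its
emission vector into an indicator on the observed coordinates only. The
initial distribution over the space is uniform unless supplied; an
observation at time 0 sharpens it through its emission.

When no current path exists (initialization, independent-draw studies) the
grid is drawn as a homogeneous Poisson(γ) process. A single FFBS pass on
such a fresh grid is *not* an exact posterior draw — the grid itself must
be resampled given a path for the kernel to target the joint posterior —
so exact-draw tests run a short chain of kernel sweeps after the fresh
start, and fresh grids that cannot connect the observations (too few
candidate times) are simply redrawn, with a bounded retry count.

The same machinery evaluates the conditional probability of a *given*
path: the path is discretized on a grid containing its jump times, forward
messages are computed first (their normalizers give the evidence; backward
messages are available as by-products), and the path's log-probability is
its joint chain weight minus the log-evidence. All message passing is
normalized per step with accumulated log-normalizers.

## Samplers

**Finite-space Gibbs.** Alternates an exact FFBS trajectory draw with the
exact conjugate parameter update: along a path with reaction counts `N_i`
and integrated rate factors `∫ρ_i = Σ_k Δt_k ρ_i(s_k)` (virtual jumps
contribute to the integrals, never to the counts), Gamma(a_i, b_i) priors
give `θ_i | path ~ Gamma(a_i + N_i, b_i + ∫ρ_i)`. The chain starts from a
prior-drawn θ and a deterministic minimal-event trajectory (shortest
reaction sequences through the observations, jumps spaced evenly) — a
fresh-grid FFBS start can be infeasible when the initial θ is tiny.

**Algorithm 1 (pseudo-marginal M–H).** A Gaussian random walk on log θ
(positivity for free; per-parameter step sizes; a linear-scale mode is
available) proposes θ*, the roulette estimate of the likelihood is
computed at θ*, and the move is accepted with the usual ratio including
the prior and the log-scale Jacobian. The estimate attached to the current
state is retained until a move is accepted; recomputing it each sweep
(the Monte-Carlo-within-Metropolis variant) would target only an
approximate posterior and is deliberately not implemented. A diagnostic
warns when a long run of consecutive proposals has zero estimated
likelihood — the "sticking" signature of an overly aggressive truncation.

**Algorithm 2 (Metropolized truncation Gibbs).** Each sweep: (1) θ* from
the exact Gamma conditional given the current path; (2) a truncation draw
m* = (roulette term count − 1), defining the box `{x : x_d ≤ y*_d + m*}`
over the observed maxima y*, and a trajectory S* drawn by FFBS on that
box; (3) the conditional probabilities of S* and the current S under both
the new and old truncations; (4) acceptance with
`α = [p_new(S*) p_new(S)] / [p_old(S) p_old(S*)]`, the whole sweep —
including θ* — discarded on rejection. With the truncation held fixed the
four factors cancel exactly and every sweep is accepted (checked bitwise
in the tests).

Design choices where the procedure is underdetermined:

- *Proposal grid.* S* is drawn with the auxiliary-variable kernel seeded
  by the current trajectory, which is always possible when the proposed
  box contains it (in particular whenever the box grows). When the current
  trajectory leaves a proposed smaller box, its conditional probability
  under the new truncation is zero, so α = 0 regardless of S*; the sweep
  is rejected immediately and no proposal is drawn.
- *Evaluation grid.* All four probabilities in α are evaluated on the
  shared grid formed by the union of the two trajectories' jump times,
  each space using its own uniformised chain (γ, B). A shared grid makes
  the grid-dependence of the discretized path probabilities cancel between
  numerator and denominator.
- *Degenerate ratios.* If numerator and denominator are both zero (each
  path impossible under the other's truncation) the sweep is rejected.
- *m\* offset.* The roulette draw k maps to box inflation m* = k − 1, so
  the minimal draw (one term) reproduces the base box that already
  contains all observations, mirroring the N = 0 term of the series.

## Diagnostics

ESS uses `n / (1 + 2Σρ_k)` with autocovariances (FFT, via statsmodels)
truncated by the initial-monotone-sequence rule on adjacent pairs; a
constant series reports ESS 0 with a warning, and ESS is capped at n. PSRF
is the classic Gelman–Rubin `√(((n−1)/n · W + B/n)/W)` on the second
halves of ≥ 2 chains (rank-normalized variants are out of scope);
identical chains (W = 0) report 1.0 with a warning. Iterations-to-
convergence scans a grid of 20 prefix checkpoints for the first at which
every parameter's PSRF is below the threshold (default 1.1), with a
sentinel when none qualifies. The relative-error metric is the mean of
`|posterior mean − θ_true|/θ_true`, in percent, reported per parameter and
averaged.

## Benchmark fixtures and the synthetic-data generator

The simulator is Gillespie's direct method; observation sets read the
trajectory at given times (right-continuous). The built-in systems:

- **Lotka–Volterra** (predators X, prey Y): reactions with rates
  `θ1·XY, θ2·X, θ3·Y, θ4·XY`; conventional start (7, 20). Default
  θ = (0.12, 0.6, 0.6, 0.12) puts the deterministic equilibrium at
  (5, 5) so simulated counts stay in the small-count regime where the
  discrete stochastic treatment matters.
- **SIR, closed** (S, I, R): infection `θ1·SI`, recovery `θ2·I`, start
  (10, 5, 0); the reachable space has exactly 121 states. Defaults
  θ = (0.1, 0.5).
- **SIR, open**: adds arrivals `∅ → S` at constant rate θ3 — an
  unbounded state space.
- **Immigration–death**: constant birth rate 150 and unit per-capita
  death, start 10; the stationary law is Poisson(150), giving closed-form
  oracles for simulator tests.
- **Genetic toggle switch**: two genes (binary activity) and their
  proteins (discrete levels); production gated on the active gene,
  mass-action degradation, constant activation, and deactivation at
  `θ7 e^{r P2}` / `θ8 e^{r P1}` with the repression constant r known
  (default 0.02, configurable). Deactivation of each protein is
  mass-action in its *own* level.

True parameter values and priors for inference experiments are
configuration, not constants of nature: fixture defaults are chosen to
keep populations small, and priors default to Gamma(1, 1).

What the generator does *not* emulate: measurement noise (observations
are exact counts; the FFBS layer accepts partial observations and could
host emission models, but no noise family is built in), time-varying
rates, delays, and hybrid/diffusion regimes. Tests passing on these
fixtures therefore demonstrate correctness of the inference machinery on
noiseless, small-count data, not robustness to misspecified or noisy real
data.

## Experiment sizes in the test suite

The statistical checks run at sizes chosen for a single core: estimator
unbiasedness uses 1e5 roulette draws against the converged `f^(20)` on the
immigration–death model; FFBS exactness uses 2e4 near-independent draws
(six kernel sweeps each) on a 3-state chain against the
matrix-exponential conditional law; the degenerate-acceptance property is
asserted bitwise over 1000 sweeps on predator–prey data; the two
pseudo-marginal samplers are compared on an open SIR model with 5 initial
individuals and 4 observations at 2e4 sweeps each (marginal total
variation < 0.1); and interval calibration runs 20 predator–prey
replicates (15 observations each, parameters drawn from the priors,
5000 sweeps) and checks ≥ 80% empirical coverage of the 90% intervals.
Monte-Carlo checks use fixed seeds; their tolerances (3σ bands, χ²
p > 0.01, total-variation margins) account for the finite sample sizes.

## Known limitations

- Cost grows exponentially with the number of species through the box
  state spaces; the intended regime is few species with small counts.
- Fast dynamics inflate γ and hence the number of candidate jump times,
  slowing FFBS; very volatile or sparsely observed processes need many
  roulette terms for low-variance estimates (the sticking diagnostic
  flags this).
- The minimal-event initial trajectory requires every consecutive
  observation pair to be connectable by reactions inside the initial box;
  pathological observation sets raise an error instead of silently
  proceeding.
- `enumerate_reachable` guards against state-space explosion with a
  configurable hard cap and raises rather than truncating silently.
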