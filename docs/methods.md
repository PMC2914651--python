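# Methods

## Model

A reaction network of `M` reactions over `K` species is a Markov jump
process on molecule-count vectors `X = (x_1, ..., x_K)`.  Reaction `r`
converts reactants `U_r` into products `V_r` (non-negative integer
stoichiometries; the net-effect matrix is `A = V - U`) and fires with
hazard `h_r(X, θ)`.  Mass-action hazards use the binomial convention

    h_r(X) = θ_r · ∏_a C(x_a, u_ra),

which counts distinct reactant combinations; it reproduces `h = k·n_A`
and `h = k·P2·DNA` for unit stoichiometries and gives `θ·x(x−1)/2` for a
dimerization.  The alternative falling-factorial convention
(`θ·x(x−1)` for dimerization) is available as the model-level option
`convention="falling_factorial"`; the two differ only by constant factors
`∏_a u_ra!`, which are absorbed into the rate constant, so the choice is a
parameter-scale convention rather than a modeling assumption.  Custom
rate laws can be given as arithmetic expressions over species names and
the reaction's own `theta`; their θ-derivatives (needed for the score)
come from symbolic differentiation.

The probability of each count state evolves by the chemical master
equation (CME).  On a truncated state-space box the generator is a sparse
matrix whose exponential gives exact transition probabilities; the
package uses this only as a validation oracle on small systems
(`skm.gradient.cme_oracle`), never inside inference.  Probability leaving
the box is treated as lost, and the oracle refuses to answer when more
than `1e-8` of the mass leaks.

## Inference problem

The data are counts of a species subset Γ at discrete times
`t_1 < ... < t_m`.  The missing data on each interval is the full reaction
path Ξ = {(r_j, t_j)}: which reactions fired, in what order, at what
times.  The complete-data log-likelihood of one interval is

    log π(Ξ | θ) = Σ_j log h_{r_j}(X^{(j−1)}) − Σ_j h_0(X^{(j)}) Δt_j,

with `h_0 = Σ_r h_r` and `Δt_j` the dwell times between events.  Under
mass action this is an exponential family with per-reaction sufficient
statistics: the event count `n_r` and the integrated propensity
`G_r = ∫ h_r(X(t)) / θ_r dt` (θ-independent).  The score of the observed
data is the conditional expectation of the complete-data score,

    ∂ log L / ∂θ_r = E[ n_r ] / θ_r − E[ G_r ],

with the expectation over latent paths conditioned on all observations.

## Path sampler

Paths conditioned on endpoint counts live in spaces of varying dimension,
so the sampler is a reversible-jump MCMC whose move alphabet comes from
the *null set*: all support-minimal, componentwise-minimal non-negative
integer vectors `q` with `Ã^T q = 0`, where `Ã` keeps the observed
columns of `A`.  Firing a whole mode leaves every observed count
unchanged.  Enumeration is exhaustive over coefficients `0..cap`
(default 4) — correct and fast for the network sizes in scope, and
checked against a brute-force oracle in the tests.  "Independent" is read
as support-minimality plus componentwise minimality, the standard
elementary-mode semantics; this collapses multiples such as `2·(R1+R2)`
onto the primitive mode.

Moves on one interval, with `α_1 = α_2 = 0.25`:

1. **add** a uniformly chosen mode `q` (probability α_1), its `Q` new
   events at i.i.d. uniform times;
2. **delete** a uniformly chosen combination of existing events matching
   `q`'s type counts (probability α_2);
3. **shuffle**: redraw all event times i.i.d. uniform, keeping the type
   multiset (remaining probability).

Detailed balance fixes the acceptance ratios.  For the add move with
current per-type counts `r_j`:

    AR_1 = π(Ξ')/π(Ξ) · (α_2/α_1) · τ^Q / ∏_j [ q_j! · C(r_j+q_j, q_j) ],

because the forward density of the new order statistics is
`∏_j q_j!/τ^{q_j}` and the reverse deletes one of
`∏_j C(r_j+q_j, q_j)` combinations; the delete move is the exact
reciprocal and the shuffle is symmetric.  A proposal that would fire a
reaction without sufficient reactants, or leave a type count negative,
has likelihood zero.  These ratios were validated two independent ways:
analytically (the sampler's stationary law on a single zero-net-effect
reaction reduces to the correct Poisson path measure) and
distributionally (total-variation distance below 0.05 against a
rejection-SSA oracle on endpoint-conditioned birth-death intervals; see
the test suite).

**Initial paths.**  Per interval, the smallest per-reaction count vector
consistent with the observed change solves an integer program
(`scipy.optimize.milp`, with a pure-Python iterative-deepening search as
a no-dependency fallback; the two agree on random instances in tests).
In the partially observed case the objective weights each reaction by
one plus the hidden molecules it moves, preferring explanations that
leave hidden species alone — per-interval minima chosen blindly would
otherwise drain a finite hidden stock (a bound promoter, say) across the
window and strand the construction in an infeasible state.
The event *order* is found by shuffle plus local repair (push a violating
event past the earliest later event that replenishes the deficient
species); if no ordering of the minimal counts is feasible, one
elementary mode is added and the search retried.

**Fully observed data** make intervals conditionally independent; one
chain runs per interval (a sweep is one proposal per interval).

**Partially observed data** correlate neighboring intervals through the
hidden components.  A mode that changes the hidden state at an interior
time `t_{i+1}` is paired with the complementary move (add↔delete of the
same mode) on interval `i+1`, started from the shifted state, which
restores the full state at `t_{i+2}`; the pair is accepted jointly.  The
complementary move is forced rather than chosen, so no α-ratio enters its
Hastings term.  The last interval's end state moves freely, and an extra
per-sweep step shifts the hidden state at `t_1` while keeping the end of
interval 1 fixed (add a mode and shift the start by `−A^T q`, or the
mirror).  A per-sweep *level-shift* move additionally proposes
translating the entire hidden trajectory by one mode's net effect
(`x(t_1) ← x(t_1) ± A^T q` with all events kept, which shifts every state
at every time); the proposal is symmetric, so the acceptance is the plain
likelihood ratio over all intervals.  This move exists because the
overall level of the hidden field is its slowest mode — pair moves change
it one time point at a time, a diffusive crawl across the whole window —
while the level move equilibrates it within a few sweeps.

Hidden states at `t_1` are initialized uniformly: conserved groups
(e.g. DNA + DNA.P2 = DNA_t) by a uniform composition of the known total,
other hidden species uniformly on `[0, hidden_cap]` (default 10);
infeasible draws are retried.  Several candidate initializations are
scored by their complete-data likelihood (each at its own refined rates)
and the best is kept, sparing the chain a long random walk from an
unlucky draw.  The implicit prior over the hidden start state is flat, so
hidden species should either appear in a known conserved total or feed
back on observed dynamics — otherwise the smoothing problem is improper
and the chain will (correctly) wander.  The sampler was validated against
an exhaustive truncated-CME forward-backward smoother on a two-copy
gene-switch toy model (TV < 0.05 on the hidden-state marginal).

For mass-action networks the path evaluator (replay, validity check,
log-likelihood and integrated propensities in one pass) is compiled with
numba; networks with custom rate laws use a vectorized numpy
implementation, and the two are cross-checked on random paths in the
tests.

## Gradient estimation

Each sweep contributes one sample of `(n, G)` summed over intervals; the
score estimate is the sample mean of `n_r/θ_r − G_r`.  Naive standard
errors of the mean ignore chain autocorrelation, so the ascent driver
uses batch-means standard errors (20 batches by default), which are
robust to correlation up to the batch length.  For custom (non
mass-action) rate laws `G_r` generalizes to `∫ ∂h_r/∂θ_r dt` via the
symbolic derivative.

## Stochastic gradient ascent

Iteration `t`: re-sample paths at `θ_t` (the chains warm-start; paths
stay valid when θ changes and the per-iteration burn-in re-equilibrates
them), estimate the score, and update
`θ ← θ · (1 + rel)` with a per-parameter relative step

    rel_r = clip( m_r · tanh(z_r / 3) · max(|n̄_r/(θ_r Ḡ_r) − 1|, η) ).

The three factors, and why each exists:

* `n̄_r/(θ_r Ḡ_r) − 1` is the relative step to the sampled complete-data
  MLE `n̄_r/Ḡ_r` — a Newton-type scale in `log θ` (the complete-data
  expected information in `log θ_r` is `θ_r G_r`).  It gives large, safe
  jumps where the data are informative.  Its floor `η` (default 0.1)
  keeps the iteration moving across nearly flat stretches of the
  likelihood, where the magnitude alone would stall.
* `m_r` is a sign-persistence multiplier (×1.3 after two same-sign
  gradients, ×0.5 on a flip, clipped to [0.1, 5]): a trend detector that
  accelerates consistent descent and damps oscillation around a maximum.
* `tanh(z_r/3)`, with `z_r` the batch-means t-statistic of the gradient,
  scales the step by how confidently the gradient differs from zero, so
  steps shrink — and the convergence criterion below can fire — only when
  the score is statistically indistinguishable from zero.

Steps are clipped to (−0.9, +2.0) per iteration and θ is floored at
`theta_floor` (1e−6).  Convergence is declared when the largest relative
change stays below `rel_tol = 0.005` on two consecutive iterations — two,
because a single quiet iteration can be a lucky Monte-Carlo draw.

**Initialization refinement.**  Before any sampling, θ is set to the
complete-data MLE `(n_r + ½)/G_r` of the integer-programming initial
paths (the half-count covers reactions absent from the minimal paths).
The rationale is a real feature of these likelihoods: in the joint scale
of the rate constants, far above the data-supported region, the
likelihood is extremely flat — observations at spacing Δt cannot
distinguish "fast dynamics equilibrating between observations" from
"very fast dynamics equilibrating between observations".  Gradient
estimates there are statistically zero at any affordable sample size, so
an ascent started at an arbitrary large scale stalls on this plateau.
The minimal-path MLE starts the ascent at (or below) the data-supported
scale, where the score is strong, turning an unreliable 50+-iteration
crawl into a reliable sub-20-iteration climb.  It can be disabled with
`SGDConfig(init_from_path=False)`, which reproduces the plateau behavior.

## Benchmarks and the synthetic-data generator

`skm.fixtures` builds the two benchmark systems and regenerates
observation datasets by exact SSA simulation — datasets are always
regenerated from seeds, never stored.

* **Birth-death**: `R1: A→∅` (rate `k1·n_A`), `R2: ∅→A` (rate `k2`);
  defaults `(k1, k2) = (0.03, 0.6)`, 21 observations at spacing 2
  (window T = 40).  The start state defaults to the stationary mean
  `round(k2/k1) = 20`, a definite reproducible choice the original
  design leaves open.
* **Auto-regulatory gene network**: 8 reactions, 5 species, true rates
  `(0.1, 0.7, 0.35, 0.3, 0.1, 0.9, 0.2, 0.1)`, DNA_t = 10 copies,
  window [0, 50) at spacings 1.0 to 0.1; the partially observed variant
  keeps only mRNA, P and P2 and treats DNA_t as known.  The start state
  defaults to all DNA unbound with no transcripts or protein,
  `(DNA_t, 0, 0, 0, 0)`; recovery experiments are insensitive to this
  after the initial transient.

What the generator emulates: exact jump-process trajectories observed
without error on an arithmetic time grid.  What it does not: measurement
noise, cell-to-cell variability, model misspecification, or irregular
sampling — passing tests therefore demonstrate correctness of the
inference machinery under the model, not robustness on real data.

**Problem sizes used in the shipped experiments.**  The test suite and
the acceptance script run the birth-death design at full scale
(m = 21, Δt = 2, 1000 samples / 100 burn-in per gradient, five replicate
datasets) and the gene network at a desk-scale design (Δt = 0.5, window
[0, 25), 2000 samples / 200 burn-in), where the average parameter error
is required to stay under 30%; the finer Δt = 0.1, [0, 50) design
sharpens the same estimates and can be run through the CLI or
`BenchmarkSpec` directly.

## Numerical choices and degenerate inputs

* Counts are exact integers throughout; hazards and likelihoods are
  floating point; `−inf` encodes invalid paths.
* Event-time ties have probability zero; uniform draws are re-sorted and
  a defensive resample guards the (never observed) exact-tie case.
* Observation sampling convention: an event at exactly an observation
  time is ordered before the observation.
* All randomness descends from a single seed through
  `numpy.random.SeedSequence` spawning, so runs are bit-reproducible.
* An SSA event cap (10^7) turns hazard explosions into a clear error.
* `find_reaction_counts` re-verifies `Ã^T r = Δ` on every call.

## Known limitations

* The flat-scale plateau described above is a property of the
  likelihood, not of the implementation; without the initialization
  refinement, runs started far above the data-supported scale can
  satisfy the relative-change criterion on the plateau.
* Sampler mixing degrades on intervals containing many events (sparse
  observations of fast dynamics): the total event count random-walks in
  steps of one mode.  Denser observations or larger sample sizes are the
  remedy, mirroring the benchmark results, where finer observation
  spacing gives markedly better estimates.
* Hidden species without feedback on observed dynamics (and outside any
  known conserved total) have improper smoothing distributions; the
  sampler cannot fix an unidentifiable model.
* With hidden species and coarse observation spacing, the maximum
  likelihood estimates of reversible-pair rates (binding/unbinding,
  dimerization/dissociation, translation/degradation) scatter widely
  across datasets: the number of within-interval round trips is latent,
  so only the pair ratio is sharply identified.  On the gene-network
  benchmark at spacing 0.5 the per-dataset average error of the exact
  optimum itself is commonly 25–45% — score checks against long chains
  confirm the optimizer reaches the optimum; the scatter is a property
  of the data design, and finer spacing is the remedy.
* Elementary-mode enumeration is exponential in `M` and intended for
  networks of up to ~20 reactions.
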