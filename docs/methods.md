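# Methods

## Model and estimand

A subject moves among states `ℋ = {1, …, H}` according to a continuous-time,
time-inhomogeneous Markov process whose allowed direct transitions form a
directed acyclic graph (no loops: once a state is left it cannot be
revisited; without this, a nonparametric estimator cannot pin down the
number of visits).  The targets are the cumulative transition intensities
`A_gh(t)` and, through product integration, the transition probability
matrices `P(s,t) = ∏_(s,t] (I + dA(u))`.

Observation is by panel: subject `i` is seen in state `x_ij` at visit times
`t_i0 < t_i1 < … `, assumed to follow a conditionally independent visit
process (the next visit time may depend on everything observed so far but
not on the path since the last visit).  The last visit acts as an
independent right-censoring time.  Optionally, a fixed known subset `ℰ` of
states is *exactly observed*: seeing `x_ij ∈ ℰ` at `t_ij` means entry
happened at exactly `t_ij`.

Following the two-state theory, where the NPMLE can place mass only between
neighbouring observation times, estimation is restricted to step functions
jumping at the sorted unique visit times `τ_1 < … < τ_K`; the free
parameters are the jumps `α_ghk ∈ [0,1]`, interpreted as conditional
one-bin transition probabilities, constrained to
`C_α = {α_ghk ≥ 0, Σ_h α_ghk ≤ 1}`.  Only the total jump mass per *support
interval* (runs of bins between informative observations) is identified;
pointwise values of `Â_gh(t)` inside a support interval are a convention
(mass at right bin endpoints, matching the right-continuous step form).
This matters when interpreting bias at a fixed `t` (see Limitations).

## EM algorithm

The complete-data log-likelihood (Poisson-style approximation of the
multinomial one-bin likelihood) is
`ℓ_C = Σ_k Σ_(g,h) d_ghk log α_ghk − α_ghk Y_gk` with `d_ghk` transition
counts and `Y_gk` at-risk counts per bin.

**E-step.**  For each subject and bin, with `(l, r]` the enclosing
observation interval and `a, b` the states at its ends, the conditional
expectations are ratios of products of the current `P̃` matrices, e.g.

    E[d_gh,ik] = P̃_ag(l, τ_{k-1}) α̃_ghk P̃_hb(τ_k, r) / P̃_ab(l, r).

When `b ∈ ℰ` with entry at `τ_kr = r`, the expectations instead condition on
the entry coming from a direct predecessor `m` of `b` occupied at
`τ_{kr−1}`, replacing the backward factor by
`Σ_m α̃_mb,kr P̃_hm(τ_k, τ_{kr−1})` and the denominator by
`D = Σ_m α̃_mb,kr P̃_am(l, τ_{kr−1})`.  At the terminal bin itself the
subject contributes `P̃_am(l, τ_{kr−1}) α̃_mb,kr / D` to both `d_mb,kr` and
`Y_m,kr` for each predecessor `m` — the entry must be an `m → b` jump at
`τ_kr` and the subject is at risk in the predecessor it occupies.  This
terminal-bin factorization is validated by monotonicity of the exact-state
observed-data likelihood across EM iterations in the test suite.

**M-step** (closed form over `C_α`): `α_ghk = d_ghk / Y_gk` when the
multiplier `μ_gk = max(0, Σ_h d_ghk − Y_gk)` is zero, else
`d_ghk / Σ_h d_ghk`.  Since per-subject transition probabilities never
exceed occupancy probabilities, `Σ_h d_ghk ≤ Y_gk` holds mathematically and
`μ > 0` can only arise from rounding.

**Stopping rules.**  Three criteria are provided: `intensity` (largest
absolute change in any jump below `tol`, default `1e-4`), `likelihood`
(absolute change in the observed-data log-likelihood below `tol`), and
`kkt`.  The KKT reduced gradient `∇_ghk = d_ghk/α̃_ghk − Y_gk − μ_gk`
(zero coordinates never block: `d = 0` whenever `α̃ = 0`, and zero jumps are
absorbing under EM) vanishes exactly at an M-step fixed point and is
reported per iteration and at the final estimate.

A practical caveat the package surfaces deliberately: the per-iteration
intensity change is **not monotone** along EM trajectories.  On
realistically sized panels it can dip below a loose tolerance (e.g. `1e-3`)
hundreds of iterations before the slow modes (jumps in sparsely-at-risk
bins crawling toward their limits) have finished, then rise again.  The
`intensity` criterion therefore stops at the first crossing — matching its
plain definition — and the reported `max_reduced_gradient` tells the user
whether the stop was premature; the `kkt` criterion is the reliable
certificate.  Iteration counts under the intensity rule are accordingly
implementation-sensitive and should not be compared across packages.

## Implementation notes

* Each EM iteration costs `O(Σ_i K_i · H²)`: per observation interval, a
  backward sweep accumulates `P̃(τ_k, r)`-type vectors and a forward sweep
  accumulates `P̃(l, τ_{k-1})` rows, so no per-bin matrix product over the
  whole grid is ever formed.  The kernel is JIT-compiled with numba when
  available, with an identical pure-Python fallback.
* The observed log-likelihood is a by-product of the same sweeps; an
  independent naive evaluator (plain ordered matrix products) cross-checks
  it in the tests.
* Probabilities are clamped nowhere; a subject interval whose probability
  underflows below `1e-300` raises `ZeroPathError` naming the subject, never
  silently yielding NaN.
* Initialization is uniform `α̃ = 1/K` on allowed transitions (strict
  positivity is required because zeros are absorbing).  On degenerate grids
  with `K ≤` the number of exits of some state, `1/K` per exit would give a
  state exit mass of 1 and zero probability to every staying path, so the
  init is capped at `0.9 / #exits`; on any realistic panel (`K ≫ H`) the
  init is exactly `1/K`.  User inits with zeros trigger a warning.
* `Y_gk = 0` (empty risk set) yields `α_ghk = 0`, not NaN.
* Row-stochasticity and the `C_α` constraint are enforced to `1e-10` at
  every M-step (construction-time validation).
* Grid convention: `τ_0` is the earliest first visit (0 in all presets);
  the grid is the set of unique post-baseline visit times; bin `k` is
  `(τ_{k-1}, τ_k]`; `P(s,t)` multiplies bins with `s < τ_k ≤ t` and is
  defined for arbitrary (non-grid) `s ≤ t`.

## Synthetic-data generator

The simulator emulates six (extended) illness-death designs over a 15-year
study: all subjects observed at time 0; cause-specific hazards exponential
(rates 0.1, 0.05, 0.1) or Weibull with survivor `exp(−λ t^k)` calibrated so
mean transition times match the exponential designs (10, 20, 10 years:
shapes 0.5/0.5/2, rates `1/√5`, `1/√10`, `Γ(1.5)²/100`); starting state
either fixed (healthy) or uniform on the two transient states; visit
processes renewal with `U[0, 4.4]` gaps (about 6–7 visits), denser/sparser
variants `U[0, 2.44]` / `U[0, 7.33]`, or a fixed panel at `3j ± U(0, 0.1)`
years; administrative censoring at 15 years; in the extended design both
death states are exactly observed.  Hazards are functions of study time
(`clock="forward"`), keeping the process Markov and making
`A_gh(t) = λ t^k` the exact truth; a `clock="reset"` semi-Markov option
exists for robustness experiments but has no Markov truth and is rejected by
the evaluation module.  Per-subject RNG substreams derive from
`(seed, subject index)`, so enlarging a study never reshuffles existing
subjects.

What the generator does *not* emulate: covariate-dependent hazards,
informative (state-dependent) visiting, missed visits/dropout other than the
administrative horizon, measurement error in the recorded state, and tied
visit times across subjects (times are continuous, so every visit creates a
grid point).  Passing tests on these panels therefore demonstrate
correctness of the estimator under its stated assumptions, not robustness to
their violation.

## Evaluation

Replicate studies fit `N` independently simulated panels and summarize, per
transition and time on a 0.1-year grid, `bias(t)`, unbiased `var(t)` and
`rmse(t) = √(var + bias²)`, reading estimates as right-continuous step
functions; transition-probability metrics compare product-integrated
estimates against a Kolmogorov-forward ODE solution of the true intensity
matrix (adaptive RK45 at tolerance 1e-10, with the Weibull shape-0.5
singularity at `t = 0` clamped at `1e-14`, an error of order `λ·10⁻⁷`).
Failed replicates (`ZeroPathError`) are dropped and counted, and replicate
results are cached per derived seed so long studies resume.

Problem sizes used by the shipped tests and acceptance script: oracle
comparisons on 50 two-state panels (n = 28, K ≤ 20) and 20 tiny multistate
instances (H ≤ 3, K ≤ 3, n ≤ 4); recovery and iteration-count studies on
the illness-death designs at n = 100–500 subjects with 10–25 replicates.
These sizes make the whole suite run in minutes on one core while leaving
Monte-Carlo bands tight enough to be informative.

## Known limitations

* Pointwise cumulative-intensity values are only identified up to support
  intervals; with ~2.2-year mean visit gaps and hazard level 0.1 this
  smears `Â(t)` by a few hundredths at fixed `t`, which replicate studies
  resolve as a small nonzero "bias" even when the mass per support interval
  is recovered correctly.
* Small risk sets (states not covered at baseline; late study times) make
  individual jumps erratic — a feature of the NPMLE, mitigated by reading
  slopes or transition probabilities from well-populated states.
* No confidence intervals: the NPMLE's nonstandard (`n^{1/3}`) pointwise
  asymptotics under continuous visiting make analytic intervals unavailable
  and bootstrap is computationally heavy; variance estimation is out of
  scope.
* No covariates, no truncation, no state-set ("known to be in one of
  several states") observations, and no smoothing of the jumps.
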