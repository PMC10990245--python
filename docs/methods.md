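# Methods

## The task

Two "casinos" (environments), each a two-armed bandit with anticorrelated
binary rewards: on every trial exactly one machine pays. The agent
alternates between casinos trial-by-trial within a block in a *balanced
random permutation* — each block of `T` trials contains exactly `T/2`
trials of each casino. With balanced permutations the pooled distribution
of maximal same-casino run lengths converges to the geometric law
`P(len = k) = 2^-k` as sequences accumulate, so about 50% of runs have
length 1 and about 25% length 2.

One casino is **stable**: the currently-better machine keeps its reward
probability (0.75 or 0.80, configurable; both appear in the shipped
experiment designs) for the whole block. The other is **volatile**: the
better machine pays with probability 0.90 and the contingency reverses
every 16–24 within-casino trials (iid uniform gaps, including the gap
before the first reversal). The **test** design runs both casinos at 0.85
with exactly two reversals per block, spaced 29–37 within-casino trials
apart; gaps are drawn the same way but the reversal count is capped at two,
because uniform gaps alone would produce a third reversal in a sizable
fraction of 100-trial streams. Each block introduces a fresh machine pair
per casino; which machine starts as the better one is a fair coin flip.

Shipped designs: `exp1` = learning 2×240 (stable 0.75) plus a control
phase 1×240 with two stable 0.75 casinos; `exp2` = learning 4×200 (stable
0.80); `exp3` = learning 3×200 plus the test phase 1×200.

The generator never produces missing responses; the CSV reader accepts
rows with empty choices and the modelling code skips them (no likelihood
contribution, no value update).

## The models

Six Rescorla-Wagner variants, crossing learning-rate kind
({single, dual, variable}) with environment specificity (shared vs one
parameter copy per casino):

- delta rule: `Q_{t+1} = Q_t + α (r_t − Q_t)`, `α ∈ [0,1]`, rewards
  `r_t ∈ {0,1}`, Q initialised at 0;
- dual rule: `α⁺` after rewarded, `α⁻` after unrewarded trials;
- variable rule: the effective rate itself is learner state,
  `α_{t+1} = η |r_t − Q_t| + (1−η) α_t`, with a higher-order rate
  `η ∈ [0,1]`; the free parameter α is the rate at `t = 0`;
- softmax choice: `p(a) = exp(βQ^a) / (exp(βQ^a) + exp(βQ^b))`,
  `β ∈ [0,10]`.

State rules, where the design leaves room:

- Q-values are tracked per machine pair (casino × block) and reset to 0 at
  block boundaries, because every block introduces new machines.
- The variable learning rate is learner state, not machine state: it
  persists across blocks within a phase and initialises to α at the first
  trial governed by its parameter cell. In the environment-specific
  variable model each casino's rate updates only after trials in that
  casino; in the shared model one rate updates after every trial.
- Only the chosen machine's value is updated; the equations reference only
  the chosen action's Q, and no counterfactual update is assumed despite
  the anticorrelated rewards.
- Non-environment-specific models share parameters across casinos but
  still carry separate Q pairs per casino (four machines per block).

Useful reductions (tested bit-for-bit): dual with `α⁺ = α⁻` and variable
with `η = 0` reproduce the single-rate likelihood exactly.

## Hierarchical estimation

For each parameter cell (phase × environment; per block in block-wise
fits), individual parameters are non-centred:

    θ_ij = lo_j + (hi_j − lo_j) · Φ(μ_j + σ_j z_ij),   z_ij ~ N(0,1)

Priors: uniform on the bounded scale for group means — equivalently a
standard normal on the probit scale, which is how it is implemented — and
half-Cauchy(0, 5) for group SDs (positive half, sampled on the log scale
with the Jacobian). Group-mean contrasts are computed on the bounded scale
(`probit(μ)`), since reported group means live there.

Sampling is adaptive Hamiltonian Monte Carlo written for this package:
leapfrog integration with a diagonal mass matrix estimated in warmup
windows, dual-averaging step-size adaptation to a 0.8 target acceptance
rate, and trajectory lengths jittered uniformly over the upper half of the
nominal length (default 2.4 time units, capped at 64 leapfrog steps) to
avoid resonances. Gradients of all six likelihoods are hand-derived
forward-mode recursions through the Q-value (and variable-rate) dynamics,
compiled with numba; they agree with finite differences to ~1e-5 in tests.
Divergent transitions (energy error > 1000) are counted and reported.
Default sampling: 4 chains × 4000 iterations with 1000 discarded as
burn-in, i.e. 12,000 retained draws; convergence is flagged when any
split Gelman-Rubin statistic (via arviz) reaches 1.1. Same seed, same
data ⇒ identical draws.

A one-tailed posterior probability is the fraction of matched draws with a
strict inequality (`a > b`); ties count against the contrast. A value
above 0.95 corresponds to a one-tailed p < 0.05.

Block-wise analyses default to one joint model with block-specific group
distributions (cells `(block, environment)`), rather than independent
per-block refits; with environment-specific models the two coincide
trial-wise because Q-values reset at block boundaries anyway. Phases are
always fitted separately.

## Model comparison

Pointwise log-likelihoods (one observation per trial) feed
Pareto-smoothed importance-sampling leave-one-out (arviz). The table
reports elpd under the label "LOOIC" (higher is better), its SE, the
difference to the top model and the SE of the pointwise differences; a
difference is *decisive* when it exceeds twice its SE. Pareto-shape values
above 0.7 are counted and reported, never silently repaired.

## Simulation studies

**Reward-rate grids.** Mean reward per parameter cell over independently
simulated single-casino blocks (default 120 within-casino trials per
replicate, fresh schedule each replicate). The full single-rate grid
crosses α ∈ {0.01…0.99} with β ∈ {0.1…9.9}; the dual grid crosses
α⁺ × α⁻ with β fixed at 4 (the typical fitted value). Common random
numbers are shared across cells so between-cell comparisons are less
noisy. The number of replicates per cell is a free knob (the source
studies do not state one). "Smoothed" copies are a 3-cell moving average
used only for presentation; every assertion uses raw cells.

**Model recovery.** Datasets are simulated from each of the six models
with group means 0.4/0.6 (stable/volatile learning rates), 3.5/4.5
(inverse temperatures), 0 (higher-order rates) — 0.5/4/0 for shared
models — and SDs 0.2/2/0.1. Individual values are drawn from normals
*truncated to the parameter bounds* on the bounded scale (a mean of 0 for
η forces either truncation or clipping; truncation is the cleaner
density). All six models are fitted to every dataset and ranked by elpd;
the recovery matrix tabulates top-rank frequencies. The reference design
is the exp1 learning phase (36 participants, 2 blocks × 120 trials per
casino); the shipped tests run a reduced version (fewer datasets,
participants and iterations) chosen to exercise the same pipeline at
minutes scale, and assert row-wise diagonal dominance rather than the
full-scale frequencies.

**Parameter recovery.** Per environment, group-mean combinations
α⁺ × α⁻ ∈ {0.2,0.4,0.6,0.8}² × β ∈ {2,4,6,8} each yield one simulated
dataset which is refitted with the dual model; true individual values are
pooled across combinations and correlated with individual-level posterior
means. Master seeds split into per-dataset seeds via
`SeedSequence.spawn`, so studies replay exactly.

**Posterior predictive check.** For each retained joint posterior draw, a
full choice sequence is re-simulated conditional on the participant's
trial sequence; reward rates are averaged over draws and correlated with
observed rates across participants, per environment.

## What the synthetic data do and do not show

The generator reproduces the trial economy of the experiments — balanced
casino alternation, anticorrelated probabilistic rewards, reversal
schedules, fresh machine pairs — and simulated agents drawn from the
fitted-scale populations. It does not emulate response times, missed
deadlines, attention lapses, practice effects, or any within-participant
non-stationarity beyond what the models themselves generate. Passing
recovery tests therefore show the *pipeline* is sound (the design
identifies models and parameters when the model family is true), not that
human data satisfy the model assumptions.

## Numerical choices and limitations

- Softmax computed with max-subtraction; Q-values stay in [0,1] by
  construction, so no further guarding is needed.
- Probit maps use `erfc`; extreme raws saturate harmlessly at the bounds
  with vanishing gradient.
- HMC is a fixed-trajectory sampler, not NUTS; on strongly funnel-shaped
  posteriors (tiny group SDs with few participants) mixing slows and
  R-hat flags it. Short-chain fits can show Pareto-k warnings in LOO;
  these are reported in the comparison table.
- Problem sizes in the shipped test suite are deliberately reduced
  (participants, datasets, chain lengths); the full-scale settings remain
  available as the defaults of the study functions and the `exp*`
  profiles.
- t-tests in the behavioural module are one-tailed in the direction of
  the stated hypotheses; the exclusion chi-square is the two-sided
  statistic with a directional (rate > 0.5) requirement, and lose-switch
  pairs never span block boundaries (new machines each block).
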