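# Methods

This note documents the models, the estimation machinery, the synthetic-data
generator and the numerical choices behind `revlearn`, including the places
where the design was genuinely open and a choice had to be made.

## Task model

The probabilistic reversal learning environment presents two stimuli, A and
B. The currently correct stimulus wins with probability 0.75 and loses with
probability 0.25; the other stimulus has the mirrored contingency. The
engine's assumptions:

- **"Consecutive correct" counts choices of the currently correct
  stimulus**, not rewarded trials. Probabilistic feedback means a correct
  choice can lose; a reward-based counter would contradict the idea of a
  performance criterion.
- The reversal criterion is drawn uniformly from {5, 6} independently for
  each episode, so reversals cannot be anticipated. The run counter resets
  to 0 after a reversal (and also when a completed run cannot trigger a
  reversal because the cap was reached, since the run is over either way).
- At most 10 reversals occur; afterwards the contingency stays fixed. An
  always-correct agent at criterion 5 could complete 12 runs in 60 trials,
  so the cap binds only in that extreme corner.
- Outcomes are coded +1 (win) / −1 (loss) internally regardless of the
  on-screen currency amounts.
- Timing fields (1,500 ms response window, 500 ms highlight, 500–1,500 ms
  outcome delay, 1,000 ms outcome display, 500–1,500 ms ITI) are metadata;
  the simulation never waits. Their expected per-trial sum, with uniform
  delays entering at their midpoints, is 5,000 ms.
- Simulated agents always respond; the `responded` flag and the 1,500 ms
  non-response convention exist for importing real data.

## Learning model

Per trial, for the chosen stimulus only:

    PE_t = R_t − EV_{t−1}
    EV_t = EV_{t−1} + α · PE_t,   α = α+ if PE_t > 0 else α−
    P(A_t) = logistic(β · (EV_A − EV_B))

Choices of the model's conventions:

- **PE = 0 uses the punishment rate** (the "worse than or equal to
  expectation" branch).
- **The unchosen stimulus's value is carried forward unchanged** — no decay,
  no fictive update. This is the minimal three-parameter model; reward and
  punishment sensitivity scaling, forgetting, and perseveration kernels are
  deliberately out of scope.
- Values start at 0 for both stimuli, so the first-trial choice probability
  is exactly 0.5 and values stay inside [−1, 1] forever (convex-combination
  bound with ±1 outcomes).
- Likelihood: iterate trials, accumulate `log P(chosen)` under the current
  values, then update with the observed outcome. Computer-selected choices
  on non-response trials enter the likelihood by default (keeping all 60
  trials defined); a `censor_nonresponse` flag drops them from the sum while
  still updating values, since the participant did observe the outcome.
- Numerical safety: choice probabilities are floored at 1e−12 before logs.
  This only matters for extreme-β proposals during sampling and changes no
  realistic likelihood by a measurable amount.

A consequence worth knowing when interpreting simulations: **accuracy is not
monotone in β** on this task. Reversals are performance-contingent, so
near-greedy agents trigger reversals as fast as possible and pay ~3 error
trials relearning after each one; mean accuracy rises with β up to roughly
β ≈ 1.5 and then declines (measured ≈ 0.50 / 0.56 / 0.61 / 0.52 at
β = 0 / 0.3 / 1.5 / 6). The achieved reversal count, by contrast, is
monotone in β throughout, which is why it is the cleaner behavioural index
of adaptive learning here.

## Hierarchical Bayesian estimation

Unconstrained per-participant triples θ_i are transformed to native scale by
α = Φ(θ), β = 10 · Φ(θ) (probit transform with a β ceiling of 10, far above
the plausible range for this task). The hierarchy, on the unconstrained
scale:

    θ_ik ~ Normal(μ_k, σ_k)
    μ_k  ~ Normal(0, 1)
    σ_k  ~ half-Normal(0.2) for the learning rates, half-Normal(1) for β

These priors follow the conventions of the hierarchical-RL modelling
literature for this model class.

**Sampler.** The posterior is explored with an adaptive
Metropolis-within-Gibbs scheme, exploiting the fact that the likelihood
factorises over participants:

1. each θ component gets a per-participant random-walk Metropolis update,
   executed for all participants in one vectorised likelihood pass
   (compiled with numba when available), with per-participant step sizes
   adapted toward 44% acceptance during warmup;
2. each group mean μ_k is redrawn exactly from its conjugate normal
   conditional;
3. each group scale σ_k is slice-sampled on the log scale;
4. **interweaving:** each (σ_k, μ_k) pair is then re-updated in the
   non-centered parameterization — holding the standardized individual
   effects (θ − μ)/σ fixed — with a slice-sampling update for log σ_k
   against the full likelihood and an adaptive Metropolis step for μ_k.

Step 4 is essential: with only 60 trials per participant the learning rates
are weakly identified individually, the posterior develops the usual funnel
at small group scales, and the centered conditionals alone leave the scale
parameters with effective sample sizes in the single digits. The
ancillarity–sufficiency interweaving raises their mixing by more than an
order of magnitude at roughly twice the per-sweep cost.

Chains start from jittered overdispersed points; one top-level seed fans
out deterministically to per-chain seeds via `numpy.random.SeedSequence`.
Convergence is assessed with rank-normalized split R-hat (arviz) on every
sampled quantity — all individual native-scale parameters, the native-scale
group locations Φ(μ), and the group scales — against a threshold of 1.01.
A failed check emits a `ConvergenceWarning`, never an error.

**Problem sizes.** The study-scale fit (95 participants × 60 trials) uses
4 chains × (1,000 warmup + 3,000 kept) sweeps, which yields minimum
effective sample sizes around 500 and maximum R-hat comfortably below 1.01
in repeated runs (~4 minutes on one CPU). Smaller exploratory fits in the
test suite use 2 chains × (400 + 400).

**MAP cross-check.** A non-hierarchical per-participant estimate maximises
the session log-likelihood plus independent Normal(0, `prior_scale`)
priors on the unconstrained scale (Nelder–Mead over random restarts). With
the default unit prior it is a weakly-regularised MAP; with a large
`prior_scale` it approaches the maximum-likelihood estimate and serves as
the unpooled reference point for verifying the direction of hierarchical
shrinkage.

## Synthetic cohort generator

The generator emulates the participant-level structure the regression layer
assumes. Defaults: 95 participants; hardship–income correlation −0.417;
standardized hardship → α− effect 0.24; native-scale group means
(α+, α−, β) = (0.72, 0.54, 1.36); four hardship items on a 1–5 Likert
scale with Cronbach's α ≈ 0.83 and a sum composite; income on a 1–7
ordinal scale with mean ≈ 3.6 and SD ≈ 1.6; age uniform on 18–20; gender
Bernoulli with 60% female.

Construction: a latent bivariate standard normal (Z_H, Z_I) drives the two
scales. Hardship items are Z_H plus independent item noise, cut at fixed
Gaussian-quantile thresholds whose category probabilities approximate the
reported item-level moments; income is Z_I cut into seven ordinal
categories the same way. True parameters are drawn on the unconstrained
scale, with the α− location shifted linearly in the standardized hardship
composite (or, optionally, in the housing-instability item alone, to
emulate subdomain-specific effects); α+ and β are independent of all
covariates.

**Calibration against the discretized scales.** Discretization attenuates
correlations and reliability, and the probit link plus the composite's
non-normality bias naive closed-form slope calibrations by several percent.
All three latent quantities — the item-noise SD, the latent (Z_H, Z_I)
correlation, and the hardship slope — are therefore solved numerically
(Brent's method) so that the *observed* discretized quantities hit their
targets, using a 100,000-draw calibration sample generated once from a
fixed internal seed. The calibration is deterministic, independent of all
user-facing seeds, cached per configuration, and costs ~0.2 s. With it, a
5,000-participant cohort reproduces r(hardship, income) ≈ −0.417,
Cronbach's α ≈ 0.83, and a standardized hardship → α− coefficient of
≈ 0.24 (on true parameters) within sampling error.

**Group scales.** The between-participant spread on the unconstrained scale
defaults to (0.30, 0.25, 0.30), i.e. native-scale SDs of roughly
(0.10, 0.10, 0.62). The β spread matches the reported sample; for the
learning rates the reported SDs of *estimated* parameters are heavily
shrunken posterior means (one printed value would imply an essentially
constant reward learning rate), so the generator uses a
literature-typical population spread instead — without it there would be no
between-subject signal for recovery studies to recover.

**Composite = sum of items** (range 4–20). The reported composite moments
are only consistent with a sum; standardization makes the choice immaterial
for standardized coefficients.

What the generator does **not** emulate: reaction times, non-response
trials, missing data, realistic demographic covariance beyond the stated
correlations, or any distributional feature of hardship beyond its first
two moments and reliability. Passing tests therefore validate the pipeline
mechanics and statistical calibration, not the behaviour of any real
population.

## Recovery and calibration benchmarks

- **Parameter recovery at study scale** (95 × 60, generator defaults): a
  pilot of 20 replicate cohorts, run before the thresholds were frozen,
  fixed the acceptance bounds for the truth-vs-estimate correlations. β
  recovers well (pilot range 0.75–0.88, mean 0.83); α− moderately
  (0.17–0.48, mean 0.33); α+ weakly (0.02–0.33, mean 0.20) — with 60
  trials and a modest true spread, single-session information about the
  reward learning rate is simply thin, and hierarchical shrinkage
  compresses what little there is. The acceptance checks assert
  correlations above 0.55 (β), 0.05 (α−), and −0.05 (α+), i.e. they
  verify the qualitative ordering the pilot established rather than
  pretending a precision the horizon cannot support.
- **Effect recovery**: regressing *true* α− on the covariates at n = 5,000
  recovers the standardized 0.24 within Monte-Carlo error. Regressions on
  *estimated* α− are attenuated (estimation noise in the outcome), which is
  expected and not treated as a failure.
- **Type-I calibration**: with the hardship effect set to 0, the full
  simulate → fit → regress pipeline's rejection rate for the hardship
  coefficient (uncorrected p < 0.05, α− model) is compatible with the
  nominal 5% over replicates. The shipped check uses 10 scaled-down
  replicates (40 participants, 2 short chains each) and binomial bounds; a
  25-replicate pilot measured a rate of 4% (1/25).

## Statistical layer

One-sample t-tests (with Cohen's d) are computed from summary statistics;
Pearson correlations use the t-transform for p-values and **Fisher-z 95%
intervals** (the interval method is a documented package choice — reported
intervals in the individual-differences literature are frequently
bootstrap-based and not reproducible from r and n alone). Standardized
regressions z-score every variable, including 0/1 gender, so all
coefficients read as standardized effect sizes; inference comes from the
standard OLS sampling distribution (statsmodels), VIFs from auxiliary
regressions, and the BH-FDR family is the hardship coefficient across the
three parameter models. Two-sided tests, α = 0.05 throughout.
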