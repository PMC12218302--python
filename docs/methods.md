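# Methods

`mediabo` implements a Bayesian-optimization (BO) loop for developing cell-culture
media: plan an initial space-filling design, measure, fit a Gaussian-process (GP)
surrogate, let an acquisition function plan the next batch, and repeat until the
model's predictions agree with the observations or the budget runs out. This note
records the model, its assumptions, the tunable parameters, and the design choices
made where the design was genuinely open.

## Design spaces

A campaign varies *factors*: continuous (e.g. glycerol % on [0, 10]), discrete
(pH ∈ {5.75, 6.0, 6.5}) or categorical (19 candidate carbon co-feeds). Continuous
and discrete factors are min–max scaled to [0, 1] internally so length scales are
comparable across factors whose raw ranges differ by orders of magnitude.
Discrete factors are modelled as continuous on their level span and snapped to
the nearest declared level at suggestion time; with three roughly equispaced pH
levels the snap error is at most half a level. Categorical factors are encoded as
indices in declaration order, which is stable across runs.

Linear equality constraints cover blend design: k media ratios with unit
coefficients summing to one are sampled *exactly* uniformly via a symmetric
Dirichlet(1, …, 1) draw. Any other linear equality system falls back to a
feasible point from linear programming followed by random bounded steps in the
constraint null space — feasible by construction, approximately uniform, and it
detects infeasible systems via the LP. Rejection sampling is not used because an
equality constraint is a measure-zero target.

A continuous factor can be declared `linked_to` a categorical factor (co-feed
concentration linked to co-feed type). The link is reporting metadata only; the
joint kernel below operates on the full (x, h) vector with no special coupling
term. A benchmark condition with *no* co-feed is represented as concentration 0
with an arbitrary co-feed type rather than as an extra "none" category: at zero
concentration the type cannot act, and keeping the category set to real
co-feeds keeps the overlap kernel's similarity structure meaningful.

## Surrogate model

Targets y are standardized (subtract mean, divide by sd of the current training
targets); the GP prior mean is zero on that scale. The covariance over an
encoded point z = (x, h) is

- continuous block: ARD Matérn, k_cont(x, x′) = m_ν(r) with
  r² = Σ_d (x_d − x′_d)²/θ_d², ν ∈ {1.5, 2.5} via the standard closed forms.
  ν defaults to 2.5 when categorical factors are present (the overlap kernel
  pairs with at-least-twice-differentiable continuous kernels) and to 1.5
  otherwise (the noisier all-continuous blend case). The general Γ/Bessel form
  is implemented as a numerical cross-check of the closed forms.
- categorical block: overlap kernel k_cat(h, h′) = (σ/c) Σ_i 1(h_i = h′_i),
  where c is the number of categorical variables. The indicator reads the
  printed difference form as equality ("categories that overlap").
- mixture: k(z, z′) = α·k_cat·k_cont + (1 − α)·(k_cat + k_cont), α ∈ [0, 1].
  α = 1 couples the continuous response to the category (each co-feed has its
  own surface); α = 0 is an additive shared trend plus category offset.
- an overall signal-variance multiplier σ_f² on the whole covariance. Target
  standardization alone cannot absorb amplitude, because the empirical sd of a
  *correlated* function draw underestimates its marginal sd; with amplitude
  pinned at 1 the likelihood compensates by shortening length scales. An
  explicit σ_f² (the `variance` every stock GP kernel carries) removes that
  bias; simulation with known length scales confirms recovery within a factor
  of two in ≥80% of seeds once σ_f² is free.

Measurement noise is *fixed*, never optimized: σ_i² is the unbiased sample
variance of the pooled control-experiment replicates across all iterations
including the contemporaneous one, computed on the raw target scale and
rescaled consistently with standardization. Pinning the noise to what controls
actually show prevents the optimizer from trading signal for noise on small
campaign datasets. A 1e−8 jitter is added to every Gram diagonal before
factorization so replicated controls (identical rows) stay numerically PSD.

Hyperparameters (θ, σ, α, σ_f²) maximize the log marginal likelihood by
multi-start bounded L-BFGS-B (10 restarts by default; closed-loop simulations
use 2–3). The first start is the default configuration — θ = 0.5 on the scaled
axes, σ = 1, α = 0.5, σ_f² = 1 — and the fit never returns a solution below
that start's likelihood. Bounds after scaling: θ ∈ [1e−3, 1e3],
σ ∈ [1e−6, 1e3], α ∈ [0, 1], σ_f² ∈ [1e−4, 1e4]. Training RMSE is logged on
every fit. Refitting with identical data and seed is bit-reproducible.

A one-hot-encoding (OHE) baseline — Matérn over [scaled continuous dims |
indicator coordinates] — is provided purely for accuracy comparisons against
the mixture kernel; it shares the fitting machinery.

### Convergence

A campaign is declared converged when, for at least 80% of the latest batch,
|observation − posterior mean| ≤ 2·(posterior sd + measurement sd). Both the
multiplier and the fraction are configurable; they are stated defaults of this
package, not externally fixed ground truth.

## Acquisition

All acquisition is maximization; minimization targets are negated at the
objective boundary.

- **UCB**: mean + κ·sd, κ default 2.0 (configurable).
- **Maximization**: unconstrained continuous spaces use multi-start L-BFGS-B on
  the scaled cube; constrained spaces use trust-region iterations restricted to
  the feasible affine slice, followed by an exact projection of the constrained
  block so residuals vanish to 1e−6; mixed categorical–continuous spaces use a
  brute-force screen of 10 000 Latin-hypercube/uniform candidates and take the
  argmax (ties → lowest candidate index).
- **Thompson sampling**: one joint posterior sample path per batch slot over a
  fresh candidate screen, argmax per path. Joint sampling is cubic in screen
  size, so Thompson uses its own screen (default 512) rather than the 10 000
  brute-force screen; at 512 candidates the screen resolution, not the sampler,
  limits suggestion precision, which is adequate during the exploration phase
  it serves.
- **EXP3 bandit over categories**: during early iterations of a mixed-space
  campaign, each batch slot's category is drawn by probability matching from
  EXP3 weights (γ-uniform mixture keeps every arm alive). The reward for an arm
  is the best direction-adjusted target achieved by that category in the latest
  batch, min–max scaled to [0, 1] over campaign history. The reward definition
  and learning rate are this package's defaults; the upstream bandit literature
  admits several variants.
- **Constant liar**: batches under UCB/brute-force are built sequentially; after
  each suggestion the model is augmented with a "lie" equal to the mean of the
  observed (unstandardized) targets at that point and re-factorized *without*
  re-optimizing hyperparameters, which collapses local uncertainty and pushes
  later batch members elsewhere. The original model is untouched.
- **Dispatch**: mixed spaces default to bandit + Thompson for iterations below 4
  and brute-force + constant liar from iteration 4 on (configurable via a
  per-iteration schedule); continuous unconstrained → UCB + L-BFGS-B;
  constrained → UCB + trust region.

## Objectives

Replicate readings are averaged into the modelling target. Specific
productivity is titer / OD600 (mg/L/OD600). The homeostasis target is
V_factor · Σ_j Frac_j over j ∈ {NK, T, B}, with V_factor = V for V ≤ 1 and 1/V
for V > 1; inputs are treated as post/pre-culture ratios because the piecewise
rule penalizes both loss and uncontrolled expansion. Whether Frac_j is a raw
post-culture fraction or a ratio to the ex vivo fraction is a labelling choice
in the config; the formula is applied as written either way.

## Transfer learning

Extending a campaign with new factors keeps the fitted GP as the prior instead
of re-running a space-filling design. Historical experiments are embedded into
the extended space with new factors pinned at the benchmark conditions under
which the history was generated (config-overridable); targets and noise carry
over unchanged. At the fill values the new dimensions contribute zero distance,
so before re-optimization the embedded model reproduces the original model's
predictions at historical points to 1e−6 (verified in tests). New continuous
dimensions start at length scale 1.0 on the scaled axis — maximally smooth and
uncertain — before the next refit. The warm-started campaign's first batch
comes from the acquisition, never from LHS, and EXP3 weights carry over for
shared categorical arms.

## Synthetic landscapes

Wet-lab responses cannot back a test suite, so closed-loop behaviour is
checked on synthetic landscapes that emulate structural features of media
responses, not biological magnitudes:

- **mixed**: continuous factors on [0, 1] plus one categorical factor; response
  = shared smooth radial trend + per-category radial bump with its own centre,
  width, height and offset; one category's bump is boosted so the global
  optimum lives in a unique category (mirroring a best co-feed with its own
  best concentration). Optimum certified by a 50-per-axis grid within every
  category; certification is resolution-limited and documented as such.
- **simplex**: blend ratios on the unit simplex; linear blending term plus an
  interior radial bump, so the interior optimal blend strictly exceeds every
  pure-component vertex (single media underperform the optimized blend).
  Certified on a dense simplex grid.
- **continuous**: a single radial bump of unit height whose optimum is its
  centre, known in closed form; used for many-factor unconstrained campaigns
  (the cytokine-cocktail analogue) where grid certification cannot scale.

Observation noise is additive Gaussian with fixed sd. What these landscapes do
*not* emulate: heteroscedastic biological noise, batch effects, replicate
pooling artefacts, non-smooth responses, or the actual magnitudes of
viabilities and titers. Passing closed-loop tests therefore demonstrates the
machinery (accounting, feasibility, exploration→exploitation, BO ≥ random at
equal budget, warm start ≥ cold start), not wet-lab performance.

## DoE budget calculator

Standard textbook run counts quantify what a static design would cost on the
same space: OFAT = k(L−1)+1; full factorial = L^k; fractional factorial =
L^(k−p); CCD = 2^k + 2k + centre; fractional CCD = 2^(k−p) + 2k + centre;
BBD = 2k(k−1) + centre (undefined for k < 3); full screen = (grid levels)^k;
categorical factors multiply any continuous design by the product of category
counts. The calculator is parameterized (fractions, centre points, grid
levels) so alternative counting conventions can be matched exactly.

## Problem sizes and numerical choices

Closed-loop simulations in the test suite and acceptance script run at desk
scale as this package's own default study conditions: 2 continuous dimensions
with 4–6 categories (mixed), 4 blend components (simplex), batches of 4–6,
budgets of 18–24 experiments, 12–20 seeds per sweep, candidate screens of
400–512 for simulated campaigns (the 10 000-point default remains for real
campaigns), and 2–3 optimizer restarts per refit. The GP-recovery simulation
uses one continuous dimension × three categories with θ = 0.4, a regime chosen
so that an oracle GP carrying the true hyperparameters already meets the
held-out-accuracy bound — i.e. 60 points genuinely determine the function and
the check measures fitting quality rather than interpolation starvation.

Tie-breaks: argmax over screens returns the lowest index; category order is
declaration order. Degenerate inputs: constant targets fall back to unit
standardization scale; empty prediction queries return empty arrays; a
zero-distance pair is held PSD by the jitter. All stochastic steps take
explicit seeds; separate child generators drive continuous and categorical
streams in the initial design so adding categories does not perturb continuous
reproducibility.

## Known limitations

- The brute-force screen scales poorly with dimension; the suggestion quality
  on mixed spaces is screen-resolution-limited.
- No inequality or nonlinear constraints, no conditional factor hierarchies.
- The bandit reward scaling is a pragmatic default; no regret guarantee is
  claimed for the combined bandit + Thompson scheme.
- Landscape optimum certification is grid-resolution-limited.
- Single-objective only; aggregation (as in the homeostasis target) is the
  supported route to multi-objective trade-offs.
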