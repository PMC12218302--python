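# mediabo

Bayesian-optimization-driven iterative experimental design for cell-culture
media development.

Developing a culture medium — a blend of basal media for keeping primary
cells alive, a cytokine cocktail for holding lymphocyte populations at their
ex vivo balance, or carbon-source supplements that boost recombinant protein
titers in *Komagataella phaffii* — means searching a design space that mixes
continuous concentrations, discrete set points (pH levels), categorical
choices (which of 19 co-feeds), and constraints (blend ratios summing to
one). Classical design-of-experiments (DoE) schemes discretize that space up
front and spend their entire budget on a static plan. `mediabo` instead runs
the loop a self-driving campaign needs: a space-filling initial design, a
Gaussian-process surrogate that learns from each batch, and an acquisition
step that balances exploring uncharted media against refining promising ones.

## The model

The surrogate is a GP, f ~ GP(m, k), over encoded points z = (x, h) with
continuous/discrete coordinates x scaled to [0, 1] and categorical
coordinates h. The covariance is

```
k_cont(x, x′) = Matérn_ν( Σ_d (x_d − x′_d)²/θ_d² ),   ν ∈ {1.5, 2.5}
k_cat(h, h′)  = (σ/c) Σ_{i=1..c} 1(h_i = h′_i)
k(z, z′)      = α · k_cat·k_cont + (1 − α) · (k_cat + k_cont)
```

with an overall signal variance σ_f² and a *fixed* white-noise term whose
variance is the pooled sample variance of replicated control experiments —
measurement noise is measured, not fitted. Hyperparameters (θ, σ, α, σ_f²)
maximize the marginal likelihood from multiple restarts (α starts at 0.5).

Batches are planned by upper confidence bound (mean + κ·sd) under
quasi-Newton (unconstrained), trust-region (simplex-constrained) or
brute-force screening over 10 000 candidates (mixed spaces), with constant-
liar batching; early iterations of mixed campaigns use an EXP3 bandit over
the categorical arms plus Thompson sampling over the continuous factors.
When the design space later grows (new supplements), the fitted GP becomes
the prior of the extended campaign instead of a fresh space-filling design.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

A simulated four-media blend campaign (ratios constrained to sum to one),
24 experiments in batches of six — an initial random feasible design plus
three BO-planned batches:

```bash
mediabo simulate --family simplex --budget 24 --batch 6 --n-init 6 \
    --noise-sd 0.03 --seed 1 --summary-out summary.json
```

prints

```json
{
  "family": "simplex",
  "seed": 1,
  "ledger_rows": 24,
  "best_observed": 0.9743415130130402,
  "best_true": 0.9485476933447229,
  "true_optimum": 0.9775685780481771,
  "regret": 0.02902088470345421
}
```

`ledger_rows` confirms the campaign accounting (6 + 3×6). `best_observed`
is the best noisy measurement; `best_true` is the landscape's true response
at that blend, within 0.03 of the certified optimum after 24 experiments —
the closed loop found a near-optimal interior blend that no single medium
(simplex vertex) matches. The same CLI drives real campaigns: `mediabo init`
from a config file, `mediabo suggest` to plan a batch into the ledger CSV,
`mediabo ingest` to load replicate measurements and refit, `mediabo status`
for convergence and the best condition so far. A library call mirrors every
command.

How many experiments would static designs need for the yeast carbon-source
space (3 continuous factors × 19 co-feed types)?

```bash
mediabo doe-size --method ccd --k 3 --categories 19    # → 285 experiments
mediabo doe-size --method full_screen --k 3 --categories 19 --grid-levels 10
# → 19000 experiments
```

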