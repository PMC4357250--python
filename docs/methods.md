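# Methods

## Tasks

Both tasks offer four inexhaustible decks (A–D) over a 120-trial session.
Payoffs are deterministic block structures: the IGT repeats a 10-card block
per deck (A/B pay $1.00 per card with losses on 5 resp. 1 cards per block;
C/D pay $0.50 with losses on 5 resp. 1 cards), the SGT a 5-card block in
which every card is a pure gain or a pure loss. In both tasks decks A and B
net −$2.50 and decks C and D +$2.50 per 10 trials; the SGT decouples this
long-run value from gain–loss frequency (its good decks lose on 4 of 5
cards). Within each block the card order is a fresh uniform permutation —
the published description says only "randomized", and an independent uniform
permutation per deck per block is the natural reading. Each deck has its own
child RNG stream, so drawing from one deck never perturbs another's
sequence, and per-block outcome multisets are exact (block expected values
carry no sampling error). Losses are stored as nonnegative magnitudes; the
published tables print them negative, which is sign notation only. A running
balance is a presentation detail of the original experiments and is not
modelled; no model component consumes it.

## Model family

Eighteen models arise from crossing three utility functions (EU, PU, PU2),
three updating rules (DELTA, DRL, MIXED) and two choice rules (TDC, TIC);
see the README for the equations. Conventions that the equations leave open:

* **Initial expectancies** are `E_j(0) = 0` for all decks, the standard
  choice in this literature; it makes the first prediction uniform, so the
  first trial is conditioned on and contributes no likelihood term.
* **PU at x = 0** takes the nonnegative branch: `0^α = 0` for `α > 0` and,
  at the step-function corner `α = 0`, the gain-branch value 1.
* **PU2 at α = 0** uses the `0^0 = 1` convention of `pow`, consistent with
  the step-function reading above. `α = 0` is a boundary of the parameter
  box that the optimizer touches with probability zero; the convention only
  pins down the corner's value.
* **Parameter order** is canonical — utility parameters, then updating
  parameters, then the consistency `c` — so fitted vectors are comparable
  across runs and serializable by position.
* **Bounds**: `W, A, D, α ∈ [0, 1]` (substantive constraints of the model
  definitions); loss aversion `λ, γ ∈ [0, 10]` and TIC `c ∈ [0, 5]`,
  generous versions of the ranges customary in this model family; TDC
  `c ∈ [−5, 5]`, negative values letting sensitivity *decrease* over trials.
  θ = 3^c − 1 at c = 5 is ≈ 242, deep in the near-deterministic regime, so
  the upper bound is not practically binding.

## Likelihood

The one-step-ahead log-likelihood runs the recursion forward over the
*observed* choices and outcomes: for `t = 1 … T−1`, the utility of trial t's
outcome updates the expectancies, and the log softmax probability of the
deck actually chosen on trial `t+1` is accumulated (T−1 terms; a uniform
predictor scores `(T−1)·ln(1/4)`). Two indexing/counting conventions are
deliberate, exposed choices:

* **TDC trial index** (`FitConfig.tdc_index`): the sensitivity for
  predicting trial `t+1` uses the index of the predicted trial (`t+1`) by
  default; `"current"` instead uses `t`, the literal reading of writing
  θ(t) next to E_j(t). The two differ by a one-trial phase shift of a
  smooth function and matter little in practice, but they are not identical,
  so the choice is explicit.
* **BIC sample size** (`FitConfig.bic_n_mode`): `n = T − 1 = 119` predicted
  choices by default, matching the number of terms in both the model and the
  baseline likelihood; `"all"` uses `n = T = 120`.

The baseline model (independent choices, constant probabilities, 3 free
parameters) is fitted in closed form on the same T−1 predicted trials as the
cognitive models, so both likelihoods condition on identical data; its MLE
is the empirical choice mix, with never-chosen decks contributing zero
log-likelihood terms.

Softmax terms are computed by max-subtraction: after the shift the largest
exponent is exactly 0, the normalizer is ≥ 1, and every per-trial
log-probability is finite for any finite θ·E — no explicit exponent capping
is needed. Probabilities themselves can underflow to exact 0.0 when
expectancy gaps exceed ~745 nats; the log-domain path never does.

## Optimization

Per (sequence, model) fit: the likelihood is evaluated at `n_starts = 50`
points of a seeded Latin-hypercube design over the parameter box (a
space-filling deterministic analogue of a coarse grid), and Nelder–Mead
simplex refinement is run from the best `n_refine = 5` starts, with function
and parameter tolerances of 1e−8 and at most 500·dim iterations per start.
Bounds are enforced by optimizing through a per-coordinate logit map to the
real line (branch-free model code, no penalty terms); start points lie in
the open box so the map is finite. The reported optimum is the best over all
raw starts and refinements, hence never worse than the best grid point.
Non-convergence of every simplex run is reported via `converged=False` with
the best point still returned. Everything is deterministic given
`FitConfig.rng_seed`.

Degenerate inputs behave sensibly: a constant-choice sequence drives the
consistency estimate toward its upper bound and returns without error; a
sequence whose every start evaluates non-finite (not reachable for valid
data) raises a fit failure, which cohort-level drivers record and skip.

## Synthetic cohorts

Agents realize a model generatively on the exact task schedules, sharing the
same compiled recursion kernels as the likelihood — the data-generating
process is exactly the process being scored. The generator's defaults mirror
the study design: 120-trial sessions, both tasks per agent under one shared
parameter vector (the premise of the cross-task consistency analysis), and
cohort sizes of ~50 agents where a sample size is needed (the study had 53
participants). Parameters are sampled independently and uniformly over their
bounds, except the consistency `c`, drawn on [0.5, 3]: near `c = 0` an agent
is uniformly random (nothing to recover), near the upper bound almost
deterministic (degenerate likelihood surface); both extremes say nothing
about recovery in the regime where real participants live. The sampler is a
plain callable and can be overridden.

Per-agent and per-task RNG streams are split deterministically from one
master seed (`numpy.random.SeedSequence`), so cohorts are byte-reproducible
and an agent's two task sessions are independent given its parameters.

What the generator does **not** emulate: clinical group structure (group
labels are arbitrary tags), choice perseveration or alternation tendencies
beyond what the 18 models express, within-session non-stationarity other
than TDC's schedule, and individual differences beyond the parameter
distribution. Passing recovery and identification tests on these cohorts
therefore demonstrates internal coherence of the pipeline — the estimator
finds the structure the generator put in — not that real participants obey
any of these models.

## Comparison and consistency statistics

BIC-difference summaries report mean, median, sample SD (n−1 denominator;
undefined/NaN for a single participant) and the percentage of *strictly*
positive scores (an exact zero is not a win). Pairwise comparisons count
participants whose score is strictly higher under one model, with exact ties
kept separate. Cross-task parameter consistency uses Spearman's rank
correlation with average ranks for ties and a one-tailed test of ρ > 0 —
the scientific hypothesis is positive association, and estimate
distributions are generally non-normal, so rank correlation is used
unconditionally. The default p-value is the large-sample t approximation
`t = ρ·√((n−2)/(1−ρ²))`; an exact permutation option is available for
n ≤ 10.

## Problem sizes and checks

The test suite validates the likelihood against a structurally independent
naive reference (dict-based expectancies, scipy log-softmax) across all 18
models, and runs two simulation studies sized to be informative yet quick:
parameter recovery on 50 PVL2 agents × 2 tasks × 120 trials with a reduced
15-start budget (all eight rank correlations — four generating-vs-recovered,
four cross-task — come out strictly positive), and model identification on a
53-agent PVL2 cohort where PVL2 beats EVL in pairwise BIC wins for a clear
majority. Larger budgets (the default 50 starts) only sharpen these results.

## Known limitations

* No perseveration term or other sequential-dependence component outside
  the expectancy mechanism; models of that kind are known competitors.
* Maximum-likelihood point estimates only — no hierarchical pooling or
  Bayesian uncertainty over parameters.
* The DRL rule's expectancies are unbounded in principle; the softmax
  depends only on expectancy *differences*, and the log-domain evaluation
  keeps the likelihood finite, but fitted DRL parameters near `A = 1` should
  be interpreted with care on long sessions.
* One-step-ahead likelihood is the only fit criterion; whole-session
  simulation-based fit indices are out of scope.
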