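# Methods

This note documents the models, the synthetic-data generator, the
estimation machinery, and the numerical choices behind `groupbandit`,
including the places where the design was genuinely open and what the
package's tests do and do not establish.

## Task

A session is 100 choices between two arms. One arm is advantageous
(win probability 0.70) and the other disadvantageous (0.30); the roles
swap after each scheduled reversal trial, by default after trials 30 and
70, so the initially advantageous arm is good on trials 1–30 and 71–100.
Trials are 1-based in configuration and reports; a reversal "at trial r"
takes effect from trial r+1. Rewards are Bernoulli and enter all models
on a 0/1 scale; the 10 points shown to players are display metadata.
Unit-scaled rewards are the only scaling consistent with inverse
temperatures in the 4–6 range: at a 10-point scale those β values would
make choice essentially deterministic at value separations of a few
points.

An oracle policy that always takes the currently better arm earns
0.70 × 100 = 70 rewarded trials in expectation; a uniform random policy
earns (0.70 + 0.30)/2 × 100 = 50. These two numbers bracket all
realistic behavior in this task.

## Q-learning models

**Simple model** (parameters α ∈ (0, 1], β ≥ 0): the chosen arm's value
moves by α times the reward prediction error δ = R − Q; the unchosen
arm's value is untouched; both values start at zero; choices follow a
two-option softmax with inverse temperature β. With two options the
softmax reduces to a logistic in β(Q₁ − Q₂); it is computed with
max-subtraction so large βQ never overflows.

**Asymmetric model** (α⁺, α⁻ ∈ (0, 1], β ≥ 0, ϕ ∈ ℝ): separate learning
rates for non-negative (α⁺, inclusive of δ = 0) and negative (α⁻)
prediction errors, plus an additive choice-trace increment ϕ applied to
the chosen arm's value on every update. ϕ > 0 produces perseveration
(recently chosen arms gain value regardless of outcome), ϕ < 0
alternation. The increment is implemented literally as an additive term
in the value update, not as a separate decaying choice kernel in the
softmax; the kernel formulation common elsewhere in the literature would
be a different model, and the two should not be conflated when comparing
fits. With α⁺ = α⁻ and ϕ = 0 the asymmetric model reproduces the simple
model exactly, which the tests exploit as a nesting check. The simple
model deliberately has no ϕ parameter.

The session log-likelihood replays the observed choices and rewards
through the update rule from zero initial values and sums the log
softmax probability of each observed choice. A session of T trials under
β = 0 scores exactly T·ln(1/2).

## Synthetic groups and the learning-coherence hypothesis

The generator stands in for human data that are not available. Each
member of a unit carries private parameters drawn from a population:
learning rates Beta(2, 2), inverse temperatures Gamma(shape 2,
scale 2.5), choice trace Normal(0, 0.1). These are weakly informative
choices centered on magnitudes typical of human fits in bandit tasks
(rates near 0.5, β near 5) without asserting any particular dataset's
estimates.

A per-size coherence parameter c ∈ [0, 1] governs how a unit chooses.
On each trial, with probability c the unit uses a **consensus policy** —
softmax over the member-averaged Q-values with the member-averaged β —
and every member integrates the outcome into their private values.
Otherwise a uniformly drawn member's own policy controls the trial, and
**only the controlling member updates**. Defaults: c = 1 for
individuals (trivially coherent), c = 0.1 for dyads, c = 0.9 for triads,
reflecting the idea that majority rule can stabilize a triad's learning
policy while a dyad's control drifts between two members.

The restriction of updates to the controlling member is the load-bearing
design choice, and it was genuinely open. A variant in which all members
update on every trial regardless of who controls (available via
`shared_updates=True`) turns out to make incoherence *harmless or mildly
helpful*: per-trial policy mixing averages the members' conditional
reward rates, and the extra choice entropy even speeds recovery after
reversals, so fully informed dyads slightly outperform solo agents. A
mixture of controllers on a shared learning stream therefore cannot
produce the hypothesized dyad deficit. Fragmented updating gives
incoherence a real cost — each member's values are trained on roughly
half the session and go stale between turns — and with it the generator
produces the U-shape: at 500 units per size, dyads earn about 1.9 fewer
rewarded trials than individuals and about 2.7 fewer than triads, and a
quadratic fit of the three group means gives size/size² coefficients of
roughly (−7, +2) on the count scale. Behaviorally, fragmented updating
models disengagement during the other member's turn; it is a stylized
mechanism, not a claim about attention in real groups.

Consensus aggregation (mean Q, mean β) is the simplest symmetric choice;
alternatives can be swapped in behind the same interface. Singleton
units never draw coherence or controller variates, so a one-member group
consumes the random stream exactly like the solo-agent simulator and
reproduces it bit for bit under the same seed.

`generate_dataset` mirrors the study design it emulates: 322 individual
sessions, 138 dyads, 108 triads by default, with group members drawn
from the pool of participants who also played alone (so every group
links to solo sessions, as required by the within-group contrasts).
Repeated participation beyond that overlap, order effects, and any
within-session parameter drift are not modeled.

## Estimation

**MAP.** Per session, the posterior mode of likelihood × independent
priors — Beta(2, 2) on each learning rate, Gamma(shape 2, scale 3) on β,
Normal(0, 1) on ϕ — is found by L-BFGS on an unconstrained scale (logit
for rates, log for β, identity for ϕ) from 10 random starts (rates
uniform on (0.05, 0.95), β log-uniform on (0.3, 15), ϕ Normal(0, 0.3)),
keeping the best local optimum; objective tolerance 1e−6. The priors are
exposed in configuration; `PriorSpec.flat()` gives uniform/improper
priors under which MAP coincides with maximum likelihood (checked in the
tests). A zero-trial session has a constant likelihood, so the fit
returns the prior mode — a useful degenerate-input check. Parameter
recovery on 100-trial sessions is necessarily noisy: over 200 sessions
with rates in (0.2, 0.9) and β in (1, 8), Spearman correlations between
true and fitted values run around 0.83 (α) and 0.89 (β).

**WBIC.** Model evidence is proxied by the widely applicable Bayesian
information criterion: the mean of the untempered log-likelihood under
the posterior tempered at 1/log(T) (≈ 0.217 for T = 100). Sampling is
random-walk Metropolis on the unconstrained scale (with the
change-of-variables Jacobian), 5000 samples after 1000 burn-in, Gaussian
proposals with scale 0.35 — tuned once to land acceptance rates near
0.5–0.65 in 2 dimensions and 0.45–0.55 in 4; rates outside (0.05, 0.95)
raise a warning rather than an error. The chain starts from the prior
center. Under this sign convention higher WBIC is better and values for
100-trial sessions sit on the log-likelihood scale (≈ −50 for
near-chance behavior). Two extra parameters cost roughly ln(T) nats
each in the tempered posterior, so the asymmetric model overtakes the
simple one only when asymmetry or a nonzero choice trace buys a
comparable likelihood gain; on simple-model data it does not, which is
the expected guard against spurious preference. Model WBICs are
compared with a pooled-variance two-sample t-test (df = n₁ + n₂ − 2).

## Group statistics

Performance is the count of rewarded trials. Between-size comparisons
use Kruskal–Wallis (midrank tie correction, χ² p-values) and pairwise
two-sided Wilcoxon rank-sum tests with Bonferroni adjustment (exact
null distribution for small tie-free samples, normal approximation with
tie correction otherwise). Within-group contrasts compare a group-level
quantity against the max, min, or mean of its members' individual-session
values; the default is a two-sample rank test in its χ² (df = 1) form,
with a paired signed-rank variant behind a flag since the vectors are
naturally paired — the two-sample form is reported for comparability,
the paired form is the statistically tighter choice. Positivity bias
(α⁺ − α⁻) is tested per size with a one-sample signed-rank test of
median zero; an all-zero vector returns a flagged degenerate result with
p = 1.

Regressions of performance are Poisson GLMs with an **identity** link:
coefficients then live directly on the rewarded-trials scale
(intercepts near 50, size effects in trials), which is the natural
scale for this bounded count outcome; a log link would put them on a
multiplicative scale. The fitter is Fisher scoring with step-halving to
keep all fitted means positive, OLS-initialized; for an intercept-only
model one Fisher step lands exactly on the sample mean, which the tests
assert. Standard errors come from the inverse Fisher information, and
AIC = −2·loglik + 2·(number of coefficients) with the full Poisson
log-likelihood (including the log y! term), matching the `statsmodels`
convention the tests cross-check against. Specifications: group dummies
with dyad baseline, group dummies with individual baseline, or
size + size², each optionally controlling for the fitted learning
parameters of one model.

## Determinism and problem sizes

Every stage derives its random streams from the single run seed:
generation from (seed, stage tag), each unit × model fit and MCMC chain
from (seed, stage tag, unit index, model index). Staged CLI runs and
the one-shot pipeline therefore write byte-identical artifacts, and CSV
round-trips preserve floats exactly (`float_precision="round_trip"`).

The test suite and the acceptance script run the method at deliberately
modest scales chosen as the package's own defaults: 500 units per size
for the U-shape checks (the deficit is ~2 trials against a within-size
SD of ~6, so hundreds of units per size are needed for stable rank
tests), 200 sessions for parameter recovery, 100 sessions for the WBIC
comparison, and 20–100 replicates for sign-recovery rates.

## What passing tests show — and what they do not

The synthetic generator demonstrates that the learning-coherence
mechanism is *sufficient* to produce a U-shaped size–performance
relationship together with depressed dyad inverse temperatures; it does
not show that this mechanism operates in human groups. Real group data
differ in ways the generator ignores: communication content, confidence
sharing, social pressure, member non-independence, learning across
repeated sessions, and reward schedules whose reversal timings varied
across experiments. One consequence worth flagging: under full
incoherence the generator's fitted group β falls significantly *below*
the member average, a sharper deficit than human dyads typically show —
the mechanism is stylized, and its strength should not be read as an
empirical calibration. Likewise the population distributions are
plausible, not estimated from any dataset, so absolute performance
levels (high 50s out of 100) exceed those of human players, who hover
near chance.

## Known limitations

* Two arms only; no drifting probabilities between reversals.
* No hierarchical pooling across sessions — each session is fitted
  independently, as in per-subject MAP pipelines.
* WBIC uses a fixed-scale random-walk sampler adequate for 2–4
  dimensions; no adaptation, no convergence diagnostics beyond the
  acceptance rate.
* The identity-link Poisson model can in principle predict negative
  means outside the observed covariate range; step-halving only
  guarantees positivity at the data points.
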