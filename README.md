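# groupbandit

Do two heads beat one — and do three beat two — when the task requires
*learning* rather than perception? `groupbandit` is a Python toolkit for
studying group decision-making in reversal two-armed bandit tasks with a
reinforcement-learning lens. It is aimed at computational cognitive
modellers who want to simulate, fit, and statistically compare the
behavior of individuals, dyads, and triads playing the same 100-trial
bandit.

The package provides:

* **Task environment** — a two-armed bandit with 70%/30% reward
  probabilities whose advantageous arm reverses at scheduled trials
  (default after trials 30 and 70).
* **Q-learning models** — the simple model
  `Q_i(t+1) = Q_i(t) + α δ(t)`, `δ(t) = R(t) − Q_i(t)`, with softmax
  choice `P(a=i) ∝ exp(β Q_i)`; and an asymmetric variant with separate
  learning rates `α⁺`/`α⁻` for non-negative/negative prediction errors
  plus an additive choice-trace increment `ϕ` on the chosen option.
* **Synthetic group generator** — individuals, dyads, and triads whose
  members carry private parameters drawn from a population; a per-size
  *coherence* parameter mixes a consensus policy (member-averaged values
  and inverse temperature) with single-member control. Incoherent,
  member-controlled trials train only the controlling member, so groups
  that cannot sustain one learning stream pay a performance cost — the
  mechanism behind the U-shaped size–performance hypothesis (dyads worst,
  individuals and majority-ruled triads better).
* **Inference** — per-session MAP estimation (Beta priors on learning
  rates, Gamma on β, Normal on ϕ; multi-start L-BFGS on an unconstrained
  reparameterization) and WBIC model comparison via random-walk
  Metropolis on the posterior tempered at `1/log(n_trials)`.
* **Group statistics** — Kruskal–Wallis and pairwise Wilcoxon rank-sum
  tests with Bonferroni adjustment, within-group contrasts of group
  values against member max/min/mean, one-sample positivity-bias tests,
  and identity-link Poisson regressions of performance counts (group
  dummies or `size + size²`).

## Worked example

```python
from groupbandit import GroupDesign, McmcSettings, RunConfig, run_pipeline

config = RunConfig(
    design=GroupDesign(n_individual_sessions=60, n_dyads=40, n_triads=40),
    mcmc=McmcSettings(n_samples=1000, burn_in=250),
    seed=7,
)
result = run_pipeline(config)
print(result.report.descriptives)
```

which prints (seed 7):

```
                    variable  individual_mean  dyad_mean  triad_mean
                 performance            56.62      52.85       58.32
              alpha (simple)             0.44       0.26        0.42
               beta (simple)             4.87       3.19        5.07
alpha+ - alpha- (asymmetric)             0.06      -0.03       -0.02
           beta (asymmetric)             4.67       3.26        5.42
            phi (asymmetric)            -0.12      -0.04       -0.04
```

Performance (rewarded trials out of 100) is U-shaped in group size:
dyads earn the fewest rewards, and their fitted inverse temperature β is
visibly depressed — incoherent control makes group choices look more
exploratory than either member alone. The accompanying rank tests:

```
             test          comparison  statistic  p_raw  p_adjusted
   kruskal_wallis             omnibus      18.95 0.0001         NaN
wilcoxon_rank_sum  individual vs dyad    1634.00 0.0022      0.0067
wilcoxon_rank_sum individual vs triad     969.50 0.1049      0.3147
wilcoxon_rank_sum       dyad vs triad     359.50 0.0000      0.0001
```

and the WBIC model comparison (higher is better; the two models are not
statistically distinguishable on these sessions, as expected when the
generating positivity bias is small):

```
 mean_wbic_simple  mean_wbic_asymmetric     t  df     p
          -46.864               -48.297 0.728 278 0.467
```

The same pipeline is available from a shell:

```bash
groupbandit run-all --seed 7 --outdir out/          # one shot
groupbandit simulate --seed 7 --outdir out/         # or staged:
groupbandit fit --sessions out/sessions.csv --units out/units.csv --out out/fits.csv
groupbandit wbic --sessions out/sessions.csv --out out/wbic.csv
groupbandit analyze --sessions out/sessions.csv --units out/units.csv \
    --fits out/fits.csv --wbic out/wbic.csv --outdir out/
```

Staged and one-shot runs write byte-identical artifacts for the same
config and seed.

## Layout

| module | contents |
| --- | --- |
| `groupbandit.task` | `TaskConfig`, `Schedule`, `build_schedule`, `sample_reward` |
| `groupbandit.qlearning` | parameter types, softmax policy, value updates, `session_loglik` |
| `groupbandit.synthetic` | population, coherence-mixture group simulator, `generate_dataset` |
| `groupbandit.inference` | `PriorSpec`, `fit_map`, `compute_wbic`, `compare_models` |
| `groupbandit.analysis` | rank tests, contrasts, positivity bias, Poisson regression |
| `groupbandit.io` / `.pipeline` / `.cli` | CSV formats, staged pipeline, `groupbandit` CLI |

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and known limitations.
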