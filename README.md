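# delaydisc

Hierarchical delay-discounting analysis for antidepressant-discontinuation
relapse studies.

## The problem

Delay discounting measures impatience for reward: the subjective value of a
reward *R* delivered after *d* days falls hyperbolically,

    V(R, d) = R / (1 + K d),

where *K* (1/day) is the individual's discount rate. Because *K* is
log-normally distributed across people, analyses work on log *K*. Steeper
discounting has been linked to depression and to reduced serotonergic
function, making it a candidate behavioural marker of relapse risk after
antidepressant discontinuation in remitted major depressive disorder.

`delaydisc` implements the full analysis chain for a two-site,
two-timepoint cohort of remitted patients (assessed before, MA1, and after,
MA2, discontinuation) and matched controls:

* **Choice tasks** — the classic 27-item monetary choice questionnaire
  (three delayed-reward magnitude bins of nine items) and a simulated
  adaptive questionnaire that re-estimates *K* after every choice and
  places the next offer at the current indifference point.
* **Hierarchical fitting** — binary choices enter a softmax likelihood,
  P(immediate) = σ(β·(r − V(R, d))), with per-participant parameters
  (log K, log β) under a population Gaussian prior learned by
  Expectation-Maximization (empirical Bayes; MAP + Laplace E-step). A
  two-timepoint variant estimates the within-person change Δlog K jointly
  with baseline log K, giving regularized gain scores.
* **Model evaluation** — per-participant accuracy, a right-tailed binomial
  test against chance (p = Σᵢ₌ₖⁿ C(n,i)·0.5ⁿ; participants with p > 0.05
  are excluded), and McFadden's pseudo-R² against the coin-flip null.
* **Pre-registered statistics** — normality/equal-variance-gated t tests
  with Cohen's *d* and bootstrap CIs, Spearman correlations with
  10,000-iteration bootstrap CIs and Bonferroni correction, Cox
  proportional hazards on days to relapse (Breslow ties), L1-regularized
  logistic relapse prediction with stratified tenfold CV and balanced
  accuracy, linear mixed-effects models for discontinuation and symptom
  change, and noncentral-t post-hoc power.
* **Synthetic cohorts** — a seeded generator that reproduces the study's
  statistical structure (group shift d = 0.34 in log K, log K/HAM-D rank
  correlation 0.24, test-retest 0.72, 35% relapse, 97 + 54 participants,
  47/50 arm split, 17 dropouts), so the whole pipeline is testable without
  the original raw data.

## Worked example

```python
import numpy as np
from delaydisc import (DiscountParams, subjective_value, p_immediate,
                       SyntheticConfig, generate_cohort, em_fit,
                       evaluate_cohort)

# the hyperbolic model's worked geometry
print(round(subjective_value(75, 20, 0.0065)))   # 66
print(round(subjective_value(75, 20, 0.0037)))   # 70
params = DiscountParams(log_k=np.log(0.0065), log_beta=0.0)
print(round(p_immediate(66, 75, 20, params), 3)) # 0.408

# a small synthetic cohort, fitted hierarchically
cfg = SyntheticConfig(n_patients=24, n_controls=12, dropout_n=4, seed=42)
cohort, choices = generate_cohort(cfg)
fit = em_fit(choices[choices.timepoint == "MA1"], seed=5)
ev = evaluate_cohort(fit, choices[choices.timepoint == "MA1"])
print(len(ev), round(ev.accuracy.mean(), 3), round(ev.pseudo_r2.mean(), 3))
# 36 0.865 0.605
```

A 75-euro reward in 20 days is worth 66 euros now to someone with
K = 0.0065 and 70 euros to someone with K = 0.0037 — the two group-mean
discount rates. At inverse temperature β = 1, an offer of 66 euros sits
just below that first agent's indifference point, so the immediate option
is chosen with probability 0.408. On the simulated cohort the fitted model
classifies 86.5% of the 36 participants' choices correctly with a mean
pseudo-R² of 0.61, and no participant fails the chance-level exclusion
test.

From a shell:

```bash
delaydisc simulate-cohort --seed 7 --out-dir data/
delaydisc analyze --cohort data/cohort.csv --choices data/choices.csv \
    --out report/ --seed 7
delaydisc simulate-adaptive --true-logk -4.0 --beta 0.8 --seed 3 --out ad.csv
```

`analyze` writes `report/report.json` with one entry per analysis step:
the baseline patient-vs-control comparison, the discontinuation and
symptom-change mixed models, the eight scale correlations, and the Cox and
lasso relapse models at MA1 and MA1+MA2.

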