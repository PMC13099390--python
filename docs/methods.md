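# Methods

## Choice model

One trial offers a smaller immediate reward *r* against a larger reward
*R* after *d* days. Subjective value is the standard single-parameter
hyperbola V(R, d) = R / (1 + K d); the generalized hyperbola with a
curvature exponent is deliberately out of scope, since a single parameter
per person is what the downstream individual-differences analyses consume.
Choice is stochastic through a logistic link,

    P(immediate) = σ(β (r − V(R, d))),   σ(x) = 1/(1+e^(−x)),

so a positive argument favours the immediate option. β (inverse
temperature, 1/currency) is a fitted per-participant parameter; the
original description prints only the sigmoid, but fitting "parameters"
plural in the cited framework implies a scale, and pinning log β = 0
(`pin_log_beta`) reproduces the unscaled sigmoid when wanted. Both
parameters live on the natural-log scale where the population distribution
of K is approximately Gaussian; any base-10 reporting is presentation
only. No amount normalisation is applied to the sigmoid argument. σ and
log σ are evaluated via `scipy.special.expit` / `log_expit`, and returned
probabilities are clipped away from exact 0/1.

Every item has an implied indifference rate K* = (R − r)/(r d); a
noiseless discounter with rate K takes the immediate reward exactly when
K > K*. The packaged 27-item monetary choice questionnaire is the
standard published bank (three delayed-reward magnitude bins — 25–35,
50–60, 75–85 currency units — of nine items each); its nine
small-magnitude items split four items with K* > 0.01 against five below,
so a K = 0.01 agent defers on the four steeper items and takes the
immediate reward on the five shallower ones.

## Hierarchical empirical-Bayes estimation

Participant parameters θ (log K, log β — or log K_MA1, Δ, log β in the
two-timepoint variant) share a Gaussian prior N(μ, Σ) whose
hyperparameters are learned by EM:

* **E-step** — per-participant MAP of log-likelihood + log prior
  (L-BFGS-B with analytic gradients; the default start is the prior mean
  or the previous iteration's MAP, plus `n_restarts = 5` starts drawn from
  the current prior; best penalised objective wins, first found on ties).
  The posterior is approximated by a Laplace Gaussian with covariance the
  inverse Hessian (central finite differences of the analytic gradient) of
  the negative penalised objective at the MAP.
* **M-step** — μ ← mean of MAPs; Σ ← mean of (outer product of centred
  MAPs + Laplace covariance). The Laplace term keeps Σ from collapsing
  when individual estimates are uncertain.

Initialization is μ = (−4, 0[, 0]) and Σ = 2·I: exp(−4) ≈ 0.018/day sits
mid-range of the MCQ item indifference rates. Convergence is a
max-absolute hyperparameter change below 1e-3 (at most 100 iterations);
Σ's eigenvalues are floored at 1e-4 so exchangeable participants cannot
drive it singular, and a diagonal-Σ mode is available. Fitting always uses
each participant's concatenated MCQ + adaptive trials. All restart
randomness flows from a single `SeedSequence(seed)` with one child stream
per participant per iteration, making a fit bit-identical for fixed data,
seed and configuration. The summed penalised objective (including the
prior normalizer) is recorded per iteration; on the simulated cohorts it
is non-decreasing to within 1e-6, which the suite asserts.

The two-timepoint variant evaluates MA1 trials at exp(log K_MA1) and MA2
trials at exp(log K_MA1 + Δ), with the prior spanning (log K_MA1, Δ,
log β) and β shared across timepoints and tasks (a configuration choice;
the original report does not say). Estimating Δ jointly, rather than
subtracting two independent fits, prevents the additive accumulation of
estimation noise; the fitted Δ is the gain score used downstream.
Participants missing a timepoint are excluded from this fit with a notice.

## Adaptive questionnaire simulator

The cited adaptive instrument estimates a discount rate after every choice
and offers the next item at the current indifference point; its exact
offer grid and stopping rule are not public, so this module's versions are
declared substitutes, not reconstructions. The staircase here: a fixed
schedule cycles delayed rewards of 30/55/80 units across delays of
7/20/50/90/160 days; the immediate offer is round(V(R, d, K̂)) clipped to
[1, R−1] (whole currency units); the running estimate is the MAP log K
under the session prior (N(−4, 2), β pinned); the session stops when the
last four estimates span less than 0.05 in log K — counting only windows
of un-clipped, informative offers — or at 30 trials. On noiseless agents
the final estimate is within the offer-rounding granularity of truth; with
softmax agents at the generator's default β, ≥90% of sessions stop on the
stability rule.

## Model evaluation and exclusion

Accuracy counts trials where the option with model probability > 0.5
matches the observed choice; exact-0.5 ties add half a success to accuracy
but count as incorrect in the binomial k (the conservative direction). The
exclusion test is the exact right-tail Binomial(n, 1/2) sum with n the
participant's total concatenated trial count; p > 0.05 flags exclusion.
McFadden's pseudo-R² is 1 − L_model/L_null with the coin-flip null
(p = 0.5 per choice) — matching the chance definition of the exclusion
criterion in the same procedure, not a fitted-intercept null.

## Synthetic cohort generator

The generator emulates the study conditions so the pipeline is testable
end to end; defaults:

| parameter | default | meaning |
|---|---|---|
| n_patients / n_controls | 97 / 54 | group sizes at MA1 |
| logk_mean_control | ln 0.0037 ≈ −5.60 | control latent mean of log K |
| logk_sd | (ln 0.0065 − ln 0.0037)/0.34 ≈ 1.657 | latent SD, making the group shift d = 0.34 land the patient mean at ln 0.0065 |
| group_effect_d | 0.34 | standardized patient shift |
| rho_hamd | 0.24 | target pooled rank correlation of log K with baseline HAM-D |
| test_retest_r | 0.72 | latent MA1/MA2 correlation of log K |
| relapse_rate | 0.35 | relapse fraction among retained patients |
| dropout_n | 17 | patient dropouts (10 before MA2, scaled) |
| beta_mean / beta_sd | −1.0 / 0.5 | mean/SD of log β |
| followup_days | 182 | censoring horizon |

Arm assignment reproduces the 47/50 randomization split (scaled for other
sizes); sites follow the two recruitment proportions. HAM-D is a floor-of-
latent-Gaussian mapped to the 0–7 remission range; the latent correlation
with log K is inflated by a factor of 1.02, fixed by a one-off 200-seed
pilot so the realised pooled Spearman ρ centres on 0.24 (group separation
adds pooled correlation; discretisation removes some — the two nearly
cancel). Discontinuers' MA2 HAM-D latent shifts by +1.5 (continuation
+0.2), reproducing the reported withdrawal-syndrome symptom increase.
log β ~ N(−1.0, 0.5²) was fixed by a pilot sweep so that fitted-model
accuracy centres near 85% and pseudo-R² near 0.6, the reported fit
quality. Relapse is Bernoulli per retained patient with log-odds optionally
shifted by standardized log K (`relapse_logk_effect`, default 0); relapse
days are uniform on (0, 182] by default (exponential optional) — the
original report gives no hazard shape, so uniform is a declared
convention. Optional causal knobs (`discontinuation_effect`,
`relapse_delta_effect`, `hamd_logk_time_effect`) shift the MA2 latents for
recovery tests and default to 0. Choices are simulated from the softmax
model at each participant's latent parameters: the full MCQ plus one
adaptive session per timepoint (controls MA1 only; pre-MA2 dropouts lack
MA2 data). One `SeedSequence` drives everything; identical configs give
byte-identical CSVs.

What the generator does **not** emulate: real item-level response
heterogeneity (the softmax model is exactly true for synthetic agents, so
fitted accuracy and pseudo-R² are upper bounds on real-data behaviour),
site-level differences beyond a label, medication class/dose, attrition
that is informative about log K, and any non-uniform relapse hazard.
Passing tests therefore certify the machinery — estimator calibration,
type-I error, determinism — not clinical conclusions about real cohorts.

## Statistics pipeline

* **Gated comparisons** — Kolmogorov–Smirnov on standardized values (per
  sample, or on paired differences) and Bartlett's equal-variance test
  (independent samples), both at fixed 0.05; Student's t if both pass,
  else Wilcoxon signed-rank / rank-sum. Applying KS to standardized values
  (no Lilliefors correction) is a documented convention. One-tailed
  directions are explicit arguments, fixed by hypothesis, never inferred.
  Cohen's d uses the pooled-SD definition with a 10,000-resample
  percentile bootstrap 95% CI (portable, in place of platform-specific CI
  tools). Zero-variance inputs route to the nonparametric path with a
  warning; identical paired samples give d = 0, p = 1.
* **Correlations** — Spearman with mid-ranks, percentile bootstrap CI over
  paired resamples (default 10,000), Bonferroni over the eight
  pre-specified scale comparisons.
* **Survival** — Cox partial likelihood with Breslow ties via statsmodels
  `PHReg` (chosen over lifelines, which implements Efron ties only);
  exactly collinear designs are rank-reduced via pivoted QR with aliased
  columns reported NaN and the fit flagged.
* **Relapse classifier** — features standardized, L1 logistic path over a
  log-spaced grid (1e−4 … 1e2 in C, 25 points), strength selected by
  stratified 10-fold CV deviance (`selection="min_deviance"`), refit on
  the training data. A one-SE selection mode exists as an option; the
  deviance minimum is the default and the documented rule. Balanced
  accuracy is the mean of per-class recalls — exactly 0.5 for any
  constant classifier, in particular the all-zero solution. Min-deviance
  CV over-selects under pure noise (the all-zero model is chosen in
  roughly a third of null runs; the one-SE rule roughly doubles that) —
  a property of the selection rule, asserted at measured envelopes in the
  suite.
* **Cross-validation honesty** — `cv_mode="strict"` (default) re-estimates
  the hierarchical prior by EM on each training fold and MAP-fits held-out
  participants under that prior, so no participant's features depend on a
  prior estimated from their own data; `cv_mode="paper"` fits once on all
  participants and then cross-validates, reproducing the original
  analysis (with its acknowledged fold leakage through the shared prior).
* **Mixed models** — statsmodels MixedLM. Discontinuation:
  log K ~ group + time + group×time; symptom change: HAM-D ~
  log K_MA1×time + arm×time; both with a participant random slope on
  time. With only two timepoints the slope is weakly identified: on
  non-convergence, singular fit or a linear-algebra failure the model
  refits with a random intercept and sets `fallback_random_intercept`.
  Wald statistics are reported with residual df (n_obs − n_fixed); the
  term structure, not the df convention, is the contract.
* **Power** — exact noncentral-t two-sample power, noncentrality
  d·√(n1·n2/(n1+n2)), df = n1+n2−2; rounding only at presentation.

## Problem sizes and numerical choices

The suite's Monte-Carlo sizes are the package's own choices: 1000 seeds
for gated-test type-I calibration, 300 for Cox, 200 for LME and generator
calibration (all on the cheap latent path that skips choice simulation);
EM recovery runs one 100-participant cohort with ~55 trials each;
end-to-end determinism uses a 24 + 12 cohort with 500 bootstrap resamples
and 4 folds. Optimizer tolerance is L-BFGS-B defaults with a max-gradient
check at 1e-4; finite-difference Hessian step 1e-5; prior covariance floor
1e-4; Bonferroni factor 8.

## Known limitations

* The Laplace E-step is a Gaussian approximation; strongly skewed
  posteriors (e.g. near-deterministic responders) are summarized by
  curvature at the mode only.
* β recovery is biased upward for near-deterministic agents (the
  likelihood is flat above a threshold); log K, the quantity analysed, is
  unaffected in rank terms.
* The adaptive staircase is a substitute for the unpublished reference
  procedure; only its described behaviour (per-trial re-estimation,
  offers at the indifference point, stability stopping) is reproduced.
* Reported mixed-model statistics are Wald z-based, which is slightly
  anti-conservative at small n relative to Satterthwaite-type df.
* The generator's HAM-D floor mapping attenuates latent HAM-D×log K time
  effects by roughly a third; recovery tests account for this.
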