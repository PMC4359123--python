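# Methods

## Response model

A 3-alternative forced-choice presentation offers three pens, one
containing n-butanol at dilution step `d` (step 1 = 4% v/v; each +1
step halves the concentration, so step 16 ≈ 1.22 ppm; steps ≤ 0 denote
stronger pens).  The probability that subject `i` picks the odorant pen
is

    P(Y_ij = 1 | alpha_i) = 1/3 + 2/3 * expit(alpha_i - beta * d_ij)

with a fixed guessing floor of 1/3 and upper asymptote 1.  `beta > 0`
(units: logits per dilution step) is the common slope of the
psychometric function; `alpha_i` is the subject's latent ability.  The
*threshold* is the step detected with probability 2/3, `t_i =
alpha_i / beta` — the natural scale on which populations are described.
The model assumes every subject has a finite threshold (no true
anosmia mass), no learning, habituation, fatigue or pen-depletion
effects, and conditional independence of responses given `alpha_i`;
consequently stimulus order is irrelevant, which is why constant-stimuli
designs may present dilutions in a fixed order.

## Populations

A population is a threshold distribution plus a slope:

| preset         | thresholds                         | beta | notes |
|----------------|------------------------------------|------|-------|
| `normosmic`    | Normal(10.5/1.12, sqrt(16.6)/1.12) | 1.12 | healthy adults; stored as exact quotients (≈ 9.4 / 3.6 steps) |
| `nshap_normal` | Normal(2.4, 3.0)                   | 0.76 | older adults, as fitted |
| `nshap_gamma`  | −3 + Gamma(3.35, 1.61)             | 0.76 | same mean (2.39) and SD (2.95), right-skewed, no mass below step −3 (64% v/v) |

The shifted gamma replaces the Normal for older adults because a Normal
puts implausible mass at very strong concentrations; the gamma instead
gives P(t ≤ −1) = 0.086, P(t ≤ −2) = 0.013, and exactly 0 below −3.
Abilities are generated as `alpha_i = beta * t_i`.

## Staircase simulator

Rules: start at pen 15 or 16 (random); a correct response triggers a
confirmation presentation of the same pen; two consecutive corrects
move one step weaker; any incorrect moves one step stronger; every
change of movement direction is a reversal; stop at 7 reversals and
score the mean of the last 4 reversal steps.  Declared conventions the
protocol descriptions leave open: the first movement sets the direction
without logging a reversal; a reversal is recorded at the step being
presented when the direction flips; the consecutive-correct counter
resets on any movement or incorrect.

By default the simulated walk uses an *unlimited* virtual dilution
ladder (`clamp=False`): subjects whose thresholds lie outside the
physical pen range keep walking rather than bouncing against pens 1/16,
so the estimated reliability measures the staircase procedure itself
rather than range censoring.  This choice is what reproduces the
published reliabilities of the staircase under both the normosmic
(~0.86) and older-adult (~0.41) populations; with a hard range the
simulated reliabilities drop to ~0.845 and ~0.34 because floor/ceiling
pile-ups compress the score scale.  `clamp=True` restores the physical
administration: boundary pens are re-presented, scores are confined to
[1, 16], and runs that cannot accumulate enough reversals are flagged
censored with a capped score.  `max_presentations` (default 200) is a
termination guarantee only; censoring at 200 is negligible for all
preset populations.

## Fitting

The random-effects likelihood integrates each subject's Bernoulli
likelihood over `alpha ~ N(mu_alpha, sigma_alpha^2)`.  The integral
uses Gauss–Hermite quadrature (default 21 nodes) made adaptive by
iterated recentering: nodes start at the prior mean/SD and are re-placed
three times at each subject's running posterior mean/SD.  This
derivative-free form of adaptive quadrature matches brute-force
integration to better than 1e-6 relative error on small instances (at
61 nodes; the 21-node default is accurate to ~1e-5, ample for
estimation).  Subjects who received the same stimulus sequence and gave
the same response pattern contribute identical likelihood terms, so the
model collapses them to weighted unique patterns (a 6-item design has
at most 64), making the fit cost independent of sample size for short
protocols.

Optimization is L-BFGS-B over `(log beta, mu_alpha, log sigma)` with an
analytic gradient obtained from the Fisher identity (posterior
expectation of the complete-data score on the same quadrature grid).
Starting values come from regressing the logit of guess-corrected
per-step accuracies on step; if the first attempt fails, a short ladder
of alternative starts is tried — sparse designs placed far from the
population's thresholds can otherwise send the optimizer to a
degenerate boundary that is not the maximum.  Standard errors are
delta-method transforms of the inverse numerical Hessian on the working
scale.  A fit is flagged *non-converged* when the optimizer fails, any
working parameter sits at its box bound (log beta in ±4, mu in ±200,
log sigma in ±6), or the observed information is not positive definite;
replication summaries aggregate over converged replications only and
report the failure percentage separately.  Failure rates are
optimizer-specific: this implementation converges in ≈100% of the
preset conditions, more often than older quadrature software on sparse
designs.

Degenerate inputs: fits with all responses correct (or incorrect) run
`sigma` or `beta` to a bound and are flagged rather than raised; a
zero-variance population drives `var_alpha` toward 0 and is likewise
flagged at the bound while still recovering `mu_alpha`.

## Threshold prediction

`empirical_bayes()` returns each subject's posterior ability mean and
SD under the fitted Normal prior, and the plug-in threshold
`alpha_eb / beta_hat`.  These are shrunk toward the population mean
(posterior SD ≤ prior SD always), which trades conditional bias in the
tails for the elimination of regression attenuation when thresholds are
used as covariates.  Under the correctly specified model the cohort
mean of EB thresholds is unbiased for the population mean.  When the
true threshold distribution is skewed (gamma) but the prior is Normal,
a small negative bias of the cohort mean appears (≈ 0.2 steps at the
older-adult settings), from the prior misspecification and the
nonlinearity of the ratio; reliability statements are unaffected since
they are correlation-based.  Per-subject maximum-likelihood fitting
(`fit_per_subject`) is provided for long protocols; it flags complete
separation (all correct / all incorrect) as non-estimable.

## Survey non-response

"Don't know" and "refused" responses are not incorrect: a forced guess
would succeed 1/3 of the time, so treating them as 0 biases thresholds
downward.  `impute_responses` replaces each such record with an
independent Bernoulli(1/3) draw across `m` imputations (default 10; DK
and REF are distinct codes in files but identical to the imputer).
Parameter estimates are pooled by Rubin's rules (total variance =
within + (1 + 1/m) · between); per-subject thresholds are pooled by
their mean across imputations.  `sum_score` provides the simple 0–6
correct count (non-response counted incorrect) as an unmodeled
alternative.

## Replication engine

`run_replications` repeats, with independent seed substreams spawned
per replication from one master seed: draw `n` thresholds → simulate
the protocol → estimate thresholds (EB for constant stimuli; last-4
reversal score or IRT for the staircase) → record the Pearson
correlation `r` with truth.  *Reliability* is `r^2` per replication;
the summary reports the mean of the per-replication `r^2` (not the
square of the mean `r`), its SE, the 5/50/95 percentiles, and the
convergence-failure percentage.  `method_correlation` administers both
protocols to the same ability draws with independent response noise.
Execution is serial; results are bit-reproducible for a given seed.

## Problem sizes and numerical defaults

Simulated checks use 100 subjects per replication for the normosmic
conditions and 2 000 for the older-adult conditions, matching the study
designs they emulate.  Replication counts in the test suite and the
acceptance script range from 100 to 500 per condition; per-replication
reliabilities have SD ≈ 0.03, so 100 replications determine a mean to
≈ 0.003 — far finer than the 0.02–0.04 tolerances used.  Quadrature
defaults (21 nodes, 3 recentering passes) change `beta_hat` by < 1e-3
relative to 61 nodes.

## What the simulations do and do not show

The generator emulates exactly the assumed response model, so recovered
reliabilities describe a world where the IRT model is true (for the
gamma population, true up to the threshold distribution's shape).  Real
administrations add day-to-day variability in subjects and
administrators, pen-concentration drift with use, odorant differences,
possible learning effects, and a truly anosmic subgroup — none of which
the model represents.  Published human test-retest reliabilities are
accordingly slightly below the simulation values; simulation-based
reliability should be read as an upper bound that ranks designs, not as
a forecast of a specific test-retest coefficient.  Mixture models for
anosmia and learning-effect terms are out of scope.
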