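# olfthresh

Design, simulation and model-based scoring of short olfactory threshold
tests.

Psychophysical threshold testing with the Sniffin' Sticks n-butanol
series (a doubling-dilution ladder: step 1 = 4% v/v, each +1 step halves
the concentration) normally uses an adaptive 3-alternative forced-choice
staircase that takes up to 20 minutes — infeasible in household surveys
and other field settings. `olfthresh` provides the machinery to design
and evaluate much shorter constant-stimuli protocols for a given target
population:

* a **3AFC logistic item-response model** with a guessing floor,

  P(Y<sub>ij</sub> = 1) = 1/3 + 2/3 · logit⁻¹(α<sub>i</sub> − β·d<sub>ij</sub>),
  α<sub>i</sub> ~ N(μ<sub>α</sub>, σ²<sub>α</sub>),

  fitted by marginal maximum likelihood with adaptive Gauss–Hermite
  quadrature.  A subject's threshold is the dilution step detected with
  probability 2/3, i.e. α<sub>i</sub>/β, predicted by empirical Bayes
  (shrunk toward the population mean, unconditionally unbiased, and
  free of regression-attenuation bias when used as a covariate);
* **protocol simulators** for the adaptive staircase (two consecutive
  corrects → weaker, any incorrect → stronger, stop after 7 reversals,
  score = mean of the last 4 reversal steps) and for arbitrary
  constant-stimuli designs, driven by the same response model;
* **population presets** (normosmic adults; older-adult survey
  populations with Normal or right-skewed shifted-gamma threshold
  distributions) plus chance-level multiple imputation for
  "don't know"/"refused" survey responses;
* a **Monte-Carlo replication engine** that estimates the reliability
  (squared Pearson correlation between estimated and true thresholds)
  of any candidate protocol for any population, so a new instrument can
  be validated by simulation instead of a human test-retest study.

## Worked example

Simulate a survey administration of the 6-pen protocol (steps
6,5,4,2,1,0) to 2 000 older adults whose thresholds follow the skewed
preset distribution, fit the IRT model, and ask how reliable the
instrument is:

```python
import numpy as np
import olfthresh as ot

pop = ot.preset("nshap_gamma")          # gamma(3.35, 1.61, -3), beta = 0.76
rng = np.random.default_rng(5)
truth = pop.sample_thresholds(2000, rng)
table = ot.simulate_constant_stimuli(
    truth, pop.beta, ot.ConstantStimuliProtocol(ot.NSHAP_STEPS), rng)

res = ot.ThresholdIRT.from_dataframe(table).fit()
print(res.summary())
eb = res.empirical_bayes()              # per-subject thresholds
print("r^2 vs truth:", round(ot.reliability(eb["threshold_eb"], truth)[1], 3))
```

```
Random-effects 3AFC logistic IRT (marginal ML)
==========================================================
Subjects:   2000    Presentations:   12000
Quadrature nodes: 21   Log-likelihood: -7149.475
Converged: True
----------------------------------------------------------
                estimate     std err
beta              0.7277      0.0345
mu_alpha          1.6753      0.0958
var_alpha         4.6703      0.5312
----------------------------------------------------------
mean threshold (mu_alpha/beta): 2.302 steps
threshold SD  (sigma/beta):     2.970 steps
==========================================================
r^2 vs truth: 0.583
```

The fit recovers the generating slope (0.73 vs 0.76) and the threshold
distribution (mean 2.3, SD 3.0 steps), and a single replication puts
the protocol's reliability near 0.58.  Averaging over many replications
(`ot.run_replications(...)`) gives ~0.56: six well-placed pens retain
most of the information of the full 16-pen series for this population.

A `olfthresh` command-line tool exposes the same workflow
(`simulate | fit | evaluate | design | fixtures`) over YAML run
configurations and CSV response files; every output directory contains
the resolved configuration and master seed needed to reproduce it.

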