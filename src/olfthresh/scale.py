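"""Dilution-step scale and the 3AFC psychometric response function.

The Sniffin' Sticks n-butanol threshold series is a doubling-dilution
series: step 1 is a 4% v/v solution and each +1 step halves the
concentration (step 16 is 4% x 1/2**15 ~ 1.22 ppm).  Steps at or below
zero denote stronger pens (step 0 = 8%, step -1 = 16%, ...), used when
testing populations with poor olfaction.

In a 3-alternative forced-choice (3AFC) presentation the subject picks
the odorant pen out of three, so even an insensitive subject is correct
with probability 1/3.  The probability of a correct response for a
subject with latent ability ``alpha`` presented dilution step ``d`` is

    P(correct) = 1/3 + 2/3 * expit(alpha - beta * d)

where ``beta > 0`` is the slope of the psychometric function per
dilution step.  Setting P(correct) = 2/3 and solving for ``d`` gives the
subject's threshold ``alpha / beta`` — the dilution step detected
two-thirds of the time.

Steps are real-valued in the model (thresholds and reversal averages are
continuous); physical protocols restrict presentations to integers.
Concentrations are v/v fractions internally; percent and ppm are display
conversions only.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "GUESS_FLOOR",
    "REFERENCE_CONCENTRATION",
    "p_correct",
    "threshold_from_ability",
    "step_to_concentration",
    "concentration_to_step",
]

#: Chance-correct probability in a 3AFC task.
GUESS_FLOOR = 1.0 / 3.0

#: v/v fraction of n-butanol at dilution step 1.
REFERENCE_CONCENTRATION = 0.04


def _check_beta(beta) -> None:
    if not np.all(np.asarray(beta) > 0):
        raise ValueError("beta (slope per dilution step) must be positive")


def p_correct(alpha, step, beta):
    """Probability of a correct 3AFC response.

    Parameters
    ----------
    alpha : array_like
        Latent olfactory ability (logit scale).
    step : array_like
        Dilution step presented (real-valued; larger = weaker).
    beta : array_like
        Slope of the psychometric function per dilution step; must be > 0.

    Returns
    -------
    ndarray or float
        ``1/3 + 2/3 * expit(alpha - beta*step)``, strictly inside
        (1/3, 1) for finite arguments.
    """
    _check_beta(beta)
    alpha = np.asarray(alpha, dtype=float)
    step = np.asarray(step, dtype=float)
    out = GUESS_FLOOR + (2.0 / 3.0) * expit(alpha - np.asarray(beta, float) * step)
    return out if out.ndim else float(out)


def threshold_from_ability(alpha, beta):
    """Dilution step at which P(correct) = 2/3, i.e. ``alpha / beta``."""
    _check_beta(beta)
    out = np.asarray(alpha, dtype=float) / np.asarray(beta, dtype=float)
    return out if out.ndim else float(out)


def step_to_concentration(step):
    """v/v n-butanol fraction of a dilution step: ``0.04 * 2**(1 - step)``."""
    step = np.asarray(step, dtype=float)
    out = REFERENCE_CONCENTRATION * np.exp2(1.0 - step)
    return out if out.ndim else float(out)


def concentration_to_step(concentration):
    """Inverse of :func:`step_to_concentration`; concentration must be > 0."""
    c = np.asarray(concentration, dtype=float)
    if not np.all(c > 0):
        raise ValueError("concentration must be a positive v/v fraction")
    out = 1.0 - np.log2(c / REFERENCE_CONCENTRATION)
    return out if out.ndim else float(out)
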