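"""Population threshold distributions and ability sampling.

A :class:`PopulationModel` describes how olfactory thresholds (on the
dilution-step scale) are distributed in a target population, together
with the slope ``beta`` of the psychometric function used to generate
responses.  Abilities are derived as ``alpha_i = beta * t_i``.

Two families are supported:

* ``normal`` — thresholds ~ N(mean, sd**2); the random-effects IRT model
  assumes this family.
* ``shifted_gamma`` — thresholds ~ location + Gamma(shape, scale); a
  positively skewed alternative with hard lower support at ``location``,
  appropriate for older-adult populations where no one's threshold lies
  below a strong-pen floor.

Built-in presets encode the fitted distributions this package ships as
generative constants:

* ``normosmic`` — normal thresholds with mean 10.5/1.12 and SD
  sqrt(16.6)/1.12, beta = 1.12 (fit to 590 normosmic adults; stored as
  exact quotients, printed as 9.4 / 3.6).
* ``nshap_normal`` — normal(2.4, 3.0), beta = 0.76 (NSHAP Wave-2 older
  adults, as fitted).
* ``nshap_gamma`` — shifted gamma(shape 3.35, scale 1.61, location -3),
  beta = 0.76; same mean (2.39) and SD (2.95) as ``nshap_normal`` but
  skewed, with zero mass below step -3 (64% n-butanol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PopulationModel", "preset", "PRESETS"]

_FAMILIES = ("normal", "shifted_gamma")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PopulationModel:
    """Threshold distribution (step units) plus the response slope beta."""

    family: str
    params: tuple
    beta: float

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.family == "normal":
            mean, sd = self.params
            if not sd > 0:
                raise ValueError("normal family requires sd > 0")
        else:
            shape, scale, _loc = self.params
            if not (shape > 0 and scale > 0):
                raise ValueError("shifted_gamma requires shape > 0 and scale > 0")

    # -- constructors -------------------------------------------------
    @classmethod
    def normal(cls, mean: float, sd: float, beta: float) -> "PopulationModel":
        return cls("normal", (float(mean), float(sd)), float(beta))

    @classmethod
    def shifted_gamma(cls, shape: float, scale: float, location: float,
                      beta: float) -> "PopulationModel":
        return cls("shifted_gamma", (float(shape), float(scale), float(location)),
                   float(beta))

    # -- distribution -------------------------------------------------
    @property
    def _dist(self):
        if self.family == "normal":
            mean, sd = self.params
            return stats.norm(loc=mean, scale=sd)
        shape, scale, loc = self.params
        return stats.gamma(shape, loc=loc, scale=scale)

    @property
    def mean_threshold(self) -> float:
        return float(self._dist.mean())

    @property
    def sd_threshold(self) -> float:
        return float(self._dist.std())

    @property
    def mean_alpha(self) -> float:
        return self.beta * self.mean_threshold

    @property
    def var_alpha(self) -> float:
        return (self.beta * self.sd_threshold) ** 2

    def sample_thresholds(self, n: int, seed) -> np.ndarray:
        """Draw ``n`` i.i.d. thresholds (step units); reproducible given seed."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = _as_rng(seed)
        if self.family == "normal":
            mean, sd = self.params
            return rng.normal(mean, sd, size=n)
        shape, scale, loc = self.params
        return loc + scale * rng.standard_gamma(shape, size=n)

    def sample_abilities(self, n: int, seed) -> np.ndarray:
        """Draw abilities ``alpha_i = beta * t_i``."""
        return self.beta * self.sample_thresholds(n, seed)

    def cdf_threshold(self, t) -> float:
        """P(threshold <= t); zero below the shifted-gamma location."""
        out = self._dist.cdf(np.asarray(t, dtype=float))
        return out if out.ndim else float(out)


def _normosmic() -> PopulationModel:
    # exact quotients of the fitted alpha-scale moments, not the rounded prints
    return PopulationModel.normal(10.5 / 1.12, math.sqrt(16.6) / 1.12, beta=1.12)


PRESETS = {
    "normosmic": _normosmic,
    "nshap_normal": lambda: PopulationModel.normal(2.4, 3.0, beta=0.76),
    "nshap_gamma": lambda: PopulationModel.shifted_gamma(3.35, 1.61, -3.0, beta=0.76),
}


def preset(name: str) -> PopulationModel:
    """Return a built-in :class:`PopulationModel` by name."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown population preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
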