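"""Prior distributions for scalar parameters.

Hand-coded log-densities (these sit on the MCMC hot path); sampling
delegates to numpy.  Every prior exposes ``log_pdf(x)`` and
``sample(rng)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

NEG_INF = float("-inf")
LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LogNormal:
    meanlog: float
    sdlog: float

    def log_pdf(self, x):
        if x <= 0:
            return NEG_INF
        z = (math.log(x) - self.meanlog) / self.sdlog
        return -0.5 * (z * z + LOG_2PI) - math.log(self.sdlog) - math.log(x)

    def sample(self, rng):
        return math.exp(rng.normal(self.meanlog, self.sdlog))


@dataclass(frozen=True)
class Exponential:
    mean: float

    def log_pdf(self, x):
        if x < 0:
            return NEG_INF
        return -math.log(self.mean) - x / self.mean

    def sample(self, rng):
        return rng.exponential(self.mean)


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def log_pdf(self, x):
        if self.low <= x <= self.high:
            return -math.log(self.high - self.low)
        return NEG_INF

    def sample(self, rng):
        return rng.uniform(self.low, self.high)


@dataclass(frozen=True)
class Gamma:
    shape: float
    scale: float

    def log_pdf(self, x):
        if x <= 0:
            return NEG_INF
        return ((self.shape - 1.0) * math.log(x) - x / self.scale
                - math.lgamma(self.shape) - self.shape * math.log(self.scale))

    def sample(self, rng):
        return rng.gamma(self.shape, self.scale)


@dataclass(frozen=True)
class InverseGamma:
    shape: float
    scale: float  # beta; mean = beta / (shape - 1)

    def log_pdf(self, x):
        if x <= 0:
            return NEG_INF
        return (self.shape * math.log(self.scale)
                - math.lgamma(self.shape)
                - (self.shape + 1.0) * math.log(x) - self.scale / x)

    def sample(self, rng):
        return self.scale / rng.gamma(self.shape, 1.0)


@dataclass(frozen=True)
class Fixed:
    value: float

    def log_pdf(self, x):
        return 0.0 if x == self.value else NEG_INF

    def sample(self, rng):
        return self.value


def prior_from_config(spec):
    """Build a prior from a config mapping like
    ``{"lognormal": {"meanlog": 0, "sdlog": 1}}`` or ``{"fixed": 2.0}``."""
    if isinstance(spec, (int, float)):
        return Fixed(float(spec))
    (kind, args), = spec.items()
    kind = kind.lower()
    table = {"lognormal": LogNormal, "exponential": Exponential,
             "uniform": Uniform, "gamma": Gamma,
             "inversegamma": InverseGamma, "fixed": Fixed}
    cls = table[kind]
    if isinstance(args, dict):
        return cls(**args)
    if isinstance(args, (list, tuple)):
        return cls(*args)
    return cls(args)
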