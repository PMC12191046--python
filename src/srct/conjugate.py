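"""Conjugate Bayesian machinery for binary and event-time endpoints.

Small randomized comparative trials (SRCTs) evaluate each arm's response
(Res) and severe-toxicity (Tox) probabilities from binomial counts.  With a
beta(a, b) prior on a probability ``theta`` and ``X`` events out of ``n``
evaluated patients, the posterior is beta(a + X, b + n - X).  Its mean,

    (a + X) / (a + b + n)
        = w * (X / n) + (1 - w) * a / (a + b),      w = n / (n + a + b),

shrinks the empirical rate toward the prior mean with weight proportional to
the prior's effective sample size ESS = a + b.  Operational priors are
elicited as a (mean, ESS) pair with ESS = 1 or 2 so that the data dominate.

Median event-time (e.g., PFS) summaries use the exponential-gamma conjugate
pair: with an exponential hazard ``lam ~ gamma(shape, rate)``, observing
``k`` events over total follow-up ``T`` gives posterior
gamma(shape + k, rate + T), and the median time is ``ln 2 / lam``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "ConfigError",
    "BetaParams",
    "BinomialCount",
    "Interval",
    "GammaParams",
    "EventTimeData",
    "prior_from_mean",
    "update_beta",
    "posterior_mean",
    "shrinkage_weights",
    "credible_interval",
    "tail_probability",
    "update_gamma_exponential",
    "median_time_interval",
]


class ConfigError(ValueError):
    """A design/configuration input violates its contract."""


@dataclass(frozen=True)
class BetaParams:
    """Pseudo-count parameterization beta(alpha, beta_) of a prior/posterior.

    ``alpha`` counts events (responders or toxicities), ``beta_`` counts
    non-events; both must be strictly positive.
    """

    alpha: float
    beta_: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha}")
        if not (self.beta_ > 0 and math.isfinite(self.beta_)):
            raise ValueError(f"beta_ must be a positive finite real, got {self.beta_}")

    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta_)

    def ess(self) -> float:
        """Effective sample size a + b: the prior's weight in patients."""
        return self.alpha + self.beta_

    def distribution(self):
        """The frozen scipy beta distribution these parameters govern."""
        return stats.beta(self.alpha, self.beta_)


_COUNT_RE = re.compile(r"^\s*(\d+)\s*/\s*(\d+)\s*$")


@dataclass(frozen=True)
class BinomialCount:
    """``events`` patients with the outcome out of ``total`` evaluated."""

    events: int
    total: int

    def __post_init__(self) -> None:
        if self.events != int(self.events) or self.total != int(self.total):
            raise ValueError("counts must be integers")
        if not (0 <= self.events <= self.total):
            raise ValueError(
                f"need 0 <= events <= total, got {self.events}/{self.total}"
            )

    @classmethod
    def from_string(cls, text: str) -> "BinomialCount":
        """Parse an ``"x/n"`` count string such as ``"8/20"``."""
        m = _COUNT_RE.match(text)
        if m is None:
            raise ValueError(f"cannot parse count {text!r}; expected 'x/n'")
        return cls(int(m.group(1)), int(m.group(2)))

    def __add__(self, other: "BinomialCount") -> "BinomialCount":
        return BinomialCount(self.events + other.events, self.total + other.total)

    def proportion(self) -> float:
        if self.total == 0:
            raise ZeroDivisionError("no patients evaluated")
        return self.events / self.total

    def __str__(self) -> str:
        return f"{self.events}/{self.total}"


@dataclass(frozen=True)
class Interval:
    """Equal-tailed credible interval [lower, upper] at posterior mass ``level``."""

    level: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class GammaParams:
    """gamma(shape, rate) prior/posterior for an exponential event hazard."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ValueError(f"shape must be positive, got {self.shape}")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    def distribution(self):
        return stats.gamma(self.shape, scale=1.0 / self.rate)


@dataclass(frozen=True)
class EventTimeData:
    """``n_events`` observed events over ``total_time`` patient-time of follow-up."""

    n_events: int
    total_time: float

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        if self.total_time < 0 or (self.n_events > 0 and self.total_time <= 0):
            raise ValueError("total_time must be positive when events are observed")


def prior_from_mean(mean: float, ess: float) -> BetaParams:
    """Beta prior elicited from its mean and effective sample size.

    Solves mean = a / (a + b) with a + b = ess, the standard operational
    construction: e.g. an elicited response mean of 0.40 at ESS 1 gives
    beta(0.40, 0.60).  Degenerate means 0 and 1 are rejected.
    """
    if not 0 < mean < 1:
        raise ValueError(f"prior mean must lie strictly inside (0, 1), got {mean}")
    if not ess > 0:
        raise ValueError(f"prior ESS must be positive, got {ess}")
    return BetaParams(mean * ess, (1.0 - mean) * ess)


def update_beta(prior: BetaParams, data: BinomialCount) -> BetaParams:
    """Conjugate update: beta(a, b) + X/n -> beta(a + X, b + n - X)."""
    return BetaParams(prior.alpha + data.events, prior.beta_ + data.total - data.events)


def posterior_mean(p: BetaParams) -> float:
    return p.mean()


def shrinkage_weights(prior: BetaParams, data: BinomialCount) -> tuple[float, float]:
    """Weights (on the sample proportion, on the prior mean) in the posterior mean.

    Returns ``(n / (n + ESS), ESS / (n + ESS))``; with n = 0 the data weight
    is 0 and the posterior mean is the prior mean.
    """
    n = data.total
    ess = prior.ess()
    w_data = n / (n + ess)
    return w_data, 1.0 - w_data


def credible_interval(p: BetaParams, level: float = 0.95) -> Interval:
    """Equal-tailed credible interval from beta quantiles at (1 +/- level)/2."""
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    dist = p.distribution()
    return Interval(level, float(dist.ppf(tail)), float(dist.ppf(1.0 - tail)))


def tail_probability(p: BetaParams, threshold: float, direction: str = "above") -> float:
    """Pr(theta > threshold | p) for ``"above"``, Pr(theta < threshold) for ``"below"``."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    dist = p.distribution()
    if direction == "above":
        return float(dist.sf(threshold))
    if direction == "below":
        return float(dist.cdf(threshold))
    raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")


def update_gamma_exponential(prior: GammaParams, data: EventTimeData) -> GammaParams:
    """Conjugate update of the exponential hazard: shape += events, rate += time."""
    return GammaParams(prior.shape + data.n_events, prior.rate + data.total_time)


def median_time_interval(post: GammaParams, level: float = 0.95) -> Interval:
    """Credible interval for the median event time ln 2 / hazard.

    The median time is a decreasing transform of the hazard, so the interval
    endpoints are the hazard quantiles with upper and lower swapped.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    dist = post.distribution()
    return Interval(
        level,
        math.log(2.0) / float(dist.ppf(1.0 - tail)),
        math.log(2.0) / float(dist.ppf(tail)),
    )
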