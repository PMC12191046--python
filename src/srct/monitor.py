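"""Posterior-probability safety and futility stopping rules.

A safety rule terminates accrual to an arm when the posterior probability
that its toxicity rate exceeds the largest acceptable value theta* passes a
cutoff:  Pr(theta_Tox > theta* | data) > c.  A variant replaces the fixed
limit with a highly informative random comparator (e.g. beta(200, 800) for a
reference rate of 0.20) and stops when Pr(theta_E > theta_S | data) > c.
Futility rules mirror this below a smallest acceptable response rate:
Pr(theta_Res < theta* | data) > c.

Cutoffs are either constant or the sample-size-adaptive family
alpha * (n / N)^beta.  Because data enter only through the event count at
each scheduled look, every rule is equivalent to a table of integer trigger
boundaries ("stop if >= x/n"), which this module derives by enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .compare import improvement_probability
from .conjugate import (
    BetaParams,
    BinomialCount,
    ConfigError,
    prior_from_mean,
    tail_probability,
    update_beta,
)

__all__ = [
    "MonitoringSchedule",
    "CutoffSpec",
    "SafetyRule",
    "FutilityRule",
    "BoundaryEntry",
    "BoundaryTable",
    "cutoff_at",
    "default_rule_prior",
    "criterion_probability",
    "safety_stop",
    "futility_stop",
    "boundary_table",
]


@dataclass(frozen=True)
class MonitoringSchedule:
    """Interim looks (per-arm evaluated counts) below the per-arm maximum.

    The final analysis at ``n_max`` is not a stopping look; a design that
    wants one must list it explicitly in ``looks``.
    """

    looks: tuple[int, ...]
    n_max: int

    def __post_init__(self) -> None:
        looks = tuple(int(n) for n in self.looks)
        object.__setattr__(self, "looks", looks)
        if not looks:
            raise ConfigError("schedule needs at least one look")
        if any(n <= 0 for n in looks) or any(
            b <= a for a, b in zip(looks, looks[1:])
        ):
            raise ConfigError(f"looks must be strictly increasing positives, got {looks}")
        if looks[-1] > self.n_max:
            raise ConfigError(
                f"looks {looks} must not exceed per-arm maximum {self.n_max}"
            )


@dataclass(frozen=True)
class CutoffSpec:
    """Decision cutoff: constant c, or the power family alpha * (n/N)^beta."""

    kind: str  # "constant" | "power"
    c: Optional[float] = None
    alpha_: Optional[float] = None
    beta_exp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.c is None or not 0 < self.c < 1:
                raise ConfigError(f"constant cutoff needs 0 < c < 1, got {self.c}")
        elif self.kind == "power":
            if self.alpha_ is None or not 0 < self.alpha_ <= 1:
                raise ConfigError(f"power cutoff needs alpha in (0, 1], got {self.alpha_}")
            if self.beta_exp is None or self.beta_exp < 0:
                raise ConfigError(f"power cutoff needs beta >= 0, got {self.beta_exp}")
        else:
            raise ConfigError(f"unknown cutoff kind {self.kind!r}")

    @classmethod
    def constant(cls, c: float) -> "CutoffSpec":
        return cls(kind="constant", c=c)

    @classmethod
    def power(cls, alpha: float, beta: float) -> "CutoffSpec":
        return cls(kind="power", alpha_=alpha, beta_exp=beta)


def cutoff_at(spec: CutoffSpec, n: int, n_max: int) -> float:
    """Evaluate the cutoff at interim sample size n of per-arm maximum n_max."""
    if not 0 < n <= n_max:
        raise ConfigError(f"need 0 < n <= n_max, got n={n}, n_max={n_max}")
    if spec.kind == "constant":
        return float(spec.c)
    value = spec.alpha_ * (n / n_max) ** spec.beta_exp
    if not 0 < value < 1:
        raise ConfigError(f"cutoff {value} at n={n} falls outside (0, 1)")
    return float(value)


def default_rule_prior(limit: float) -> BetaParams:
    """Operational rule prior beta(theta*, 1 - theta*): mean theta*, ESS 1."""
    return prior_from_mean(limit, 1.0)


@dataclass(frozen=True)
class SafetyRule:
    """Stop if Pr(theta_Tox > theta* | data) > cutoff (or > comparator for the
    random-comparator variant).  ``limit`` is theta*, the largest acceptable
    toxicity probability; ``unacceptable`` is the larger theta** used when
    calibrating operating characteristics.  The comparator posterior, when
    present, is never updated by trial data."""

    prior: BetaParams
    limit: float
    unacceptable: float
    cutoff: CutoffSpec
    schedule: MonitoringSchedule
    comparator: Optional[BetaParams] = None

    def __post_init__(self) -> None:
        if not 0 < self.limit < self.unacceptable <= 1:
            raise ConfigError(
                f"need 0 < theta* < theta**, got {self.limit}, {self.unacceptable}"
            )


@dataclass(frozen=True)
class FutilityRule:
    """Stop if Pr(theta_Res < theta* | data) > cutoff.  ``limit`` is theta*,
    the smallest acceptable response probability; ``unacceptable`` < theta*."""

    prior: BetaParams
    limit: float
    unacceptable: float
    cutoff: CutoffSpec
    schedule: MonitoringSchedule

    def __post_init__(self) -> None:
        if not 0 <= self.unacceptable < self.limit < 1:
            raise ConfigError(
                f"need theta** < theta* in (0, 1), got {self.unacceptable}, {self.limit}"
            )


Rule = Union[SafetyRule, FutilityRule]


def criterion_probability(rule: Rule, data: BinomialCount) -> float:
    """The rule's posterior stopping criterion evaluated on interim data."""
    post = update_beta(rule.prior, data)
    if isinstance(rule, SafetyRule):
        if rule.comparator is not None:
            return improvement_probability(post, rule.comparator, 0.0)
        return tail_probability(post, rule.limit, "above")
    return tail_probability(post, rule.limit, "below")


def _check_look(rule: Rule, data: BinomialCount) -> None:
    if data.total not in rule.schedule.looks:
        raise ConfigError(
            f"n={data.total} is not a scheduled look {rule.schedule.looks}"
        )


def safety_stop(rule: SafetyRule, data: BinomialCount) -> bool:
    """True when the safety criterion strictly exceeds the cutoff at this look."""
    if not isinstance(rule, SafetyRule):
        raise TypeError("safety_stop needs a SafetyRule")
    _check_look(rule, data)
    c = cutoff_at(rule.cutoff, data.total, rule.schedule.n_max)
    return criterion_probability(rule, data) > c


def futility_stop(rule: FutilityRule, data: BinomialCount) -> bool:
    if not isinstance(rule, FutilityRule):
        raise TypeError("futility_stop needs a FutilityRule")
    _check_look(rule, data)
    c = cutoff_at(rule.cutoff, data.total, rule.schedule.n_max)
    return criterion_probability(rule, data) > c


@dataclass(frozen=True)
class BoundaryEntry:
    look_n: int
    trigger: Optional[int]  # None when no count at this look can stop
    criterion_at_trigger: Optional[float]


@dataclass(frozen=True)
class BoundaryTable:
    """Integer trigger counts equivalent to a posterior stopping rule.

    Safety: stop when events >= trigger.  Futility: stop when events <=
    trigger.  ``kind`` records which comparison applies.
    """

    kind: str  # "safety" | "futility"
    entries: tuple[BoundaryEntry, ...]

    @property
    def looks(self) -> tuple[int, ...]:
        return tuple(e.look_n for e in self.entries)

    def trigger_at(self, look_n: int) -> Optional[int]:
        for e in self.entries:
            if e.look_n == look_n:
                return e.trigger
        raise ConfigError(f"{look_n} is not a look of this table")

    def stops(self, look_n: int, events: int) -> bool:
        trig = self.trigger_at(look_n)
        if trig is None:
            return False
        return events >= trig if self.kind == "safety" else events <= trig

    def to_text(self) -> str:
        """Protocol-ready line, e.g. ``stop if >= 3/4, 5/8, 6/12``."""
        op = ">=" if self.kind == "safety" else "<="
        parts = [
            f"{e.trigger}/{e.look_n}" if e.trigger is not None else f"-/{e.look_n}"
            for e in self.entries
        ]
        return f"stop if {op} " + ", ".join(parts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "look_n": [e.look_n for e in self.entries],
                "trigger": [e.trigger for e in self.entries],
                "criterion_value_at_trigger": [
                    e.criterion_at_trigger for e in self.entries
                ],
            }
        )


def boundary_table(rule: Rule) -> BoundaryTable:
    """Derive the integer trigger boundary at every scheduled look.

    Safety: the smallest event count whose criterion strictly exceeds the
    cutoff (monotone increasing in events).  Futility: the largest response
    count that still triggers (criterion decreasing in events).  Comparing
    observed counts against the table reproduces the rule exactly.
    """
    kind = "safety" if isinstance(rule, SafetyRule) else "futility"
    entries = []
    for look in rule.schedule.looks:
        c = cutoff_at(rule.cutoff, look, rule.schedule.n_max)
        trigger: Optional[int] = None
        crit: Optional[float] = None
        counts = range(look + 1) if kind == "safety" else range(look, -1, -1)
        for x in counts:
            p = criterion_probability(rule, BinomialCount(x, look))
            if p > c:
                trigger, crit = x, p
                break
        entries.append(BoundaryEntry(look, trigger, crit))
    return BoundaryTable(kind=kind, entries=tuple(entries))
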