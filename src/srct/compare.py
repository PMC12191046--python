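"""Posterior comparison of treatment arms via the difference of two betas.

Arms are modeled as independent: theta_E ~ beta(aE, bE), theta_S ~ beta(aS, bS).
The distribution of theta_E - theta_S has no closed form; its CDF is computed
by adaptive quadrature of

    Pr(theta_E - theta_S <= d) = int_0^1 f_S(v) F_E(clip(v + d, 0, 1)) dv,

which backs equal-tailed credible intervals for the treatment effect and the
improvement probability Pr(theta_E > theta_S + delta | data) used to judge
whether an experimental arm beats the reference by a clinically meaningful
margin (delta = 0.15 or 0.20 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .conjugate import BetaParams, ConfigError, Interval

__all__ = [
    "ArmPosterior",
    "DifferenceSummary",
    "StratumWeight",
    "DEFAULT_DELTAS",
    "difference_cdf",
    "improvement_probability",
    "difference_interval",
    "difference_mean",
    "summarize_difference",
    "compare_arms",
    "comparison_table",
    "post_stratified_difference",
]

#: Conventional clinically meaningful improvement margins.
DEFAULT_DELTAS: tuple[float, ...] = (0.15, 0.20)

_QUAD_ABS_TOL = 1e-10
_ROOT_TOL = 1e-9


@dataclass(frozen=True)
class ArmPosterior:
    label: str
    params: BetaParams


@dataclass(frozen=True)
class DifferenceSummary:
    """Posterior summary of theta_E - theta_S for one contrast."""

    mean: float
    interval: Interval
    improvement: Mapping[float, float]  # delta -> Pr(theta_E > theta_S + delta)


@dataclass(frozen=True)
class StratumWeight:
    """One stratum of a post-stratified comparison.

    Each arm is either a ``BetaParams`` posterior or a known probability
    (a float), the latter matching textbook mixture arithmetic exactly.
    """

    weight: float
    arm_e: Union[BetaParams, float]
    arm_s: Union[BetaParams, float]


def difference_cdf(post_e: BetaParams, post_s: BetaParams, d: float) -> float:
    """Pr(theta_E - theta_S <= d) by adaptive quadrature (abs. tol 1e-10)."""
    if d <= -1.0:
        return 0.0
    if d >= 1.0:
        return 1.0
    f_s = post_s.distribution().pdf
    cdf_e = post_e.distribution().cdf

    def integrand(v: float) -> float:
        u = v + d
        if u <= 0.0:
            return 0.0
        if u >= 1.0:
            return f_s(v)
        return f_s(v) * cdf_e(u)

    # kinks where v + d crosses the [0, 1] support of theta_E
    breaks = sorted({min(max(x, 0.0), 1.0) for x in (-d, 1.0 - d)})
    value, _ = integrate.quad(
        integrand, 0.0, 1.0, epsabs=_QUAD_ABS_TOL, limit=200, points=breaks
    )
    return min(max(value, 0.0), 1.0)


def improvement_probability(
    post_e: BetaParams, post_s: BetaParams, delta: float
) -> float:
    """Pr(theta_E > theta_S + delta | data) = 1 - CDF of the difference at delta."""
    return 1.0 - difference_cdf(post_e, post_s, delta)


def difference_interval(
    post_e: BetaParams, post_s: BetaParams, level: float = 0.95
) -> Interval:
    """Equal-tailed credible interval for theta_E - theta_S.

    Each endpoint is the root of difference_cdf(.) = tail mass on [-1, 1],
    located by Brent's method.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0

    def endpoint(q: float) -> float:
        return optimize.brentq(
            lambda x: difference_cdf(post_e, post_s, x) - q,
            -1.0,
            1.0,
            xtol=_ROOT_TOL,
            maxiter=200,
        )

    return Interval(level, endpoint(tail), endpoint(1.0 - tail))


def difference_mean(post_e: BetaParams, post_s: BetaParams) -> float:
    """E(theta_E - theta_S) by linearity of expectation."""
    return post_e.mean() - post_s.mean()


def summarize_difference(
    post_e: BetaParams,
    post_s: BetaParams,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    level: float = 0.95,
) -> DifferenceSummary:
    return DifferenceSummary(
        mean=difference_mean(post_e, post_s),
        interval=difference_interval(post_e, post_s, level),
        improvement={
            float(d): improvement_probability(post_e, post_s, d) for d in deltas
        },
    )


def compare_arms(
    arms: Sequence[ArmPosterior],
    reference: str,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    level: float = 0.95,
) -> list[tuple[str, DifferenceSummary]]:
    """Each non-reference arm versus the reference, in input order.

    Returns pairs of a contrast label ``"E - S"`` and its DifferenceSummary.
    """
    labels = [a.label for a in arms]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"arm labels must be unique, got {labels}")
    if reference not in labels:
        raise ConfigError(f"reference arm {reference!r} not among {labels}")
    if len(arms) < 2:
        raise ConfigError("need at least two arms to compare")
    ref = next(a for a in arms if a.label == reference)
    out = []
    for arm in arms:
        if arm.label == reference:
            continue
        out.append(
            (
                f"{arm.label} - {reference}",
                summarize_difference(arm.params, ref.params, deltas, level),
            )
        )
    return out


def comparison_table(
    comparisons: Sequence[tuple[str, DifferenceSummary]]
) -> pd.DataFrame:
    """Flatten compare_arms output into a tidy frame (one row per contrast)."""
    rows = []
    for label, summ in comparisons:
        row: dict[str, object] = {
            "contrast": label,
            "mean": summ.mean,
            "cri_lower": summ.interval.lower,
            "cri_upper": summ.interval.upper,
            "level": summ.interval.level,
        }
        for d, p in summ.improvement.items():
            row[f"pr_improve_{d:g}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def _stratum_draws(
    arm: Union[BetaParams, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(arm, BetaParams):
        return rng.beta(arm.alpha, arm.beta_, size=n)
    return np.full(n, float(arm))


def post_stratified_difference(
    strata: Sequence[StratumWeight],
    level: float = 0.95,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, Interval]:
    """Weighted average of within-stratum treatment differences.

    The point estimate is the exact weighted mean difference; the interval is
    the equal-tailed quantile range of seeded Monte-Carlo draws of the
    weighted difference (known probabilities contribute as constants).
    """
    weights = np.array([s.weight for s in strata], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigError(f"stratum weights must sum to 1, got {weights.sum()!r}")

    def arm_mean(arm: Union[BetaParams, float]) -> float:
        return arm.mean() if isinstance(arm, BetaParams) else float(arm)

    mean = float(
        sum(s.weight * (arm_mean(s.arm_e) - arm_mean(s.arm_s)) for s in strata)
    )
    rng = np.random.default_rng(seed)
    draws = np.zeros(n_draws)
    for s in strata:
        draws += s.weight * (
            _stratum_draws(s.arm_e, n_draws, rng) - _stratum_draws(s.arm_s, n_draws, rng)
        )
    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(draws, [tail, 1.0 - tail])
    return mean, Interval(level, float(lower), float(upper))
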