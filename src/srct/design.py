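"""Heuristic sample-size exploration for small randomized trials.

Rather than powering a hypothesis test, a small randomized comparative trial
picks (N, K, n) with N = K * n by examining how precisely the treatment
effect theta_E - theta_S could be estimated at each candidate per-arm size
n: hypothetical future data at fixed response fractions are scaled to each
n, and the resulting posterior credible intervals and improvement
probabilities Pr(theta_E > theta_S + delta | data) are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .compare import difference_interval, improvement_probability
from .conjugate import BetaParams, BinomialCount, ConfigError, update_beta

__all__ = ["DesignCandidate", "HypotheticalProfile", "explore_designs"]

FractionLike = Union[Fraction, tuple[int, int], str]


def _as_fraction(f: FractionLike) -> Fraction:
    if isinstance(f, tuple):
        return Fraction(f[0], f[1])
    return Fraction(f)


@dataclass(frozen=True)
class DesignCandidate:
    """A (N, K, n) triple with N = K * n."""

    k_arms: int
    n_per_arm: int

    def __post_init__(self) -> None:
        if self.k_arms < 2:
            raise ConfigError("need at least two arms")
        if self.n_per_arm <= 0:
            raise ConfigError("per-arm sample size must be positive")

    @property
    def n_total(self) -> int:
        return self.k_arms * self.n_per_arm


@dataclass(frozen=True)
class HypotheticalProfile:
    """Hypothetical future response fractions per arm, reference named.

    Fractions are scaled to each candidate's per-arm n; a fraction that does
    not scale to an integer event count at some n is a configuration error
    (rows must be exactly reproducible, never rounded).
    """

    fractions: Mapping[str, FractionLike]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.fractions:
            raise ConfigError(
                f"reference {self.reference!r} missing from {list(self.fractions)}"
            )
        if len(self.fractions) < 2:
            raise ConfigError("profile needs at least two arms")

    def scaled_to(self, n: int) -> dict[str, BinomialCount]:
        out = {}
        for arm, f in self.fractions.items():
            events = _as_fraction(f) * n
            if events.denominator != 1:
                raise ConfigError(
                    f"fraction {f} for arm {arm!r} does not scale to integer "
                    f"events at n={n}"
                )
            out[arm] = BinomialCount(int(events), n)
        return out


def explore_designs(
    candidates: Sequence[DesignCandidate],
    profile: HypotheticalProfile,
    deltas: Sequence[float] = (0.15,),
    level: float = 0.95,
    priors: Optional[Mapping[str, BetaParams]] = None,
) -> pd.DataFrame:
    """One row per candidate and non-reference arm: CrI + improvement probs.

    ``priors`` maps arm labels to beta priors; arms left unspecified get the
    non-informative beta(0.5, 0.5).
    """
    priors = dict(priors or {})
    rows = []
    for cand in candidates:
        counts = profile.scaled_to(cand.n_per_arm)
        ref_count = counts[profile.reference]
        ref_post = update_beta(
            priors.get(profile.reference, BetaParams(0.5, 0.5)), ref_count
        )
        for arm, count in counts.items():
            if arm == profile.reference:
                continue
            post = update_beta(priors.get(arm, BetaParams(0.5, 0.5)), count)
            ci = difference_interval(post, ref_post, level)
            row: dict[str, object] = {
                "n_per_arm": cand.n_per_arm,
                "n_total": cand.n_total,
                "data": f"{count} with {arm} vs. {ref_count} with {profile.reference}",
                "cri_lower": ci.lower,
                "cri_upper": ci.upper,
            }
            for d in deltas:
                row[f"pr_improve_{d:g}"] = improvement_probability(post, ref_post, d)
            rows.append(row)
    return pd.DataFrame(rows)
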