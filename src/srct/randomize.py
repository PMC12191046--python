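"""Balanced permuted-block randomization.

Assignments are generated in fixed-size blocks, each an independent uniform
random permutation of the balanced multiset (every arm appearing
block_size / K times), so per-arm sample sizes are exactly equal at every
block boundary.  Choosing the block size so boundaries coincide with the
monitoring schedule keeps interim per-arm sample sizes equal each time a
stopping rule is applied.  Stratified variants run an independent plan per
stratum; enrichment replanning re-blocks the unfilled tail of a plan over
the surviving arms after an arm is dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .conjugate import ConfigError

__all__ = [
    "BlockSpec",
    "RandomizationPlan",
    "StratifiedPlan",
    "permuted_blocks",
    "balance_report",
    "stratified_plan",
    "enrichment_replan",
]

SeedLike = Union[int, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class BlockSpec:
    arms: tuple[str, ...]
    block_size: int
    n_blocks: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        if len(self.arms) < 1 or len(set(self.arms)) != len(self.arms):
            raise ConfigError(f"arms must be distinct labels, got {self.arms}")
        if self.block_size <= 0 or self.block_size % len(self.arms) != 0:
            raise ConfigError(
                f"block size {self.block_size} must be a positive multiple of "
                f"{len(self.arms)} arms"
            )
        if self.n_blocks <= 0:
            raise ConfigError(f"n_blocks must be positive, got {self.n_blocks}")

    @property
    def total(self) -> int:
        return self.block_size * self.n_blocks


@dataclass(frozen=True)
class RandomizationPlan:
    """A full pre-generated assignment sequence with its block structure."""

    arms: tuple[str, ...]
    block_size: int
    assignments: tuple[str, ...]
    block_boundaries: tuple[int, ...]  # cumulative end positions of each block
    seed: object

    def __len__(self) -> int:
        return len(self.assignments)

    def counts_at(self, position: int) -> dict[str, int]:
        """Per-arm assignment counts among the first ``position`` patients."""
        head = self.assignments[:position]
        return {arm: head.count(arm) for arm in self.arms}

    def block_index(self, position: int) -> int:
        """0-based block containing enrollment position ``position``."""
        for i, end in enumerate(self.block_boundaries):
            if position < end:
                return i
        raise IndexError(position)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": range(1, len(self.assignments) + 1),
                "block": [self.block_index(i) + 1 for i in range(len(self.assignments))],
                "arm": self.assignments,
            }
        )


def _random_block(
    arms: Sequence[str], block_size: int, rng: np.random.Generator
) -> list[str]:
    per_arm = block_size // len(arms)
    multiset = np.repeat(np.arange(len(arms)), per_arm)
    return [arms[i] for i in rng.permutation(multiset)]


def permuted_blocks(spec: BlockSpec, seed: SeedLike) -> RandomizationPlan:
    """Generate ``n_blocks`` independent uniformly permuted balanced blocks."""
    rng = _rng(seed)
    assignments: list[str] = []
    boundaries: list[int] = []
    for _ in range(spec.n_blocks):
        assignments.extend(_random_block(spec.arms, spec.block_size, rng))
        boundaries.append(len(assignments))
    return RandomizationPlan(
        arms=spec.arms,
        block_size=spec.block_size,
        assignments=tuple(assignments),
        block_boundaries=tuple(boundaries),
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def balance_report(
    plan: RandomizationPlan, checkpoints: Sequence[int]
) -> pd.DataFrame:
    """Per-arm counts at each checkpoint, with a flag for exact balance."""
    rows = []
    for cp in checkpoints:
        if cp > len(plan):
            raise ConfigError(f"checkpoint {cp} exceeds plan length {len(plan)}")
        counts = plan.counts_at(cp)
        rows.append(
            {
                "checkpoint": cp,
                **counts,
                "balanced": len(set(counts.values())) == 1,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StratifiedPlan:
    plans: Mapping[str, RandomizationPlan]

    def __getitem__(self, stratum: str) -> RandomizationPlan:
        return self.plans[stratum]


def stratified_plan(
    strata: Sequence[tuple[str, BlockSpec]], seed: int
) -> StratifiedPlan:
    """Independent permuted-block plan per stratum with distinct derived seeds."""
    if not strata:
        raise ConfigError("need at least one stratum")
    children = np.random.SeedSequence(seed).spawn(len(strata))
    return StratifiedPlan(
        plans={
            label: permuted_blocks(spec, np.random.default_rng(child))
            for (label, spec), child in zip(strata, children)
        }
    )


def enrichment_replan(
    plan: RandomizationPlan,
    dropped: str,
    from_position: int,
    seed: SeedLike,
) -> RandomizationPlan:
    """Re-block positions >= from_position over the surviving arms.

    The dropped arm's remaining slots are randomized among survivors: the
    tail is regenerated as permuted blocks whose size keeps the original
    per-arm quota (block_size / K patients per arm per block), truncating
    the final partial block so the total planned N is preserved.  Earlier
    assignments are untouched.
    """
    if dropped not in plan.arms:
        raise ConfigError(f"{dropped!r} is not an arm of this plan")
    survivors = tuple(a for a in plan.arms if a != dropped)
    if not survivors:
        raise ConfigError("cannot drop the last remaining arm")
    if not 0 <= from_position <= len(plan):
        raise ConfigError(f"from_position {from_position} outside plan")
    tail_len = len(plan) - from_position
    if tail_len == 0:
        return plan

    per_arm = plan.block_size // len(plan.arms)
    new_block = per_arm * len(survivors)
    rng = _rng(seed)
    tail: list[str] = []
    while len(tail) < tail_len:
        tail.extend(_random_block(survivors, new_block, rng))
    tail = tail[:tail_len]

    boundaries = [b for b in plan.block_boundaries if b <= from_position]
    if not boundaries or boundaries[-1] < from_position:
        boundaries.append(from_position)
    pos = from_position
    while pos < len(plan):
        pos = min(pos + new_block, len(plan))
        boundaries.append(pos)

    return RandomizationPlan(
        arms=survivors,
        block_size=new_block,
        assignments=plan.assignments[:from_position] + tuple(tail),
        block_boundaries=tuple(boundaries),
        seed=None,
    )
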