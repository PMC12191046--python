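"""Operating characteristics of monitored trial designs.

Single-arm behavior is computed exactly: because a stopping rule reduces to
integer trigger boundaries, the stop-time distribution under a true event
probability follows from a dynamic program over (look, cumulative event
count) with binomial cohort increments — no simulation error.  Full
multi-arm trials (block randomization, enrichment after an arm is dropped,
final selection of the experimental arm with the largest posterior mean
response rate) are simulated with seeded, reproducible Monte Carlo because
arm interactions break independence.  The module also calibrates decision
cutoffs against target stopping probabilities and generates patient-level
synthetic trial datasets.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conjugate import BetaParams, BinomialCount, ConfigError, prior_from_mean
from .monitor import (
    BoundaryTable,
    CutoffSpec,
    FutilityRule,
    SafetyRule,
    boundary_table,
    cutoff_at,
)
from .randomize import BlockSpec, RandomizationPlan, enrichment_replan, permuted_blocks

__all__ = [
    "ArmScenario",
    "TrialDesign",
    "SingleArmOC",
    "TrialOC",
    "CalibrationResult",
    "exact_arm_oc",
    "sample_size_quartiles",
    "simulate_arm_stops",
    "simulate_trial",
    "calibrate_cutoff",
    "generate_trial_dataset",
    "oc_table",
]

NONE_SELECTED = "none"


@dataclass(frozen=True)
class ArmScenario:
    """True event probabilities assumed for one arm in an evaluation scenario."""

    label: str
    true_p_tox: float = 0.0
    true_p_res: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.true_p_tox, self.true_p_res):
            if not 0 <= p <= 1:
                raise ConfigError(f"scenario probabilities must be in [0, 1], got {p}")


@dataclass(frozen=True)
class TrialDesign:
    """A monitored, block-randomized multi-arm design.

    ``arms`` lists labels with the reference (standard-of-care) arm first.
    ``safety_rules`` / ``futility_rules`` map experimental arm labels to
    their rules.  With ``enrichment`` on, a dropped arm's remaining slots
    are re-randomized among surviving arms so the planned total N = K * n
    is preserved whenever at least one experimental arm survives.
    ``selection_delta`` > 0 additionally requires the best survivor's
    posterior mean response rate to beat the reference's by that margin.
    """

    arms: tuple[str, ...]
    n_per_arm: int
    block_size: int
    safety_rules: Mapping[str, SafetyRule] = field(default_factory=dict)
    futility_rules: Mapping[str, FutilityRule] = field(default_factory=dict)
    enrichment: bool = True
    selection_delta: float = 0.0
    selection_prior: BetaParams = field(
        default_factory=lambda: BetaParams(0.5, 0.5)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        if len(self.arms) < 2 or len(set(self.arms)) != len(self.arms):
            raise ConfigError(f"need >= 2 distinct arms, got {self.arms}")
        if self.n_per_arm <= 0:
            raise ConfigError("n_per_arm must be positive")
        if self.block_size % len(self.arms) != 0:
            raise ConfigError(
                f"block size {self.block_size} not divisible by {len(self.arms)} arms"
            )
        for label in list(self.safety_rules) + list(self.futility_rules):
            if label not in self.arms:
                raise ConfigError(f"rule for unknown arm {label!r}")

    @property
    def reference(self) -> str:
        return self.arms[0]

    @property
    def n_total(self) -> int:
        return self.n_per_arm * len(self.arms)


@dataclass(frozen=True)
class SingleArmOC:
    """Stop-time law of one monitored arm under a true event probability.

    ``stop_distribution`` maps the per-arm enrolled count at termination to
    its probability; the mass at ``n_max`` includes arms never stopped.
    """

    p_stop: float
    stop_distribution: Mapping[int, float]
    quartiles: tuple[int, int, int]
    true_p: float


@dataclass(frozen=True)
class TrialOC:
    """Monte-Carlo operating characteristics of a full multi-arm trial."""

    stop_probability: Mapping[str, float]
    selection_probability: Mapping[str, float]  # arms plus "none"
    total_n_distribution: Mapping[int, float]
    n_sims: int


def sample_size_quartiles(
    stop_distribution: Mapping[int, float]
) -> tuple[int, int, int]:
    """(q25, q50, q75): smallest reachable sample size with cumulative mass >= q."""
    sizes = sorted(stop_distribution)
    out = []
    for q in (0.25, 0.50, 0.75):
        cum = 0.0
        for s in sizes:
            cum += stop_distribution[s]
            if cum >= q - 1e-12:
                out.append(s)
                break
        else:
            out.append(sizes[-1])
    return tuple(out)  # type: ignore[return-value]


def _check_alignment(
    boundary: BoundaryTable, cohort_sizes: Sequence[int], n_max: int
) -> list[int]:
    cum = np.cumsum(cohort_sizes)
    if cum[-1] != n_max:
        raise ConfigError(
            f"cohort sizes {list(cohort_sizes)} must sum to n_max {n_max}"
        )
    cumset = set(int(c) for c in cum)
    for look in boundary.looks:
        if look not in cumset:
            raise ConfigError(
                f"look {look} not aligned with cumulative cohorts {sorted(cumset)}"
            )
    return [int(c) for c in cum]


def exact_arm_oc(
    boundary: BoundaryTable,
    cohort_sizes: Sequence[int],
    true_p: float,
    n_max: int,
) -> SingleArmOC:
    """Exact stop-time distribution by dynamic programming.

    State: probability vector over the cumulative event count among paths
    still accruing.  Each cohort convolves a binomial(m, true_p) increment;
    at each scheduled look the triggered mass is removed and credited to
    stopping at that sample size.  Exact to floating precision.
    """
    cum = _check_alignment(boundary, cohort_sizes, n_max)
    dist = np.array([1.0])  # index = cumulative events among continuing paths
    stop_dist: dict[int, float] = {}
    total = 0
    for m, at_n in zip(cohort_sizes, cum):
        inc = stats.binom.pmf(np.arange(m + 1), m, true_p)
        dist = np.convolve(dist, inc)
        total = at_n
        if at_n in boundary.looks:
            stopped = np.array(
                [boundary.stops(at_n, x) for x in range(len(dist))], dtype=bool
            )
            stop_dist[at_n] = float(dist[stopped].sum())
            dist = np.where(stopped, 0.0, dist)
    p_stop = float(sum(stop_dist.values()))
    full = {n: stop_dist.get(n, 0.0) for n in sorted(set(boundary.looks))}
    full[n_max] = full.get(n_max, 0.0) + float(dist.sum())
    return SingleArmOC(
        p_stop=p_stop,
        stop_distribution=full,
        quartiles=sample_size_quartiles(full),
        true_p=true_p,
    )


def simulate_arm_stops(
    boundary: BoundaryTable,
    cohort_sizes: Sequence[int],
    true_p: float,
    n_sims: int,
    seed: int,
) -> SingleArmOC:
    """Vectorized Monte-Carlo counterpart of exact_arm_oc (simulation check)."""
    cum = _check_alignment(boundary, cohort_sizes, n_max=int(np.sum(cohort_sizes)))
    n_max = cum[-1]
    rng = np.random.default_rng(seed)
    outcomes = rng.random((n_sims, n_max)) < true_p
    counts = np.cumsum(outcomes, axis=1)
    size = np.full(n_sims, n_max)
    active = np.ones(n_sims, dtype=bool)
    for look in boundary.looks:
        trig = boundary.trigger_at(look)
        if trig is None:
            continue
        x = counts[:, look - 1]
        hit = active & (x >= trig if boundary.kind == "safety" else x <= trig)
        size[hit] = look
        active &= ~hit
    sizes, freq = np.unique(size, return_counts=True)
    dist = {int(s): 0.0 for s in list(boundary.looks) + [n_max]}
    dist.update({int(s): c / n_sims for s, c in zip(sizes, freq)})
    return SingleArmOC(
        p_stop=float(np.mean(~active)),
        stop_distribution=dist,
        quartiles=sample_size_quartiles(dist),
        true_p=true_p,
    )


def oc_table(ocs: Sequence[SingleArmOC]) -> pd.DataFrame:
    """Tidy frame mirroring a per-scenario OC report (one row per true p)."""
    return pd.DataFrame(
        {
            "true_p": [oc.true_p for oc in ocs],
            "p_stop": [oc.p_stop for oc in ocs],
            "q25": [oc.quartiles[0] for oc in ocs],
            "q50": [oc.quartiles[1] for oc in ocs],
            "q75": [oc.quartiles[2] for oc in ocs],
        }
    )


# ---------------------------------------------------------------------------
# Full-trial simulation


def _arm_boundaries(design: TrialDesign) -> dict[str, list[BoundaryTable]]:
    tables: dict[str, list[BoundaryTable]] = {a: [] for a in design.arms}
    for label, rule in design.safety_rules.items():
        tables[label].append(boundary_table(rule))
    for label, rule in design.futility_rules.items():
        tables[label].append(boundary_table(rule))
    return tables


def _run_trial(
    design: TrialDesign,
    scen: Mapping[str, ArmScenario],
    tables: Mapping[str, Sequence[BoundaryTable]],
    rng: np.random.Generator,
    record: Optional[list] = None,
):
    """One trial realization; returns (stopped set, per-arm counts, total n)."""
    n_total = design.n_total
    n_blocks = math.ceil(n_total / design.block_size)
    plan = permuted_blocks(
        BlockSpec(design.arms, design.block_size, n_blocks), rng
    )
    enrolled = {a: 0 for a in design.arms}
    tox = {a: 0 for a in design.arms}
    res = {a: 0 for a in design.arms}
    stopped: set[str] = set()
    experimental = [a for a in design.arms if a != design.reference]
    pos = 0
    while pos < n_total:
        arm = plan.assignments[pos]
        block = plan.block_index(pos)
        pos += 1
        enrolled[arm] += 1
        s = scen[arm]
        y_tox = rng.random() < s.true_p_tox
        y_res = rng.random() < s.true_p_res
        tox[arm] += y_tox
        res[arm] += y_res
        if record is not None:
            record.append(
                {
                    "id": sum(enrolled.values()),
                    "block": block + 1,
                    "arm": arm,
                    "tox": int(y_tox),
                    "res": int(y_res),
                }
            )
        # evaluate this arm's rules when its evaluated count reaches a look
        stop_here = False
        for table in tables.get(arm, ()):  # tox rules then res rules
            count = tox[arm] if table.kind == "safety" else res[arm]
            if enrolled[arm] in table.looks and table.stops(enrolled[arm], count):
                stop_here = True
        if stop_here:
            stopped.add(arm)
            survivors_exp = [a for a in experimental if a not in stopped]
            if not survivors_exp:
                break  # all experimental arms dropped: terminate the trial
            if design.enrichment and pos < n_total:
                plan = enrichment_replan(plan, arm, pos, rng)
    total_n = sum(enrolled.values())
    return stopped, enrolled, tox, res, total_n


def _select(
    design: TrialDesign,
    stopped: set[str],
    enrolled: Mapping[str, int],
    res: Mapping[str, int],
) -> str:
    """Final selection: largest posterior mean response rate among surviving
    experimental arms; ties break toward the earliest-listed (lowest-dose)
    arm.  With selection_delta > 0 the winner must also beat the reference
    posterior mean by that margin."""
    survivors = [
        a for a in design.arms if a != design.reference and a not in stopped
    ]
    if not survivors:
        return NONE_SELECTED

    def post_mean(arm: str) -> float:
        prior = design.selection_prior
        return (prior.alpha + res[arm]) / (prior.ess() + enrolled[arm])

    best = max(survivors, key=lambda a: (post_mean(a), -design.arms.index(a)))
    if design.selection_delta > 0:
        if post_mean(best) < post_mean(design.reference) + design.selection_delta:
            return NONE_SELECTED
    return best


def simulate_trial(
    design: TrialDesign,
    scenario: Sequence[ArmScenario],
    n_sims: int,
    seed: int,
) -> TrialOC:
    """Seeded Monte Carlo of the full design under a true scenario.

    Per-simulation RNG streams are derived from (seed, sim index), so results
    are reproducible and independent of n_sims batching.
    """
    if n_sims < 1:
        raise ConfigError("n_sims must be >= 1")
    scen = {s.label: s for s in scenario}
    if set(scen) != set(design.arms):
        raise ConfigError(
            f"scenario arms {sorted(scen)} do not match design arms {design.arms}"
        )
    tables = _arm_boundaries(design)
    stop_counts = {a: 0 for a in design.arms}
    select_counts = {a: 0 for a in design.arms}
    select_counts[NONE_SELECTED] = 0
    n_dist: dict[int, int] = {}
    for i in range(n_sims):
        rng = np.random.default_rng([seed, i])
        stopped, enrolled, _tox, res, total_n = _run_trial(
            design, scen, tables, rng
        )
        for a in stopped:
            stop_counts[a] += 1
        select_counts[_select(design, stopped, enrolled, res)] += 1
        n_dist[total_n] = n_dist.get(total_n, 0) + 1
    return TrialOC(
        stop_probability={a: c / n_sims for a, c in stop_counts.items()},
        selection_probability={a: c / n_sims for a, c in select_counts.items()},
        total_n_distribution={n: c / n_sims for n, c in sorted(n_dist.items())},
        n_sims=n_sims,
    )


def generate_trial_dataset(
    design: TrialDesign,
    scenario: Sequence[ArmScenario],
    seed: int,
) -> pd.DataFrame:
    """Patient-level synthetic dataset from one simulated trial realization.

    One row per enrolled patient (id, block, arm, tox, res), truncated at any
    triggered stop; byte-identical for a fixed seed.
    """
    scen = {s.label: s for s in scenario}
    if set(scen) != set(design.arms):
        raise ConfigError(
            f"scenario arms {sorted(scen)} do not match design arms {design.arms}"
        )
    tables = _arm_boundaries(design)
    record: list[dict] = []
    _run_trial(design, scen, tables, np.random.default_rng([seed, 0]), record)
    return pd.DataFrame(record, columns=["id", "block", "arm", "tox", "res"])


# ---------------------------------------------------------------------------
# Cutoff calibration


@dataclass(frozen=True)
class CalibrationResult:
    cutoff: CutoffSpec
    oc_at_limit: SingleArmOC
    oc_at_unacceptable: SingleArmOC
    feasible: bool  # p_stop(theta*) met the cap
    meets_power: bool  # p_stop(theta**) reached the requested floor


def calibrate_cutoff(
    rule_template: SafetyRule,
    cohort_sizes: Sequence[int],
    p_stop_max_at_limit: float,
    p_stop_min_at_unacceptable: float,
    grid: Sequence[CutoffSpec],
) -> CalibrationResult:
    """Pick the grid cutoff with the best operating characteristics.

    Among cutoffs with exact p_stop(theta*) <= cap, maximizes p_stop(theta**),
    breaking ties toward the larger cutoff (fewer stops at an acceptable
    rate).  If no cutoff meets the cap, the feasibility-closest one is
    returned flagged infeasible.
    """
    if not grid:
        raise ConfigError("cutoff grid must be non-empty")
    n_max = rule_template.schedule.n_max
    evaluated = []
    for spec in grid:
        rule = dataclasses.replace(rule_template, cutoff=spec)
        table = boundary_table(rule)
        oc_lim = exact_arm_oc(table, cohort_sizes, rule.limit, n_max)
        oc_bad = exact_arm_oc(table, cohort_sizes, rule.unacceptable, n_max)
        evaluated.append((spec, oc_lim, oc_bad))

    def final_cutoff(spec: CutoffSpec) -> float:
        return cutoff_at(spec, rule_template.schedule.looks[-1], n_max)

    feasible = [e for e in evaluated if e[1].p_stop <= p_stop_max_at_limit]
    if feasible:
        spec, oc_lim, oc_bad = max(
            feasible, key=lambda e: (e[2].p_stop, final_cutoff(e[0]))
        )
        return CalibrationResult(
            spec, oc_lim, oc_bad, True, oc_bad.p_stop >= p_stop_min_at_unacceptable
        )
    spec, oc_lim, oc_bad = min(evaluated, key=lambda e: e[1].p_stop)
    return CalibrationResult(spec, oc_lim, oc_bad, False, False)
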