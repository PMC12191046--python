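"""Worked examples: a self-contained reproduction of the toolkit's reference
computations, bundled so `srct examples` can regenerate them as one report.

The inputs are printed counts and published design settings of a three-arm
randomized cell-therapy trial for steroid-refractory GvHD (two cell doses
added to a Jak-kinase inhibitor versus the inhibitor alone, n = 16 per arm)
together with standard textbook worked numbers; everything is recomputed
from those inputs at call time.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .compare import ArmPosterior, compare_arms, comparison_table
from .conjugate import (
    BetaParams,
    BinomialCount,
    credible_interval,
    prior_from_mean,
    update_beta,
)
from .design import DesignCandidate, HypotheticalProfile, explore_designs
from .monitor import (
    CutoffSpec,
    MonitoringSchedule,
    SafetyRule,
    boundary_table,
    default_rule_prior,
)
from .ocs import exact_arm_oc, oc_table

__all__ = [
    "cell_trial_safety_rule",
    "comparator_safety_rule",
    "write_examples",
]


def cell_trial_safety_rule() -> SafetyRule:
    """The cell-therapy trial's within-arm safety rule.

    Fixed toxicity limit theta* = 0.30 (theta** = 0.50 unacceptable),
    operational prior with mean theta* and ESS 1, constant cutoff 0.90,
    looks at 4, 8, 12 of 16 patients per arm.  Its derived boundary is
    stop if >= 3/4, 5/8, 6/12.
    """
    return SafetyRule(
        prior=default_rule_prior(0.30),
        limit=0.30,
        unacceptable=0.50,
        cutoff=CutoffSpec.constant(0.90),
        schedule=MonitoringSchedule((4, 8, 12), 16),
    )


def comparator_safety_rule() -> SafetyRule:
    """Two-look random-comparator safety rule for n = 24 per arm.

    Non-informative beta(0.20, 0.80) prior on the experimental toxicity
    rate, highly informative beta(200, 800) comparator centred at
    theta* = 0.20 (theta** = 0.40), cutoff 0.90, looks at 8 and 16.  Its
    derived boundary is stop if >= 4/8, 6/16.
    """
    return SafetyRule(
        prior=prior_from_mean(0.20, 1.0),
        limit=0.20,
        unacceptable=0.40,
        cutoff=CutoffSpec.constant(0.90),
        schedule=MonitoringSchedule((8, 16), 24),
        comparator=BetaParams(200, 800),
    )


def _posterior_rows() -> pd.DataFrame:
    cases = [
        ("beta(0.5, 0.5) + 8/20", prior_from_mean(0.5, 1.0), "8/20"),
        ("beta(80, 20) + 0/20", BetaParams(80, 20), "0/20"),
        ("beta(0.8, 0.2) + 0/20", prior_from_mean(0.8, 1.0), "0/20"),
    ]
    rows = []
    for label, prior, count in cases:
        post = update_beta(prior, BinomialCount.from_string(count))
        ci = credible_interval(post, 0.95)
        rows.append(
            {
                "case": label,
                "alpha": post.alpha,
                "beta": post.beta_,
                "mean": post.mean(),
                "cri_lower": ci.lower,
                "cri_upper": ci.upper,
            }
        )
    return pd.DataFrame(rows)


def _difference_rows() -> pd.DataFrame:
    cases = [
        ("7/15 vs 3/15", "7/15", "3/15"),
        ("10/15 vs 3/15", "10/15", "3/15"),
        ("8/20 vs 4/20", "8/20", "4/20"),
        ("12/20 vs 4/20", "12/20", "4/20"),
        ("12/24 vs 6/24", "12/24", "6/24"),
        ("8/16 vs 4/16", "8/16", "4/16"),
    ]
    uniform = prior_from_mean(0.5, 1.0)
    arms = []
    for label, e_count, s_count in cases:
        post_e = update_beta(uniform, BinomialCount.from_string(e_count))
        post_s = update_beta(uniform, BinomialCount.from_string(s_count))
        arms.append(
            (label, compare_arms(
                [ArmPosterior("E", post_e), ArmPosterior("S", post_s)],
                "S",
                deltas=(0.0, 0.15, 0.20),
            ))
        )
    frames = []
    for label, comp in arms:
        frame = comparison_table(comp)
        frame.insert(0, "data", label)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _design_rows() -> pd.DataFrame:
    rows = []
    for n, frac_e, frac_s in [(10, "3/5", "3/10"), (15, "2/3", "1/3"), (20, "7/10", "7/20")]:
        profile = HypotheticalProfile({"E": frac_e, "S": frac_s}, "S")
        rows.append(
            explore_designs([DesignCandidate(3, n)], profile, deltas=(0.15,))
        )
    return pd.concat(rows, ignore_index=True)


def _interim_rows() -> pd.DataFrame:
    uniform = prior_from_mean(0.5, 1.0)

    def posts(counts: dict[str, str]) -> list[ArmPosterior]:
        return [
            ArmPosterior(k, update_beta(uniform, BinomialCount.from_string(v)))
            for k, v in counts.items()
        ]

    day28 = comparison_table(
        compare_arms(posts({"S": "5/9", "E1": "9/10", "E2": "10/11"}), "S", (0.15,))
    )
    day28.insert(0, "outcome", "day28_response")
    day180 = comparison_table(
        compare_arms(posts({"S": "2/6", "E1": "5/8", "E2": "7/9"}), "S", (0.15,))
    )
    day180.insert(0, "outcome", "day180_success")
    return pd.concat([day28, day180], ignore_index=True)


def write_examples(out_dir: Path) -> str:
    """Recompute every worked example, write CSVs, and return a text report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    posteriors = _posterior_rows()
    differences = _difference_rows()
    designs = _design_rows()
    interim = _interim_rows()

    cell_rule = cell_trial_safety_rule()
    comp_rule = comparator_safety_rule()
    cell_bounds = boundary_table(cell_rule)
    comp_bounds = boundary_table(comp_rule)
    cell_oc = oc_table(
        [exact_arm_oc(cell_bounds, (4, 4, 4, 4), p, 16) for p in (0.3, 0.4, 0.5, 0.6)]
    )
    comp_oc = oc_table(
        [exact_arm_oc(comp_bounds, (8, 8, 8), p, 24) for p in (0.2, 0.4)]
    )

    posteriors.to_csv(out_dir / "posterior_examples.csv", index=False)
    differences.to_csv(out_dir / "difference_examples.csv", index=False)
    designs.to_csv(out_dir / "design_exploration.csv", index=False)
    interim.to_csv(out_dir / "interim_comparisons.csv", index=False)
    cell_bounds.to_frame().to_csv(out_dir / "cell_trial_boundary.csv", index=False)
    comp_bounds.to_frame().to_csv(out_dir / "comparator_boundary.csv", index=False)
    cell_oc.to_csv(out_dir / "cell_trial_oc.csv", index=False)
    comp_oc.to_csv(out_dir / "comparator_oc.csv", index=False)

    fmt = lambda f: f.round(2).to_string(index=False)  # noqa: E731
    report = "\n\n".join(
        [
            "== Beta-binomial posterior summaries ==\n" + fmt(posteriors),
            "== Difference-of-betas comparisons (beta(0.5, 0.5) priors) ==\n"
            + fmt(differences),
            "== Per-arm sample-size exploration ==\n" + fmt(designs),
            "== Interim arm comparisons ==\n" + fmt(interim),
            "== Cell-trial safety boundary ==\n" + cell_bounds.to_text(),
            "== Comparator safety boundary ==\n" + comp_bounds.to_text(),
            "== Cell-trial rule exact operating characteristics ==\n"
            + cell_oc.round(3).to_string(index=False),
            "== Comparator rule exact operating characteristics ==\n"
            + comp_oc.round(3).to_string(index=False),
        ]
    )
    (out_dir / "report.txt").write_text(report + "\n")
    return report
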