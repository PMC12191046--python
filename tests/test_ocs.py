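"""Operating characteristics: exact stop-time DP, trial simulation, calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from srct import (
    ArmScenario,
    BetaParams,
    ConfigError,
    CutoffSpec,
    MonitoringSchedule,
    SafetyRule,
    TrialDesign,
    boundary_table,
    calibrate_cutoff,
    default_rule_prior,
    exact_arm_oc,
    generate_trial_dataset,
    sample_size_quartiles,
    simulate_arm_stops,
    simulate_trial,
)
from srct.ocs import _arm_boundaries, _run_trial


@pytest.fixture(scope="module")
def cell_boundary(cell_rule):
    return boundary_table(cell_rule)


@pytest.fixture(scope="module")
def comparator_boundary(comparator_rule):
    return boundary_table(comparator_rule)


def brute_force_stop_distribution(boundary, looks, true_p, n_max):
    """Enumerate every binary outcome sequence of length n_max exactly."""
    dist = {n: 0.0 for n in list(looks) + [n_max]}
    for seq in itertools.product((0, 1), repeat=n_max):
        prob = true_p ** sum(seq) * (1 - true_p) ** (n_max - sum(seq))
        size = n_max
        for look in looks:
            if boundary.stops(look, sum(seq[:look])):
                size = look
                break
        dist[size] += prob
    return dist


def test_exact_dp_matches_exhaustive_enumeration(cell_rule):
    """All 2^12 outcome sequences agree with the dynamic program exactly."""
    rule = SafetyRule(
        prior=cell_rule.prior,
        limit=0.30,
        unacceptable=0.50,
        cutoff=CutoffSpec.constant(0.90),
        schedule=MonitoringSchedule((4, 8), 12),
    )
    boundary = boundary_table(rule)
    for p in (0.25, 0.5):
        oc = exact_arm_oc(boundary, (4, 4, 4), p, 12)
        brute = brute_force_stop_distribution(boundary, (4, 8), p, 12)
        for size, prob in brute.items():
            assert oc.stop_distribution[size] == pytest.approx(prob, abs=1e-12)


def test_exact_stopping_probability_of_comparator_rule(comparator_boundary):
    oc_low = exact_arm_oc(comparator_boundary, (8, 8, 8), 0.20, 24)
    oc_high = exact_arm_oc(comparator_boundary, (8, 8, 8), 0.40, 24)
    assert oc_low.p_stop == pytest.approx(0.1063, abs=5e-4)
    assert oc_high.p_stop == pytest.approx(0.698, abs=5e-4)


def test_no_events_means_no_stops(cell_boundary):
    oc = exact_arm_oc(cell_boundary, (4, 4, 4, 4), 0.0, 16)
    assert oc.p_stop == 0.0
    assert oc.quartiles == (16, 16, 16)


def test_stop_distribution_sums_to_one(cell_boundary):
    oc = exact_arm_oc(cell_boundary, (4, 4, 4, 4), 0.45, 16)
    assert sum(oc.stop_distribution.values()) == pytest.approx(1.0, abs=1e-12)


def test_misaligned_schedule_rejected(cell_boundary):
    with pytest.raises(ConfigError):
        exact_arm_oc(cell_boundary, (5, 5, 6), 0.3, 16)
    with pytest.raises(ConfigError):
        exact_arm_oc(cell_boundary, (4, 4, 4), 0.3, 16)  # cohorts must reach n_max


def test_quartile_definition(cell_boundary):
    oc = exact_arm_oc(cell_boundary, (4, 4, 4, 4), 0.30, 16)
    assert oc.quartiles == (16, 16, 16)
    oc = exact_arm_oc(cell_boundary, (4, 4, 4, 4), 0.50, 16)
    assert oc.quartiles == (4, 12, 16)
    assert sample_size_quartiles({16: 1.0}) == (16, 16, 16)


def test_p_stop_monotone_in_true_toxicity(cell_boundary):
    grid = np.linspace(0.05, 0.8, 12)
    p_stops = [
        exact_arm_oc(cell_boundary, (4, 4, 4, 4), p, 16).p_stop for p in grid
    ]
    assert all(a <= b + 1e-12 for a, b in zip(p_stops, p_stops[1:]))


def test_vectorized_simulation_agrees_with_exact(cell_boundary):
    for p in (0.3, 0.5):
        exact = exact_arm_oc(cell_boundary, (4, 4, 4, 4), p, 16)
        sim = simulate_arm_stops(cell_boundary, (4, 4, 4, 4), p, 100_000, seed=17)
        se = np.sqrt(exact.p_stop * (1 - exact.p_stop) / 100_000)
        assert abs(sim.p_stop - exact.p_stop) < 3 * se


def make_design(cell_rule, arms=("S", "E1", "E2"), rules=("E1", "E2")):
    return TrialDesign(
        arms=arms,
        n_per_arm=16,
        block_size=2 * len(arms),
        safety_rules={a: cell_rule for a in rules},
    )


def scenario_for(design, p_tox, p_res=0.4):
    return [ArmScenario(a, p_tox, p_res) for a in design.arms]


def test_simulated_two_arm_trial_matches_exact_single_arm(cell_rule, cell_boundary):
    """With one monitored arm the trial simulator reduces to the exact DP."""
    design = make_design(cell_rule, arms=("S", "E1"), rules=("E1",))
    n_sims = 3000
    oc = simulate_trial(design, scenario_for(design, 0.5), n_sims, seed=21)
    exact = exact_arm_oc(cell_boundary, (4, 4, 4, 4), 0.5, 16)
    se = np.sqrt(exact.p_stop * (1 - exact.p_stop) / n_sims)
    assert abs(oc.stop_probability["E1"] - exact.p_stop) < 3 * se
    assert oc.stop_probability["S"] == 0.0


def test_simulated_cell_trial_per_arm_stop_probability(cell_rule):
    design = make_design(cell_rule)
    n_sims = 2000
    oc = simulate_trial(design, scenario_for(design, 0.5), n_sims, seed=8)
    se = np.sqrt(0.658 * (1 - 0.658) / n_sims)
    for arm in ("E1", "E2"):
        assert abs(oc.stop_probability[arm] - 0.658) < 3 * se
    assert sum(oc.selection_probability.values()) == pytest.approx(1.0)


def test_no_rules_means_full_enrollment(cell_rule):
    design = TrialDesign(arms=("S", "E1", "E2"), n_per_arm=16, block_size=6)
    oc = simulate_trial(design, scenario_for(design, 0.9), 50, seed=4)
    assert oc.total_n_distribution == {48: 1.0}
    assert all(p == 0.0 for p in oc.stop_probability.values())


def test_enrichment_preserves_total_sample_size(cell_rule):
    """Total enrolled <= N always, and == N whenever any experimental arm survives."""
    design = make_design(cell_rule)
    scen = {s.label: s for s in scenario_for(design, 0.55)}
    tables = _arm_boundaries(design)
    for i in range(150):
        rng = np.random.default_rng([99, i])
        stopped, enrolled, _, _, total = _run_trial(design, scen, tables, rng)
        assert total <= design.n_total
        survivors = {"E1", "E2"} - stopped
        if survivors:
            assert total == design.n_total
        else:
            assert total < design.n_total


def test_selection_prefers_higher_true_response(cell_rule):
    design = make_design(cell_rule)
    scen = [
        ArmScenario("S", 0.0, 0.3),
        ArmScenario("E1", 0.0, 0.2),
        ArmScenario("E2", 0.0, 0.8),
    ]
    oc = simulate_trial(design, scen, 300, seed=12)
    assert oc.selection_probability["E2"] > oc.selection_probability["E1"]
    assert oc.selection_probability["none"] == 0.0  # no toxicity, no stops


def test_scenario_mismatch_rejected(cell_rule):
    design = make_design(cell_rule)
    with pytest.raises(ConfigError):
        simulate_trial(design, scenario_for(design, 0.3)[:2], 10, seed=0)


def test_simulation_reproducible(cell_rule):
    design = make_design(cell_rule)
    a = simulate_trial(design, scenario_for(design, 0.5), 200, seed=5)
    b = simulate_trial(design, scenario_for(design, 0.5), 200, seed=5)
    assert a == b


def test_calibration_selects_ninety_percent_cutoff(comparator_rule):
    """The 0.90 cutoff meets Pstop(0.20) <= 0.11 and maximizes Pstop(0.40)."""
    grid = [CutoffSpec.constant(c) for c in (0.80, 0.85, 0.90, 0.95)]
    result = calibrate_cutoff(comparator_rule, (8, 8, 8), 0.11, 0.60, grid)
    assert result.feasible and result.meets_power
    assert result.cutoff.c == 0.90
    assert result.oc_at_limit.p_stop == pytest.approx(0.1063, abs=5e-4)
    assert result.oc_at_unacceptable.p_stop == pytest.approx(0.698, abs=5e-4)


def test_calibration_single_member_grid(comparator_rule):
    result = calibrate_cutoff(
        comparator_rule, (8, 8, 8), 0.5, 0.5, [CutoffSpec.constant(0.85)]
    )
    assert result.cutoff.c == 0.85


def test_calibration_infeasible_constraint_is_flagged(comparator_rule):
    result = calibrate_cutoff(
        comparator_rule, (8, 8, 8), 0.0, 0.5, [CutoffSpec.constant(0.9)]
    )
    assert not result.feasible
    with pytest.raises(ConfigError):
        calibrate_cutoff(comparator_rule, (8, 8, 8), 0.1, 0.5, [])


def test_dataset_generator_deterministic_and_balanced(cell_rule):
    design = make_design(cell_rule)
    scen = scenario_for(design, 0.0, p_res=0.4)  # no toxicity: no stops
    df1 = generate_trial_dataset(design, scen, seed=13)
    df2 = generate_trial_dataset(design, scen, seed=13)
    pd.testing.assert_frame_equal(df1, df2)
    assert len(df1) == design.n_total
    # balanced per-arm counts at every block boundary
    for end in range(design.block_size, design.n_total + 1, design.block_size):
        counts = df1.iloc[:end]["arm"].value_counts()
        assert counts.nunique() == 1


def test_dataset_event_rates_match_scenario(cell_rule):
    design = TrialDesign(arms=("S", "E"), n_per_arm=20_000, block_size=4)
    scen = [ArmScenario("S", 0.2, 0.3), ArmScenario("E", 0.1, 0.6)]
    df = generate_trial_dataset(design, scen, seed=2)
    for arm, p_tox, p_res in [("S", 0.2, 0.3), ("E", 0.1, 0.6)]:
        sub = df[df["arm"] == arm]
        n = len(sub)
        for col, p in (("tox", p_tox), ("res", p_res)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(sub[col].mean() - p) < 3 * se
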