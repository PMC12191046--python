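import pytest

from srct import BetaParams, prior_from_mean
from srct.examples import cell_trial_safety_rule, comparator_safety_rule


@pytest.fixture(scope="session")
def cell_rule():
    """Fixed-limit safety rule: theta* = 0.30, cutoff 0.90, looks 4/8/12 of 16."""
    return cell_trial_safety_rule()


@pytest.fixture(scope="session")
def comparator_rule():
    """Random-comparator safety rule: beta(200, 800) comparator, looks 8/16 of 24."""
    return comparator_safety_rule()


@pytest.fixture(scope="session")
def jeffreys():
    """The operational beta(0.5, 0.5) prior used throughout the comparisons."""
    return prior_from_mean(0.5, 1.0)
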