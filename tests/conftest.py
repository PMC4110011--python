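import numpy as np
import pytest

from multisense.stats import RewardRange, SufficientStats, update_stats


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def stats_from(rewards, reward_range=RewardRange()) -> SufficientStats:
    """Build sufficient statistics by folding in rewards one at a time."""
    s = SufficientStats()
    for r in rewards:
        s = update_stats(s, r, reward_range)
    return s


@pytest.fixture
def make_stats():
    return stats_from
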