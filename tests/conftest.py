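import numpy as np
import pandas as pd
import pytest

from cardioscore.lme import StackedDesign
from cardioscore.score_time import BeatTimeMap, ScoreTimeGrid
from cardioscore.synthetic import SyntheticConfig, generate_fixtures


@pytest.fixture(scope="session")
def grid848() -> ScoreTimeGrid:
    return ScoreTimeGrid(848)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Shrunk study: 60 bars (240 half-beats), 4 performances."""
    return SyntheticConfig(seed=123, n_bars=60, n_performances=4)


@pytest.fixture(scope="session")
def small_fixtures(small_config):
    return generate_fixtures(small_config)


@pytest.fixture
def uniform_beats() -> BeatTimeMap:
    """848 half-beats at exactly 0.25 s spacing (120 BPM quarter pulse)."""
    return BeatTimeMap(1, 0.5 + 0.25 * np.arange(848))


def make_regression_design(
    rng: np.random.Generator,
    n_per_group: int = 40,
    n_groups: int = 6,
    beta: dict[str, float] | None = None,
    group_sd: float = 0.1,
    noise_sd: float = 0.5,
) -> StackedDesign:
    """Small random-intercept regression problem with known coefficients."""
    beta = beta if beta is not None else {"x1": 1.0, "x2": 0.8, "noise": 0.0}
    n = n_per_group * n_groups
    groups = np.repeat(np.arange(1, n_groups + 1), n_per_group)
    cols = {name: rng.normal(size=n) for name in beta}
    y = 0.5 + sum(b * cols[t] for t, b in beta.items())
    y = y + np.repeat(rng.normal(0.0, group_sd, n_groups), n_per_group)
    y = y + rng.normal(0.0, noise_sd, n)
    frame = pd.DataFrame({"performance": groups, "rr_norm": y, **cols})
    return StackedDesign(frame, tuple(beta))
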