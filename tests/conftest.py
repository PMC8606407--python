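import numpy as np
import pytest

from microexplore import SimParams, generate_cohort, make_track
from microexplore.baseline import ImitativeAnchor


@pytest.fixture(scope="session")
def small_params():
    """A small but otherwise default-conditioned cohort for fast tests."""
    return SimParams(n_participants=12, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params)


@pytest.fixture
def anchor():
    return ImitativeAnchor(x_anchor=458.29, y_anchor=347.79,
                           n_frames=100, n_contributors=10)


@pytest.fixture
def random_track():
    rng = np.random.default_rng(123)
    n = 900  # 30 s at 30 fps
    parts = {}
    for name in ("handle_base", "handle_mid", "handle_tip"):
        xy = rng.uniform(0, 600, size=(n, 2))
        lik = rng.uniform(0.5, 1.0, size=n)
        parts[name] = np.column_stack([xy, lik])
    return make_track(parts, fps=30, participant_id="p000", trial_number=1)
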