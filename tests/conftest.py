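import numpy as np
import pytest

from formuqbd.mixture_design import MixtureConstraints


@pytest.fixture
def constraints():
    return MixtureConstraints()


@pytest.fixture
def unconstrained_simplex():
    """Full simplex scaled to the 59% variable total."""
    return MixtureConstraints(
        lower=(0.0, 0.0, 0.0),
        upper=(59.0, 59.0, 59.0),
        fixed={"drug": 40.0, "lubricant": 1.0},
        total=59.0,
    )


@pytest.fixture
def release_time_grid():
    """Typical 24-h dissolution sampling grid (hours)."""
    return np.array([0.5, 1, 2, 4, 6, 8, 10, 12, 16, 20, 24], dtype=float)
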