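import numpy as np
import pytest

from difficulty_ddm.core import CollapsingBound, ColorDDMParams
from difficulty_ddm.models import DifficultyParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ref_params():
    """Difficulty-model parameters used across tests (fast, realistic RTs)."""
    from difficulty_ddm.models import REFERENCE_PARAMS

    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def color_params():
    return ColorDDMParams(
        kappa=12.0, c0=0.0, bound=CollapsingBound(u=1.6, a=1.5, d=1.0), tnd_mean=0.32
    )


@pytest.fixture(scope="session")
def flat_params():
    """Flat bound at B = 1 (u = 2, a = 0) with unit drift coefficient."""
    return ColorDDMParams(
        kappa=1.0, c0=0.0, bound=CollapsingBound(u=2.0, a=0.0, d=1.0), tnd_mean=0.35
    )


@pytest.fixture(scope="session")
def difference_dataset(ref_params):
    """One simulated session of the 12 x 12 reaction-time difficulty design."""
    from difficulty_ddm.data import design_exp1_difficulty, generate_dataset

    design = design_exp1_difficulty(seed=7)
    return generate_dataset("difference", ref_params, design, seed=77, dt=0.01)
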