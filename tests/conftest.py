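import numpy as np
import pytest

from nhejkin import REYNOLDS_LIKE_PARAMS, DoseSchedule
from nhejkin.synthetic import generate_bundle, reynolds_like_preset, simulate_true_curves


@pytest.fixture(scope="session")
def preset_params():
    return REYNOLDS_LIKE_PARAMS


@pytest.fixture(scope="session")
def acute():
    return DoseSchedule.acute(0.5)


@pytest.fixture(scope="session")
def sf3_noiseless_bundle():
    """Noiseless SF3 bundle from the reynolds-like preset (ground truth known)."""
    return generate_bundle(reynolds_like_preset(variant="SF3", sigma=0.0, seed=7))


@pytest.fixture(scope="session")
def sf1_noisy_bundle():
    """SF1 preset bundle with the default 0.05 noise."""
    return generate_bundle(reynolds_like_preset(variant="SF1", sigma=0.05, seed=3))


@pytest.fixture(scope="session")
def sf3_noisy_bundle():
    return generate_bundle(reynolds_like_preset(variant="SF3", sigma=0.05, seed=5))


@pytest.fixture(scope="session")
def sf1_true_curves():
    """Noiseless control/inhibited trajectories of the SF1 preset."""
    return simulate_true_curves(reynolds_like_preset(variant="SF1", sigma=0.0, seed=0))


def perturbed_start(params, free, seed, factors=(0.5, 1.5)):
    """Deterministic per-parameter multiplicative perturbation of a start point."""
    rng = np.random.default_rng(seed)
    return params.updated(**{nm: params.value(nm) * rng.choice(factors) for nm in free})
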