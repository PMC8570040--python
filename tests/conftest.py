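import numpy as np
import pytest

from erdnet import EEGTrialSet, ModelConfig, SimConfig, build_model
from erdnet.simulate import generate_session_pair


@pytest.fixture
def tiny_trialset() -> EEGTrialSet:
    rng = np.random.default_rng(0)
    return EEGTrialSet(
        signals=rng.standard_normal((10, 4, 32)).astype(np.float32),
        labels=rng.integers(0, 2, 10),
        sampling_rate=250.0,
        channel_names=["C3", "Cz", "C4", "Fz"],
        class_names=["left_hand", "right_hand"],
    )


@pytest.fixture
def tiny_model_cfg() -> ModelConfig:
    # small enough for fast forward/backward, divisible pooling: 32/4=8, 8/2=4
    return ModelConfig(T=32, E=4, M=2, F1=2, F2=3, K1=5, K2=3, D=2, P1=4, P2=2)


@pytest.fixture
def tiny_model(tiny_model_cfg):
    return build_model(tiny_model_cfg, seed=0)


@pytest.fixture(scope="session")
def small_session_pair():
    """A quickly separable synthetic subject for end-to-end smoke training."""
    cfg = SimConfig(
        n_classes=2,
        trials_per_class=30,
        n_channels=4,
        n_samples=200,
        erd_strength=0.8,
        seed=3,
    )
    return generate_session_pair(cfg, test_trials_per_class=15)
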