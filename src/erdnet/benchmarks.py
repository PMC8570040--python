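"""The synthetic benchmark conditions used for end-to-end validation.

One simulated subject: 2 classes, 8 channels, 2 s trials at 250 Hz
(T = 500 samples), 100 training and 50 test trials per class, ERD depth
rho = 0.8.  The matching architecture keeps the standard filter counts and
kernels but uses pooling (P1, P2) = (10, 5), which divides T = 500 exactly
(feature dim 160).  Training: Adam 1e-3, batch 32, 60 epochs.

The label-noise variant flips 10% of training labels and trains for 200
epochs — long enough for an unregularized model to fully memorize the
mislabeled trials, the precondition for any overfitting contrast between
plain and smoothed cross-entropy.
"""

from __future__ import annotations

from dataclasses import replace

from .simulate import SimConfig, generate_session_pair
from .net import ModelConfig
from .train import TrainConfig
from .losses import LossWeights

__all__ = [
    "benchmark_sim_config",
    "benchmark_model_config",
    "benchmark_train_config",
    "benchmark_session",
]

TRAIN_TRIALS_PER_CLASS = 100
TEST_TRIALS_PER_CLASS = 50
EPOCHS = 60
NOISE_EPOCHS = 200
BATCH_SIZE = 32


def benchmark_sim_config(
    seed: int = 7, erd_strength: float = 0.8, label_noise_frac: float = 0.0
) -> SimConfig:
    return SimConfig(
        n_classes=2,
        trials_per_class=TRAIN_TRIALS_PER_CLASS,
        n_channels=8,
        n_samples=500,
        sampling_rate=250.0,
        erd_strength=erd_strength,
        label_noise_frac=label_noise_frac,
        seed=seed,
    )


def benchmark_model_config() -> ModelConfig:
    return ModelConfig(T=500, E=8, M=2, P1=10, P2=5)


def benchmark_train_config(
    seed: int = 7,
    alpha_lsr: float = 0.5,
    alpha_ct: float = 0.5,
    epochs: int = EPOCHS,
) -> TrainConfig:
    return TrainConfig(
        epochs=epochs,
        batch_size=BATCH_SIZE,
        seed=seed,
        weights=LossWeights(alpha_lsr, alpha_ct),
    )


def benchmark_session(
    seed: int = 7, erd_strength: float = 0.8, label_noise_frac: float = 0.0
):
    """Train/test sessions of one simulated subject under the benchmark regime."""
    cfg = benchmark_sim_config(seed, erd_strength, label_noise_frac)
    return generate_session_pair(cfg, test_trials_per_class=TEST_TRIALS_PER_CLASS)
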