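"""Synthetic motor-imagery EEG sessions with controllable class separability.

The discriminative physiology of motor imagery is event-related
desynchronization (ERD): imagery of a specific movement attenuates the
band-limited mu (~10 Hz) and beta (~20 Hz) rhythms over a class-specific
subset of sensorimotor electrodes.  The generator models exactly that —
class identity enters only through multiplicative attenuation of the rhythm
amplitude on "affected" channels, on top of 1/f pink background noise and
white sensor noise.  The attenuation depth ``erd_strength`` (rho) is the
single separability dial: rho = 0 yields class-independent trials (chance
level for any classifier); rho near 1 makes band power a strong cue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import periodogram
from scipy.integrate import trapezoid

from .trialdata import EEGTrialSet

__all__ = [
    "SimConfig",
    "make_spatial_patterns",
    "synthesize_trial",
    "generate_dataset",
    "generate_session_pair",
    "band_power",
]


@dataclass
class SimConfig:
    """Parameters of a simulated motor-imagery session.

    Amplitudes are in microvolts.  Defaults mirror a cue-based recording at
    250 Hz with a ~10 uV sensorimotor rhythm over a 5 uV pink / 2 uV white
    noise floor.
    """

    n_classes: int = 2
    trials_per_class: int = 72
    n_channels: int = 8
    n_samples: int = 1000
    sampling_rate: float = 250.0
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    rhythm_amp: float = 10.0
    erd_strength: float = 0.8  # rho: multiplicative attenuation depth in [0, 1]
    pink_noise_amp: float = 5.0
    white_noise_amp: float = 2.0
    label_noise_frac: float = 0.0
    seed: int = 0
    # the subject's class-specific channel topography; sessions of the same
    # simulated subject (e.g. train/test splits) must share this seed
    pattern_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.trials_per_class < 1 or self.n_channels < 1 or self.n_samples < 1:
            raise ValueError("trials_per_class, n_channels and n_samples must be >= 1")
        if not 0.0 <= self.erd_strength <= 1.0:
            raise ValueError(f"erd_strength must lie in [0, 1], got {self.erd_strength}")
        if not 0.0 <= self.label_noise_frac <= 1.0:
            raise ValueError(f"label_noise_frac must lie in [0, 1], got {self.label_noise_frac}")
        for name in ("rhythm_amp", "pink_noise_amp", "white_noise_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        nyquist = self.sampling_rate / 2.0
        if self.mu_freq >= nyquist or self.beta_freq >= nyquist:
            raise ValueError("rhythm frequencies must be below Nyquist")


def make_spatial_patterns(M: int, E: int, seed: int) -> np.ndarray:
    """Draw an M x E matrix of per-class channel involvement in [0, 1].

    Each row marks the channel subset whose rhythm the class attenuates:
    affected channels get weights in [0.6, 1], the rest in [0, 0.2].  Rows
    are pairwise distinct; affected subsets are made distinct across classes
    whenever ``M <= 2**E`` allows it.
    """
    if M < 2 or E < 1:
        raise ValueError("need M >= 2 classes and E >= 1 channels")
    if M > 2**E:
        raise ValueError(f"cannot draw {M} distinct channel subsets from {E} channels")
    rng = np.random.default_rng(seed)
    masks: list[tuple] = []
    for _ in range(M):
        for _attempt in range(1000):
            mask = rng.random(E) < 0.4
            if not mask.any():
                mask[rng.integers(E)] = True
            if tuple(mask) not in masks:
                break
        masks.append(tuple(mask))
    patterns = np.empty((M, E))
    for j, mask in enumerate(masks):
        mask = np.array(mask)
        patterns[j, mask] = rng.uniform(0.6, 1.0, size=int(mask.sum()))
        patterns[j, ~mask] = rng.uniform(0.0, 0.2, size=int((~mask).sum()))
    # continuous draws make ties essentially impossible, but guarantee it
    for j in range(M):
        for k in range(j):
            if np.array_equal(patterns[j], patterns[k]):
                raise ValueError("failed to draw distinct spatial patterns")
    return patterns


def _pink_noise(n_samples: int, n_series: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via inverse-FFT spectral shaping (power ∝ 1/f)."""
    n_freq = n_samples // 2 + 1
    spectrum = rng.standard_normal((n_series, n_freq)) + 1j * rng.standard_normal(
        (n_series, n_freq)
    )
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros(n_freq)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ∝ f^{-1/2} so power ∝ 1/f
    x = np.fft.irfft(spectrum * scale, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def synthesize_trial(
    class_id: int,
    patterns: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one E x T trial for ``class_id``.

    Channel e carries
    ``(1 - rho * pattern[class, e]) * A * (sin(2π f_mu t + φ_e) + 0.5 sin(2π f_beta t + ψ_e))``
    plus pink and white noise; phases are drawn fresh per trial and channel.
    """
    M, E = patterns.shape
    if not 0 <= class_id < M:
        raise ValueError(f"class_id {class_id} outside [0, {M})")
    T = cfg.n_samples
    t = np.arange(T) / cfg.sampling_rate
    phi = rng.uniform(0, 2 * np.pi, size=(E, 1))
    psi = rng.uniform(0, 2 * np.pi, size=(E, 1))
    rhythm = np.sin(2 * np.pi * cfg.mu_freq * t + phi) + 0.5 * np.sin(
        2 * np.pi * cfg.beta_freq * t + psi
    )
    gain = (1.0 - cfg.erd_strength * patterns[class_id])[:, None] * cfg.rhythm_amp
    trial = gain * rhythm
    trial = trial + cfg.pink_noise_amp * _pink_noise(T, E, rng)
    trial = trial + cfg.white_noise_amp * rng.standard_normal((E, T))
    return trial


def generate_dataset(cfg: SimConfig) -> EEGTrialSet:
    """Simulate a full session: balanced classes, randomized trial order.

    Fully determined by ``cfg.seed``.  If ``label_noise_frac > 0``, exactly
    ``round(frac * n)`` trials (chosen without replacement) have their label
    reassigned uniformly to a *different* class after generation, so the
    signal content still reflects the original class — mislabeled data.
    """
    rng = np.random.default_rng(cfg.seed)
    M, E = cfg.n_classes, cfg.n_channels
    pattern_seed = cfg.pattern_seed if cfg.pattern_seed is not None else cfg.seed
    patterns = make_spatial_patterns(M, E, seed=pattern_seed)
    labels = np.repeat(np.arange(M), cfg.trials_per_class)
    labels = labels[rng.permutation(labels.size)]
    signals = np.stack(
        [synthesize_trial(int(y), patterns, cfg, rng) for y in labels]
    )
    if cfg.label_noise_frac > 0:
        n_flip = int(round(cfg.label_noise_frac * labels.size))
        flip_idx = rng.choice(labels.size, size=n_flip, replace=False)
        offsets = rng.integers(1, M, size=n_flip)
        labels = labels.copy()
        labels[flip_idx] = (labels[flip_idx] + offsets) % M
    return EEGTrialSet(
        signals=signals,
        labels=labels,
        sampling_rate=cfg.sampling_rate,
        channel_names=[f"ch{i}" for i in range(E)],
        class_names=[f"class{j}" for j in range(M)],
    )


def generate_session_pair(
    cfg: SimConfig, test_trials_per_class: int | None = None
) -> tuple[EEGTrialSet, EEGTrialSet]:
    """Train/test sessions of the same simulated subject.

    Both sessions share the subject's spatial patterns (``pattern_seed``
    defaults to ``cfg.seed``) but draw independent noise and phases; the
    test session never receives label noise.
    """
    if test_trials_per_class is None:
        test_trials_per_class = max(1, cfg.trials_per_class // 2)
    pattern_seed = cfg.pattern_seed if cfg.pattern_seed is not None else cfg.seed
    train = generate_dataset(replace(cfg, pattern_seed=pattern_seed))
    test_cfg = replace(
        cfg,
        trials_per_class=test_trials_per_class,
        label_noise_frac=0.0,
        seed=cfg.seed + 100_003,
        pattern_seed=pattern_seed,
    )
    return train, generate_dataset(test_cfg)


def band_power(
    trial_channel: np.ndarray,
    band: tuple[float, float],
    sampling_rate: float,
) -> float:
    """Periodogram power integrated over ``[low, high]`` Hz."""
    low, high = band
    if not (0 <= low < high <= sampling_rate / 2.0):
        raise ValueError(
            f"band {band} must satisfy 0 <= low < high <= Nyquist ({sampling_rate / 2.0} Hz)"
        )
    freqs, psd = periodogram(np.asarray(trial_channel, dtype=float), fs=sampling_rate)
    sel = (freqs >= low) & (freqs <= high)
    if sel.sum() < 2:
        return float(psd[sel].sum())
    return float(trapezoid(psd[sel], freqs[sel]))
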