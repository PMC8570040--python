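"""The combined training objective: smoothed cross-entropy + center loss.

Two regularizers supplement the standard cross-entropy L_cl:

* label-smoothing regularization L_lsr — the cross-entropy between the
  uniform distribution u(y|x) = 1/M and the prediction, weighted by
  alpha_lsr.  Equivalently, train against smoothed targets
  p' = (1 - eps) * onehot + eps * u with eps = alpha_lsr / (1 + alpha_lsr);
  the two parameterizations differ only by the constant factor (1 - eps).
* center loss L_ct — half the squared distance between each penultimate
  ("deep") feature and a running per-class center, weighted by alpha_ct.
  Centers are model state, not trainable parameters: gradients flow into
  the features only, and centers move through :func:`update_centers`.

Total objective: L = L_cl + alpha_lsr * L_lsr + alpha_ct * L_ct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PROB_FLOOR",
    "SmoothingConfig",
    "LossWeights",
    "CenterBank",
    "epsilon_from_alpha",
    "smooth_labels",
    "one_hot",
    "cross_entropy",
    "lsr_term",
    "smoothed_cross_entropy",
    "center_loss",
    "update_centers",
    "combined_loss",
]

# floor applied inside logarithms so a zero predicted probability stays finite
PROB_FLOOR = 1e-12


def epsilon_from_alpha(alpha_lsr: float) -> float:
    """Smoothing mass eps solving eps / (1 - eps) = alpha_lsr."""
    if alpha_lsr < 0:
        raise ValueError(f"alpha_lsr must be non-negative, got {alpha_lsr}")
    return alpha_lsr / (1.0 + alpha_lsr)


@dataclass(frozen=True)
class SmoothingConfig:
    """Label-smoothing weight alpha_lsr and the derived smoothing mass eps."""

    alpha_lsr: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha_lsr < 0:
            raise ValueError(f"alpha_lsr must be non-negative, got {self.alpha_lsr}")

    @property
    def epsilon(self) -> float:
        return epsilon_from_alpha(self.alpha_lsr)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the two regularizers in the combined objective."""

    alpha_lsr: float = 0.5
    alpha_ct: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha_lsr < 0 or self.alpha_ct < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class CenterBank:
    """Per-class deep-feature centers c_j and their update step size."""

    centers: np.ndarray  # (M, d)
    center_step: float = 0.5

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2:
            raise ValueError("centers must be an (M, d) matrix")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers contain non-finite values")
        if not 0.0 <= self.center_step <= 1.0:
            raise ValueError(f"center_step must lie in [0, 1], got {self.center_step}")

    @classmethod
    def zeros(cls, n_classes: int, feature_dim: int, center_step: float = 0.5) -> "CenterBank":
        return cls(np.zeros((n_classes, feature_dim)), center_step)


def one_hot(labels: np.ndarray, M: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= M):
        raise ValueError(f"labels must lie in [0, {M})")
    out = np.zeros((labels.shape[0], M))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def smooth_labels(labels: np.ndarray, M: int, epsilon: float) -> np.ndarray:
    """Smoothed targets p' = (1 - eps) * onehot + eps / M, rows on the simplex."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    return (1.0 - epsilon) * one_hot(labels, M) + epsilon / M


def _reduce(per_trial: np.ndarray, reduction: str) -> float:
    if reduction == "mean":
        return float(per_trial.mean())
    if reduction == "sum":
        return float(per_trial.sum())
    raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")


def cross_entropy(target: np.ndarray, predicted: np.ndarray, reduction: str = "mean") -> float:
    """H(p, q) = -sum_y p log q per trial, reduced over trials."""
    target = np.asarray(target, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if target.shape != predicted.shape:
        raise ValueError(f"shape mismatch: target {target.shape} vs predicted {predicted.shape}")
    logq = np.log(np.clip(predicted, PROB_FLOOR, None))
    return _reduce(-(target * logq).sum(axis=1), reduction)


def lsr_term(predicted: np.ndarray, M: int | None = None, reduction: str = "mean") -> float:
    """Sum over trials of H(u, q) with u uniform: -(1/M) sum_y log q_y."""
    predicted = np.asarray(predicted, dtype=float)
    if M is None:
        M = predicted.shape[1]
    if M != predicted.shape[1]:
        raise ValueError(f"M={M} does not match prediction width {predicted.shape[1]}")
    logq = np.log(np.clip(predicted, PROB_FLOOR, None))
    return _reduce(-logq.mean(axis=1), reduction)


def smoothed_cross_entropy(
    labels: np.ndarray,
    predicted: np.ndarray,
    cfg: SmoothingConfig | float = SmoothingConfig(),
    reduction: str = "mean",
) -> float:
    """Cross-entropy against smoothed targets, CE(p', q).

    Identical (up to the constant factor 1 - eps) to
    ``cross_entropy(onehot, q) + alpha_lsr * lsr_term(q)``; both forms are
    exposed and tested for mutual consistency.
    """
    if not isinstance(cfg, SmoothingConfig):
        cfg = SmoothingConfig(float(cfg))
    M = np.asarray(predicted).shape[1]
    targets = smooth_labels(labels, M, cfg.epsilon)
    return cross_entropy(targets, predicted, reduction=reduction)


def center_loss(
    features: np.ndarray,
    labels: np.ndarray,
    bank: CenterBank,
    reduction: str = "mean",
) -> float:
    """L_ct = (1/2) sum_i ||x_i - c_{y_i}||^2 over the batch."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[1] != bank.centers.shape[1]:
        raise ValueError(
            f"feature width {features.shape} does not match centers {bank.centers.shape}"
        )
    if labels.size and (labels.min() < 0 or labels.max() >= bank.centers.shape[0]):
        raise ValueError(f"labels must lie in [0, {bank.centers.shape[0]})")
    diff = features - bank.centers[labels]
    return _reduce(0.5 * (diff**2).sum(axis=1), reduction)


def center_loss_grad(features: np.ndarray, labels: np.ndarray, bank: CenterBank) -> np.ndarray:
    """d L_ct / d features (per trial, before reduction): x_i - c_{y_i}."""
    return np.asarray(features, dtype=float) - bank.centers[np.asarray(labels)]


def update_centers(bank: CenterBank, features: np.ndarray, labels: np.ndarray) -> CenterBank:
    """One damped step of each present class center toward its batch mean.

    For class j with n_j batch members,
    ``delta_j = sum_{i: y_i=j} (c_j - x_i) / (1 + n_j)`` and
    ``c_j <- c_j - step * delta_j``; absent classes are untouched.  The
    1/(1 + n_j) damping keeps rarely-seen classes from jumping.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[1] != bank.centers.shape[1]:
        raise ValueError("feature width does not match centers")
    centers = bank.centers.copy()
    M = centers.shape[0]
    counts = np.bincount(labels, minlength=M).astype(float)
    sums = np.zeros_like(centers)
    np.add.at(sums, labels, features)
    present = counts > 0
    delta = (counts[:, None] * centers - sums) / (1.0 + counts[:, None])
    centers[present] -= bank.center_step * delta[present]
    return CenterBank(centers, bank.center_step)


def combined_loss(
    labels: np.ndarray,
    predicted: np.ndarray,
    features: np.ndarray,
    bank: CenterBank,
    weights: LossWeights = LossWeights(),
    reduction: str = "mean",
) -> float:
    """L = L_cl + alpha_lsr * L_lsr + alpha_ct * L_ct."""
    M = np.asarray(predicted).shape[1]
    value = cross_entropy(one_hot(labels, M), predicted, reduction=reduction)
    if weights.alpha_lsr:
        value += weights.alpha_lsr * lsr_term(predicted, M, reduction=reduction)
    if weights.alpha_ct:
        value += weights.alpha_ct * center_loss(features, labels, bank, reduction=reduction)
    return value
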