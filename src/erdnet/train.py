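"""Mini-batch training with the combined objective, plus the ablation harness.

The optimizer is Adam (adaptive moment estimation) with the conventional
moment decays 0.9/0.999 and eps 1e-8; only the learning rate is considered a
tunable.  Each step: forward pass in training mode, combined loss
L = L_cl + alpha_lsr * L_lsr + alpha_ct * L_ct, exact backward pass, Adam
update, then a damped center update (per batch by default, optionally once
per epoch).  Per-epoch records of every loss term and of train/test accuracy
are kept for learning-curve analysis.

All randomness (weight init, shuffling) derives from ``TrainConfig.seed``;
the whole pipeline is plain single-threaded NumPy, so two runs with the same
seed produce bitwise-identical histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trialdata import EEGTrialSet
from .net import ModelConfig, EEGNetClassifier, build_model
from .losses import (
    LossWeights,
    CenterBank,
    one_hot,
    cross_entropy,
    lsr_term,
    center_loss,
    center_loss_grad,
    update_centers,
)

__all__ = ["TrainConfig", "TrainHistory", "AdamOptimizer", "train_model", "run_ablation"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam at 1e-3, batches of 64, 750 epochs by default."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 750
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    center_update_mode: str = "per_batch"  # or "per_epoch"
    center_step: float = 0.5
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch statistics need 2+ samples)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.center_update_mode not in ("per_batch", "per_epoch"):
            raise ValueError(
                f"center_update_mode must be 'per_batch' or 'per_epoch', "
                f"got {self.center_update_mode!r}"
            )


@dataclass
class TrainHistory:
    """Per-epoch training records (the learning-curve data).

    Train-side values are running averages over the epoch's mini-batches in
    training mode; test-side values are computed in inference mode after the
    epoch.  ``train_loss``/``test_loss`` are the combined objective;
    ``*_ce``, ``*_lsr``, ``*_ct`` are its unweighted terms.
    """

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: str) -> np.ndarray:
        return np.asarray([r[key] for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrainHistory):
            return NotImplemented
        return self.to_frame().equals(other.to_frame())


class AdamOptimizer:
    """Adam with in-place parameter updates (preserves parameter aliasing)."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            np.subtract(self.params[k], update, out=self.params[k])


def _check_compatible(train_set: EEGTrialSet, test_set: EEGTrialSet, cfg: ModelConfig) -> None:
    for name, ts in (("train", train_set), ("test", test_set)):
        if ts.n_channels != cfg.E or ts.n_samples != cfg.T:
            raise ValueError(
                f"{name} set shape (E={ts.n_channels}, T={ts.n_samples}) does not match "
                f"model config (E={cfg.E}, T={cfg.T})"
            )
        if ts.n_classes != cfg.M:
            raise ValueError(f"{name} set has {ts.n_classes} classes, model expects {cfg.M}")
    if train_set.sampling_rate != test_set.sampling_rate:
        raise ValueError("train and test sampling rates differ")


def _evaluate(
    model: EEGNetClassifier,
    signals: np.ndarray,
    labels: np.ndarray,
    bank: CenterBank,
    weights: LossWeights,
    batch_size: int = 256,
) -> dict:
    """Inference-mode loss terms and accuracy over a full set."""
    n = signals.shape[0]
    M = bank.centers.shape[0]
    ce = lsr = ct = 0.0
    correct = 0
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        out = model.forward(signals[sl])
        y = labels[sl]
        w = y.size
        ce += cross_entropy(one_hot(y, M), out.probabilities) * w
        lsr += lsr_term(out.probabilities, M) * w
        ct += center_loss(out.features, y, bank) * w
        correct += int((np.argmax(out.logits, axis=1) == y).sum())
    ce, lsr, ct = ce / n, lsr / n, ct / n
    total = ce + weights.alpha_lsr * lsr + weights.alpha_ct * ct
    return {"loss": total, "ce": ce, "lsr": lsr, "ct": ct, "acc": correct / n}


def train_model(
    train_set: EEGTrialSet,
    test_set: EEGTrialSet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[EEGNetClassifier, CenterBank, TrainHistory]:
    """Train the CNN with the combined objective and log per-epoch metrics."""
    _check_compatible(train_set, test_set, model_cfg)
    w = train_cfg.weights
    model = build_model(model_cfg, seed=train_cfg.seed)
    bank = CenterBank.zeros(model_cfg.M, model_cfg.feature_dim, train_cfg.center_step)
    optimizer = AdamOptimizer(model.params, train_cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 1]))

    X = np.asarray(train_set.signals, dtype=model.dtype)
    y = train_set.labels
    X_test = np.asarray(test_set.signals, dtype=model.dtype)
    y_test = test_set.labels
    n = X.shape[0]
    M = model_cfg.M
    history = TrainHistory()

    for epoch in range(train_cfg.epochs):
        order = shuffle_rng.permutation(n) if train_cfg.shuffle else np.arange(n)
        sums = {"loss": 0.0, "ce": 0.0, "lsr": 0.0, "ct": 0.0}
        correct = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            if idx.size < 2:  # batch statistics need >= 2 samples
                continue
            xb, yb = X[idx], y[idx]
            out, cache = model.forward(xb, training=True, return_cache=True)
            q = out.probabilities

            ce = cross_entropy(one_hot(yb, M), q)
            lsr = lsr_term(q, M)
            ct = center_loss(out.features, yb, bank)
            total = ce + w.alpha_lsr * lsr + w.alpha_ct * ct
            sums["loss"] += total * idx.size
            sums["ce"] += ce * idx.size
            sums["lsr"] += lsr * idx.size
            sums["ct"] += ct * idx.size
            correct += int((np.argmax(out.logits, axis=1) == yb).sum())

            # dL/dz for mean-reduced CE terms: (1 + a_lsr) q - (onehot + a_lsr/M)
            dlogits = ((1 + w.alpha_lsr) * q - one_hot(yb, M) - w.alpha_lsr / M) / idx.size
            dfeat = (
                w.alpha_ct * center_loss_grad(out.features, yb, bank) / idx.size
                if w.alpha_ct
                else None
            )
            grads = model.backward(cache, dlogits, dfeat)
            optimizer.step(grads)
            if train_cfg.center_update_mode == "per_batch":
                bank = update_centers(bank, out.features, yb)
        if train_cfg.center_update_mode == "per_epoch":
            from .net import extract_features

            bank = update_centers(bank, extract_features(model, train_set), y)

        test_metrics = _evaluate(model, X_test, y_test, bank, w)
        history.append(
            epoch=epoch,
            train_loss=sums["loss"] / n,
            train_ce=sums["ce"] / n,
            train_lsr=sums["lsr"] / n,
            train_ct=sums["ct"] / n,
            train_acc=correct / n,
            test_loss=test_metrics["loss"],
            test_ce=test_metrics["ce"],
            test_lsr=test_metrics["lsr"],
            test_ct=test_metrics["ct"],
            test_acc=test_metrics["acc"],
        )
    return model, bank, history


def run_ablation(
    train_set: EEGTrialSet,
    test_set: EEGTrialSet,
    model_cfg: ModelConfig,
    base_cfg: TrainConfig,
    param: str,
    values,
    return_details: bool = False,
):
    """One full training per grid value of ``alpha_lsr`` or ``alpha_ct``.

    All other settings (including the seed) are held fixed.  Returns a
    DataFrame with columns ``[param, accuracy, test_ce, test_loss]``
    (accuracy in percent, final epoch); with ``return_details`` also a dict
    value -> (model, bank, history).
    """
    if param not in ("alpha_lsr", "alpha_ct"):
        raise ValueError(f"ablation parameter must be 'alpha_lsr' or 'alpha_ct', got {param!r}")
    rows = []
    details = {}
    for value in values:
        weights = replace(base_cfg.weights, **{param: float(value)})
        cfg = replace(base_cfg, weights=weights)
        model, bank, history = train_model(train_set, test_set, model_cfg, cfg)
        final = history.records[-1]
        rows.append(
            {
                param: float(value),
                "accuracy": 100.0 * final["test_acc"],
                "test_ce": final["test_ce"],
                "test_loss": final["test_loss"],
            }
        )
        details[float(value)] = (model, bank, history)
    table = pd.DataFrame(rows)
    if return_details:
        return table, details
    return table
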