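"""Model/Results front end: fit a motor-imagery classifier to a trial set.

``MotorImageryClassifier`` bundles a trial set with an architecture config;
``fit()`` runs the combined-objective training and returns a
``MotorImageryResults`` carrying the trained network, the class centers, the
per-epoch history, and reporting helpers (``summary``, ``predict``,
``accuracy``, dispersion and plots).  This is a convenience layer: the
underlying machinery lives in :mod:`erdnet.train` and :mod:`erdnet.evaluate`.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .trialdata import EEGTrialSet
from .net import ModelConfig, EEGNetClassifier, extract_features, predict_labels
from .losses import LossWeights, CenterBank
from .train import TrainConfig, TrainHistory, train_model
from . import evaluate as _ev

__all__ = ["MotorImageryClassifier", "MotorImageryResults"]


class MotorImageryClassifier:
    """A CNN motor-imagery decoder bound to a training trial set.

    Parameters
    ----------
    train_set : EEGTrialSet
        Labeled training trials.
    model_cfg : ModelConfig, optional
        Architecture; if omitted, T/E/M are taken from the data and the
        remaining hyperparameters use their defaults (pooling lengths must
        then divide T).
    """

    def __init__(self, train_set: EEGTrialSet, model_cfg: ModelConfig | None = None):
        self.train_set = train_set
        if model_cfg is None:
            model_cfg = ModelConfig(
                T=train_set.n_samples, E=train_set.n_channels, M=train_set.n_classes
            )
        self.model_cfg = model_cfg

    @classmethod
    def from_arrays(
        cls,
        signals: np.ndarray,
        labels: np.ndarray,
        sampling_rate: float,
        model_cfg: ModelConfig | None = None,
    ) -> "MotorImageryClassifier":
        return cls(EEGTrialSet(signals, labels, sampling_rate), model_cfg)

    def fit(
        self,
        test_set: EEGTrialSet | None = None,
        train_cfg: TrainConfig | None = None,
        **kwargs,
    ) -> "MotorImageryResults":
        """Train and return results.

        ``kwargs`` override individual TrainConfig fields, e.g.
        ``fit(test_set, epochs=60, seed=7)``.  With no test set, the
        training set doubles as the monitoring set.
        """
        if train_cfg is None:
            train_cfg = TrainConfig()
        if kwargs:
            weight_keys = {k: kwargs.pop(k) for k in ("alpha_lsr", "alpha_ct") if k in kwargs}
            if weight_keys:
                kwargs["weights"] = replace(train_cfg.weights, **weight_keys)
            train_cfg = replace(train_cfg, **kwargs)
        monitor = test_set if test_set is not None else self.train_set
        model, bank, history = train_model(self.train_set, monitor, self.model_cfg, train_cfg)
        return MotorImageryResults(self, model, bank, history, train_cfg, test_set)


class MotorImageryResults:
    """Fitted decoder: trained weights, class centers, and per-epoch history."""

    def __init__(
        self,
        spec: MotorImageryClassifier,
        model: EEGNetClassifier,
        centers: CenterBank,
        history: TrainHistory,
        train_cfg: TrainConfig,
        test_set: EEGTrialSet | None,
    ):
        self.model_spec = spec
        self.model = model
        self.centers = centers
        self.history = history
        self.train_cfg = train_cfg
        self.test_set = test_set

    # -- predictions -------------------------------------------------------
    def predict(self, data) -> np.ndarray:
        """Class labels for a trial set or raw (n, E, T) array."""
        signals = data.signals if isinstance(data, EEGTrialSet) else np.asarray(data)
        return predict_labels(self.model, signals)

    def accuracy(self, data: EEGTrialSet | None = None) -> float:
        """Percent accuracy on ``data`` (default: the held-out test set)."""
        ts = data if data is not None else self.test_set
        if ts is None:
            raise ValueError("no test set available; pass a trial set explicitly")
        return _ev.accuracy(self.predict(ts), ts.labels)

    def features(self, data: EEGTrialSet | None = None) -> np.ndarray:
        ts = data if data is not None else self.test_set
        if ts is None:
            raise ValueError("no test set available; pass a trial set explicitly")
        return extract_features(self.model, ts)

    def dispersion(self, data: EEGTrialSet | None = None) -> _ev.DispersionSummary:
        ts = data if data is not None else self.test_set
        if ts is None:
            raise ValueError("no test set available; pass a trial set explicitly")
        return _ev.class_dispersion(self.features(ts), ts.labels)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        cfg, tc = self.model_spec.model_cfg, self.train_cfg
        final = self.history.records[-1]
        lines = [
            "Motor-Imagery CNN Results",
            "=" * 58,
            f"architecture      T={cfg.T} E={cfg.E} M={cfg.M} "
            f"F1={cfg.F1} F2={cfg.F2} K1={cfg.K1} K2={cfg.K2} D={cfg.D} "
            f"P1={cfg.P1} P2={cfg.P2}",
            f"feature dim       {cfg.feature_dim}",
            f"parameters        {self.model.n_params}",
            f"objective         L_cl + {tc.weights.alpha_lsr}*L_lsr + {tc.weights.alpha_ct}*L_ct",
            f"optimizer         Adam lr={tc.learning_rate}, batch={tc.batch_size}, "
            f"epochs={tc.epochs}, seed={tc.seed}",
            "-" * 58,
            f"final train loss  {final['train_loss']:.4f}  "
            f"(CE {final['train_ce']:.4f}, LSR {final['train_lsr']:.4f}, "
            f"CT {final['train_ct']:.4f})",
            f"final train acc   {100 * final['train_acc']:.2f}%",
            f"final test loss   {final['test_loss']:.4f}",
            f"final test acc    {100 * final['test_acc']:.2f}%",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_learning_curves(self, path=None, ax=None):
        return _ev.plot_learning_curves(self.history, path=path, ax=ax)

    def plot_feature_scatter(self, data: EEGTrialSet | None = None, path=None, ax=None):
        ts = data if data is not None else self.test_set
        if ts is None:
            raise ValueError("no test set available; pass a trial set explicitly")
        return _ev.plot_feature_scatter(self.features(ts), ts.labels, path=path, ax=ax)
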