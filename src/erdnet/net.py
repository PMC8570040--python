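"""Compact temporal/depthwise/separable CNN for raw EEG trials.

The architecture is the EEGNet family's three-stage pipeline, with the first
temporal kernel kept short (K1 = 32 samples at 250 Hz, i.e. ~8 Hz and above)
so the filters concentrate on the mu/beta band where motor imagery lives:

1. temporal convolution, F1 filters of kernel (K1, 1), length-preserving
   zero padding, batch norm;
2. depthwise spatial convolution across all E electrodes (kernel (1, E),
   depth multiplier D, no padding), batch norm, ELU, average pool (P1, 1);
3. separable convolution — a per-channel temporal filter of kernel (K2, 1)
   followed by a pointwise mix to F2 maps — batch norm, ELU, average
   pool (P2, 1);
4. flatten to the deep-feature vector of length T*F2/(P1*P2), then a dense
   layer to M logits and softmax.

Everything is plain NumPy: the forward pass caches intermediates and the
backward pass returns exact gradients (verified against central finite
differences in the test suite), so no deep-learning framework is required.
Inference mode uses batch-norm running statistics and is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelConfig",
    "NetworkOutputs",
    "ConfigurationError",
    "feature_dim",
    "build_model",
    "forward",
    "extract_features",
    "predict_labels",
    "softmax",
    "EEGNetClassifier",
]

BN_MOMENTUM = 0.99
BN_EPS = 1e-3


class ConfigurationError(ValueError):
    """Architecture hyperparameters violate a shape constraint."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the standard 4-class, 22-electrode configuration for 4 s
    trials at 250 Hz (T = 1000 samples).  Constructing a config only checks
    positivity; :func:`feature_dim` requires the flatten length
    T*F2/(P1*P2) to be integral, and :func:`build_model` additionally
    requires ``T`` divisible by ``P1`` and ``T // P1`` by ``P2`` so every
    pooled tensor has an exact length.
    """

    T: int = 1000  # samples per trial
    E: int = 22  # electrodes
    M: int = 4  # classes
    F1: int = 8  # temporal filters
    F2: int = 16  # separable (pointwise) filters
    K1: int = 32  # temporal kernel length
    K2: int = 16  # separable kernel length
    D: int = 2  # depth multiplier of the spatial convolution
    P1: int = 8  # first average-pooling length
    P2: int = 8  # second average-pooling length

    def __post_init__(self) -> None:
        for name in ("T", "E", "M", "F1", "F2", "K1", "K2", "D", "P1", "P2"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.M < 2:
            raise ConfigurationError("M must be >= 2")

    def check_pooling(self) -> None:
        """Require exact pooled lengths (needed to build the network)."""
        if self.T % self.P1 != 0 or (self.T // self.P1) % self.P2 != 0:
            raise ConfigurationError(
                f"T={self.T} must be divisible by P1={self.P1} and T/P1 by P2={self.P2}"
            )

    @property
    def feature_dim(self) -> int:
        return feature_dim(self)

    def layer_output_shapes(self) -> list[tuple[int, int, int]]:
        """Per-stage output shapes in (time, space, maps) order."""
        self.check_pooling()
        return [
            (self.T, self.E, self.F1),
            (self.T, 1, self.F1 * self.D),
            (self.T // self.P1, 1, self.F1 * self.D),
            (self.T // self.P1, 1, self.F2),
            (self.T // (self.P1 * self.P2), 1, self.F2),
        ]


def feature_dim(cfg: ModelConfig) -> int:
    """Length of the flattened deep feature: T * F2 / (P1 * P2)."""
    num = cfg.T * cfg.F2
    den = cfg.P1 * cfg.P2
    if num % den:
        raise ConfigurationError(
            f"feature dim {num}/{den} is not integral for "
            f"T={cfg.T}, F2={cfg.F2}, P1={cfg.P1}, P2={cfg.P2}"
        )
    return num // den


@dataclass
class NetworkOutputs:
    """Forward-pass products: logits z, softmax probabilities q, deep features."""

    logits: np.ndarray  # (n, M)
    probabilities: np.ndarray  # (n, M), rows on the simplex
    features: np.ndarray  # (n, feature_dim)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction for overflow safety."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# convolution primitives (correlation convention, length-preserving padding)
# ---------------------------------------------------------------------------

def _same_pads(K: int) -> tuple[int, int]:
    return (K - 1) // 2, K // 2


def _corr_shared(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """x (N, G, L) filtered along L by W (F, K), same filters for every G.

    Returns (N, F, G, L).
    """
    K = W.shape[1]
    pl, pr = _same_pads(K)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = sliding_window_view(xp, K, axis=-1)  # (N, G, L, K)
    return np.einsum("ngtk,fk->nfgt", win, W, optimize=True)


def _corr_shared_backward(
    dy: np.ndarray, x: np.ndarray, W: np.ndarray, need_dx: bool = True
) -> tuple[np.ndarray | None, np.ndarray]:
    """Gradients of :func:`_corr_shared` w.r.t. x and W.

    ``need_dx=False`` skips the (expensive) input gradient — used at the
    first layer, whose input is the data.
    """
    K = W.shape[1]
    pl, pr = _same_pads(K)
    L = x.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = sliding_window_view(xp, K, axis=-1)
    dW = np.einsum("nfgt,ngtk->fk", dy, win, optimize=True)
    if not need_dx:
        return None, dW
    dyp = np.pad(dy, ((0, 0), (0, 0), (0, 0), (K - 1, K - 1)))
    dwin = sliding_window_view(dyp, K, axis=-1)  # (N, F, G, L+K-1, K)
    dxp = np.einsum("nfgtk,fk->ngt", dwin, W[:, ::-1], optimize=True)
    return dxp[..., pl : pl + L], dW


def _corr_depthwise(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """x (N, C, L) filtered along L, one kernel per channel: W (C, K) -> (N, C, L)."""
    K = W.shape[1]
    pl, pr = _same_pads(K)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = sliding_window_view(xp, K, axis=-1)
    return np.einsum("nctk,ck->nct", win, W, optimize=True)


def _corr_depthwise_backward(
    dy: np.ndarray, x: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    K = W.shape[1]
    pl, pr = _same_pads(K)
    L = x.shape[-1]
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    win = sliding_window_view(xp, K, axis=-1)
    dW = np.einsum("nct,nctk->ck", dy, win, optimize=True)
    dyp = np.pad(dy, ((0, 0), (0, 0), (K - 1, K - 1)))
    dwin = sliding_window_view(dyp, K, axis=-1)
    dxp = np.einsum("nctk,ck->nct", dwin, W[:, ::-1], optimize=True)
    return dxp[..., pl : pl + L], dW


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    # derivative in terms of output: 1 for x > 0, y + 1 otherwise (alpha = 1)
    return np.where(x > 0, 1.0, y + 1.0)


class _BatchNorm:
    """Per-channel batch normalization over all non-channel axes."""

    def __init__(self, n_channels: int, dtype=np.float64):
        self.gamma = np.ones(n_channels, dtype=dtype)
        self.beta = np.zeros(n_channels, dtype=dtype)
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)

    def forward(self, x: np.ndarray, axes: tuple, training: bool) -> tuple[np.ndarray, dict]:
        shape = [1] * x.ndim
        shape[1] = x.shape[1]  # channel axis is 1 by convention
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = BN_MOMENTUM * self.running_mean + (1 - BN_MOMENTUM) * mean
            self.running_var = BN_MOMENTUM * self.running_var + (1 - BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        y = self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)
        cache = {
            "xhat": xhat,
            "inv_std": inv_std,
            "axes": axes,
            "shape": shape,
            "training": training,
        }
        return y, cache

    def backward(self, dy: np.ndarray, cache: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes, shape = cache["axes"], cache["shape"]
        xhat, inv_std = cache["xhat"], cache["inv_std"]
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma.reshape(shape)
        if not cache["training"]:
            return dxhat * inv_std.reshape(shape), dgamma, dbeta
        dx = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        ) * inv_std.reshape(shape)
        return dx, dgamma, dbeta


def _avg_pool(x: np.ndarray, P: int) -> np.ndarray:
    N, C, L = x.shape
    return x.reshape(N, C, L // P, P).mean(axis=-1)


def _avg_pool_backward(dy: np.ndarray, P: int) -> np.ndarray:
    return np.repeat(dy / P, P, axis=-1)


class EEGNetClassifier:
    """The CNN with explicit parameters, forward cache and exact backward pass.

    Parameters are Glorot-uniform initialized from ``seed``; convolutions
    carry no bias (each is followed by batch norm), only the final dense
    layer has one.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        cfg.check_pooling()
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        C = cfg.F1 * cfg.D
        d = cfg.feature_dim

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape).astype(self.dtype)

        self.params: dict[str, np.ndarray] = {
            "w_temporal": glorot((cfg.F1, cfg.K1), cfg.K1, cfg.F1 * cfg.K1),
            "w_spatial": glorot((cfg.F1, cfg.D, cfg.E), cfg.E, cfg.D),
            "w_sep_depth": glorot((C, cfg.K2), cfg.K2, cfg.K2),
            "w_sep_point": glorot((cfg.F2, C), C, cfg.F2),
            "w_dense": glorot((cfg.M, d), d, cfg.M),
            "b_dense": np.zeros(cfg.M, dtype=self.dtype),
        }
        self.bn1 = _BatchNorm(cfg.F1, self.dtype)
        self.bn2 = _BatchNorm(C, self.dtype)
        self.bn3 = _BatchNorm(cfg.F2, self.dtype)
        for i, bn in enumerate((self.bn1, self.bn2, self.bn3), start=1):
            self.params[f"bn{i}_gamma"] = bn.gamma
            self.params[f"bn{i}_beta"] = bn.beta

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params.items()}
        for i, bn in enumerate((self.bn1, self.bn2, self.bn3), start=1):
            state[f"bn{i}_running_mean"] = bn.running_mean.copy()
            state[f"bn{i}_running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            np.copyto(self.params[k], state[k])
        for i, bn in enumerate((self.bn1, self.bn2, self.bn3), start=1):
            bn.running_mean = np.array(state[f"bn{i}_running_mean"])
            bn.running_var = np.array(state[f"bn{i}_running_var"])

    def save(self, path) -> None:
        """Write weights (.npz) with the config embedded as JSON."""
        np.savez(path, __config__=json.dumps(asdict(self.cfg)), **self.state_dict())

    @classmethod
    def load(cls, path) -> "EEGNetClassifier":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig(**json.loads(str(data["__config__"])))
            model = cls(cfg)
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model

    # -- forward -----------------------------------------------------------
    def forward(
        self, batch: np.ndarray, training: bool = False, return_cache: bool = False
    ):
        """Run the network on a (n, E, T) batch of trials."""
        cfg = self.cfg
        x = np.asarray(batch, dtype=self.dtype)
        if x.ndim != 3 or x.shape[1:] != (cfg.E, cfg.T):
            raise ValueError(
                f"batch shape {x.shape} does not match (n, E={cfg.E}, T={cfg.T})"
            )
        p = self.params
        c: dict = {"x": x}

        # stage 1: temporal convolution + BN          -> (n, F1, E, T)
        c["conv1"] = _corr_shared(x, p["w_temporal"])
        c["bn1"], c["bn1_cache"] = self.bn1.forward(c["conv1"], (0, 2, 3), training)

        # stage 2: depthwise spatial conv (1, E) + BN + ELU + pool -> (n, F1*D, T/P1)
        c["spat"] = np.einsum("nfet,fde->nfdt", c["bn1"], p["w_spatial"], optimize=True)
        N = x.shape[0]
        c["spat_flat"] = c["spat"].reshape(N, cfg.F1 * cfg.D, cfg.T)
        c["bn2"], c["bn2_cache"] = self.bn2.forward(c["spat_flat"], (0, 2), training)
        c["elu2"] = _elu(c["bn2"])
        c["pool2"] = _avg_pool(c["elu2"], cfg.P1)

        # stage 3: separable conv (depthwise K2 + pointwise) + BN + ELU + pool
        c["sepd"] = _corr_depthwise(c["pool2"], p["w_sep_depth"])
        c["sepp"] = np.einsum("nct,fc->nft", c["sepd"], p["w_sep_point"], optimize=True)
        c["bn3"], c["bn3_cache"] = self.bn3.forward(c["sepp"], (0, 2), training)
        c["elu3"] = _elu(c["bn3"])
        c["pool3"] = _avg_pool(c["elu3"], cfg.P2)

        # stage 4: flatten (time-major, matching the (time, 1, maps) layout)
        feats = c["pool3"].transpose(0, 2, 1).reshape(N, -1)
        logits = feats @ p["w_dense"].T + p["b_dense"]
        c["features"] = feats
        out = NetworkOutputs(logits=logits, probabilities=softmax(logits), features=feats)
        if return_cache:
            return out, c
        return out

    # -- backward ----------------------------------------------------------
    def backward(
        self, cache: dict, dlogits: np.ndarray, dfeatures: np.ndarray | None = None
    ) -> dict[str, np.ndarray]:
        """Exact gradients of the cached forward pass.

        ``dlogits`` is dL/dz; ``dfeatures`` is any extra gradient applied
        directly to the deep features (the center-loss pull).
        """
        cfg, p, c = self.cfg, self.params, cache
        N = c["x"].shape[0]
        grads: dict[str, np.ndarray] = {}

        feats = c["features"]
        grads["w_dense"] = dlogits.T @ feats
        grads["b_dense"] = dlogits.sum(axis=0)
        dfeat = dlogits @ p["w_dense"]
        if dfeatures is not None:
            dfeat = dfeat + dfeatures
        L3 = cfg.T // (cfg.P1 * cfg.P2)
        dpool3 = dfeat.reshape(N, L3, cfg.F2).transpose(0, 2, 1)

        delu3 = _avg_pool_backward(dpool3, cfg.P2)
        dbn3 = delu3 * _elu_grad(c["elu3"], c["bn3"])
        dsepp, grads["bn3_gamma"], grads["bn3_beta"] = self.bn3.backward(dbn3, c["bn3_cache"])
        grads["w_sep_point"] = np.einsum("nft,nct->fc", dsepp, c["sepd"], optimize=True)
        dsepd = np.einsum("nft,fc->nct", dsepp, p["w_sep_point"], optimize=True)
        dpool2, grads["w_sep_depth"] = _corr_depthwise_backward(
            dsepd, c["pool2"], p["w_sep_depth"]
        )

        delu2 = _avg_pool_backward(dpool2, cfg.P1)
        dbn2 = delu2 * _elu_grad(c["elu2"], c["bn2"])
        dspat_flat, grads["bn2_gamma"], grads["bn2_beta"] = self.bn2.backward(
            dbn2, c["bn2_cache"]
        )
        dspat = dspat_flat.reshape(N, cfg.F1, cfg.D, cfg.T)
        grads["w_spatial"] = np.einsum("nfdt,nfet->fde", dspat, c["bn1"], optimize=True)
        dbn1 = np.einsum("nfdt,fde->nfet", dspat, p["w_spatial"], optimize=True)

        dconv1, grads["bn1_gamma"], grads["bn1_beta"] = self.bn1.backward(dbn1, c["bn1_cache"])
        _, grads["w_temporal"] = _corr_shared_backward(
            dconv1, c["x"], p["w_temporal"], need_dx=False
        )
        return grads


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def build_model(cfg: ModelConfig, seed: int = 0, dtype=np.float32) -> EEGNetClassifier:
    """Construct the network with deterministic seeded initialization.

    ``dtype`` is the compute precision: float32 (default) is plenty for
    training this compact architecture; float64 is used by the
    finite-difference gradient checks.
    """
    return EEGNetClassifier(cfg, seed=seed, dtype=dtype)


def forward(model: EEGNetClassifier, batch: np.ndarray) -> NetworkOutputs:
    """Inference-mode forward pass (batch-norm running statistics)."""
    return model.forward(batch, training=False)


def extract_features(model: EEGNetClassifier, trialset, batch_size: int = 256) -> np.ndarray:
    """Penultimate (flatten-layer) activations for every trial, inference mode."""
    signals = np.asarray(trialset.signals if hasattr(trialset, "signals") else trialset)
    rows = []
    for start in range(0, signals.shape[0], batch_size):
        rows.append(model.forward(signals[start : start + batch_size]).features)
    return np.concatenate(rows, axis=0)


def predict_labels(model: EEGNetClassifier, signals: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Argmax class per trial; exact ties resolve to the lowest class index."""
    signals = np.asarray(signals)
    out = []
    for start in range(0, signals.shape[0], batch_size):
        logits = model.forward(signals[start : start + batch_size]).logits
        out.append(np.argmax(logits, axis=1))
    return np.concatenate(out)
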