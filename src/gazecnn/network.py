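"""The 1-D convolutional gaze classifier.

A (2 x 600) trial — x- and y-position over the 1,200-ms search window —
passes through a single valid (unpadded) convolution (64 features, kernel 3,
stride 1), a ReLU, dropout (training only, p = 0.25), max pooling (size and
stride 5), and is flattened to 7,616 values feeding three linear transforms
(64, 32, and 6 neurons) with no activation between them.  The six outputs
are logits, one per candidate stimulus location; the argmax is the
prediction.

The forward and backward passes are implemented here directly on numpy
arrays, which keeps every intermediate quantity inspectable by the
attribution machinery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetworkConfig",
    "GazeNet",
    "conv_output_length",
    "predict",
    "save_model",
    "load_model",
]


def conv_output_length(L: int, k: int, s: int = 1) -> int:
    """Number of valid kernel placements on a length-L input: floor((L-k)/s)+1."""
    if k < 1 or s < 1:
        raise ValueError("kernel and stride must be positive")
    if L < k:
        raise ValueError(f"input length {L} is shorter than the kernel {k}")
    return (L - k) // s + 1


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture constants; the defaults reproduce the reference stack."""

    in_channels: int = 2
    conv_features: int = 64
    kernel_size: int = 3
    stride: int = 1
    dropout_p: float = 0.25
    pool_size: int = 5
    pool_stride: int = 5
    hidden_sizes: Tuple[int, ...] = (64, 32)
    n_classes: int = 6
    input_length: int = 600

    @property
    def conv_length(self) -> int:
        return conv_output_length(self.input_length, self.kernel_size, self.stride)

    @property
    def pooled_length(self) -> int:
        return self.conv_length // self.pool_size

    @property
    def flatten_length(self) -> int:
        """64 features x 119 pooled samples = 7,616 for the default window."""
        return self.conv_features * self.pooled_length


def _init_params(cfg: NetworkConfig, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    # fan-in-scaled uniform init, U(-1/sqrt(fan_in), 1/sqrt(fan_in)) per layer
    p: Dict[str, np.ndarray] = {}
    fan = cfg.in_channels * cfg.kernel_size
    b = 1.0 / np.sqrt(fan)
    p["Wc"] = rng.uniform(-b, b, size=(cfg.conv_features, cfg.in_channels, cfg.kernel_size))
    p["bc"] = rng.uniform(-b, b, size=cfg.conv_features)
    sizes = (cfg.flatten_length, *cfg.hidden_sizes, cfg.n_classes)
    for i in range(len(sizes) - 1):
        b = 1.0 / np.sqrt(sizes[i])
        p[f"W{i}"] = rng.uniform(-b, b, size=(sizes[i], sizes[i + 1]))
        p[f"b{i}"] = rng.uniform(-b, b, size=sizes[i + 1])
    return p


@dataclass
class GazeNet:
    """Network parameters plus a training-mode flag (dropout active only then)."""

    config: NetworkConfig
    params: Dict[str, np.ndarray]
    training: bool = False

    @classmethod
    def init(cls, config: NetworkConfig = NetworkConfig(), seed: int = 0) -> "GazeNet":
        return cls(config=config, params=_init_params(config, np.random.default_rng(seed)))

    @property
    def n_linear(self) -> int:
        return len(self.config.hidden_sizes) + 1

    def copy(self) -> "GazeNet":
        return GazeNet(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            training=self.training,
        )

    # ----- forward ---------------------------------------------------------

    def _conv(self, x: np.ndarray) -> np.ndarray:
        cfg = self.config
        win = sliding_window_view(x, cfg.kernel_size, axis=2)[:, :, :: cfg.stride]
        return np.einsum("nclk,fck->nfl", win, self.params["Wc"], optimize=True) + self.params["bc"][:, None]

    def forward(
        self,
        x: np.ndarray,
        rng: Optional[np.random.Generator] = None,
        cache: Optional[dict] = None,
    ) -> np.ndarray:
        """Logits of shape (n, n_classes) for a batch of (n, 2, L) traces.

        When ``training`` is set, dropout is sampled from ``rng`` with
        inverted scaling; in evaluation mode the pass is deterministic.
        ``cache``, if given a dict, is filled with the intermediates needed
        by :meth:`backward`.
        """
        cfg = self.config
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1] != cfg.in_channels or x.shape[2] != cfg.input_length:
            raise ValueError(
                f"expected input of shape (n, {cfg.in_channels}, {cfg.input_length}), "
                f"got {x.shape}"
            )
        pre = self._conv(x)
        act = np.maximum(pre, 0.0)
        if self.training and cfg.dropout_p > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = rng.random(act.shape) >= cfg.dropout_p
            mask = keep / (1.0 - cfg.dropout_p)
        else:
            mask = None
        dropped = act * mask if mask is not None else act
        Lp = cfg.pooled_length
        windows = dropped[:, :, : Lp * cfg.pool_size].reshape(
            x.shape[0], cfg.conv_features, Lp, cfg.pool_size
        )
        arg = windows.argmax(axis=3)
        pooled = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]
        h = pooled.reshape(x.shape[0], -1)
        hs = [h]
        for i in range(self.n_linear):
            h = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            hs.append(h)
        if cache is not None:
            cache.update(x=x, pre=pre, mask=mask, windows=windows, arg=arg, hs=hs)
        return hs[-1]

    # ----- backward --------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        """Parameter gradients given d(loss)/d(logits) and a forward cache."""
        cfg = self.config
        grads: Dict[str, np.ndarray] = {}
        hs = cache["hs"]
        dh = dlogits
        for i in range(self.n_linear - 1, -1, -1):
            grads[f"W{i}"] = hs[i].T @ dh
            grads[f"b{i}"] = dh.sum(axis=0)
            dh = dh @ self.params[f"W{i}"].T
        n = cache["x"].shape[0]
        Lp = cfg.pooled_length
        dpool = dh.reshape(n, cfg.conv_features, Lp)
        dwin = np.zeros_like(cache["windows"])
        np.put_along_axis(dwin, cache["arg"][..., None], dpool[..., None], axis=3)
        ddrop = np.zeros((n, cfg.conv_features, cfg.conv_length))
        ddrop[:, :, : Lp * cfg.pool_size] = dwin.reshape(n, cfg.conv_features, Lp * cfg.pool_size)
        if cache["mask"] is not None:
            ddrop = ddrop * cache["mask"]
        dpre = ddrop * (cache["pre"] > 0)
        win = sliding_window_view(cache["x"], cfg.kernel_size, axis=2)[:, :, :: cfg.stride]
        grads["Wc"] = np.einsum("nfl,nclk->fck", dpre, win, optimize=True)
        grads["bc"] = dpre.sum(axis=(0, 2))
        return grads


def predict(logits: np.ndarray) -> np.ndarray:
    """Per-trial argmax over the six logits; ties go to the lowest index."""
    logits = np.asarray(logits, dtype=float)
    if not np.isfinite(logits).all():
        raise ValueError("cannot predict from non-finite logits")
    return logits.argmax(axis=-1)


def save_model(model: GazeNet, path) -> None:
    """Versioned checkpoint: architecture config + all weights, exact round-trip."""
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(asdict(model.config)).encode(), dtype=np.uint8),
        **model.params,
    )


def load_model(path) -> GazeNet:
    with np.load(path) as z:
        cfg_raw = json.loads(bytes(z["__config__"].tobytes()).decode())
        cfg_raw["hidden_sizes"] = tuple(cfg_raw["hidden_sizes"])
        cfg = NetworkConfig(**cfg_raw)
        params = {k: z[k] for k in z.files if k != "__config__"}
    return GazeNet(config=cfg, params=params)
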