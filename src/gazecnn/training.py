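"""Mini-batched training with Adam, exponential LR decay, and early stopping.

Each training/validation cycle runs ceil(n_train/64) gradient updates with
dropout active, then freezes the weights and scores the validation set with
dropout off.  The learning rate starts at 1e-3 and shrinks by gamma = 0.9
after every cycle.  Training halts after 10 consecutive cycles without a new
minimum validation loss, and the weights from the minimum-loss cycle are
restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .network import GazeNet, NetworkConfig, predict
from .partition import SplitIndex, make_minibatches
from .preprocess import TraceMatrix

__all__ = [
    "TrainConfig",
    "TrainingState",
    "softmax",
    "cross_entropy_loss",
    "decay_lr",
    "early_stopping_step",
    "fit",
]


@dataclass
class TrainConfig:
    batch_size: int = 64
    initial_lr: float = 1e-3
    gamma: float = 0.9          # per-cycle LR multiplier
    patience: int = 10          # cycles without a new minimum before stopping
    beta1: float = 0.9          # Adam moment-decay constants
    beta2: float = 0.999
    eps: float = 1e-8
    max_epochs: int = 200       # safety cap on top of early stopping
    reshuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must lie in (0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainingState:
    epoch: int = 0
    current_lr: float = 1e-3
    best_val_loss: float = np.inf
    best_epoch: int = -1
    epochs_since_improvement: int = 0
    best_checkpoint: Optional[GazeNet] = None
    n_updates: int = 0
    history: List[Dict[str, float]] = field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy, -log softmax(logits)[label]."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= logits.shape[-1]:
        raise ValueError("labels must index a logit column")
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    return float(-logp[np.arange(len(labels)), labels].mean())


def decay_lr(lr: float, gamma: float) -> float:
    """Exponential decay: the next cycle's rate is lr * gamma."""
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    return lr * gamma


def early_stopping_step(
    state: TrainingState,
    val_loss: float,
    model: GazeNet,
    patience: int = 10,
) -> Tuple[TrainingState, bool]:
    """Track the minimum validation loss; stop after `patience` flat cycles.

    A strict decrease snapshots the model and resets the counter; anything
    else (including an exact tie) increments it.  On stop the state carries
    the minimum-loss snapshot for restoration.
    """
    if not np.isfinite(val_loss):
        raise FloatingPointError("validation loss diverged (non-finite)")
    if val_loss < state.best_val_loss:
        state.best_val_loss = float(val_loss)
        state.best_epoch = state.epoch
        state.best_checkpoint = model.copy()
        state.epochs_since_improvement = 0
    else:
        state.epochs_since_improvement += 1
    return state, state.epochs_since_improvement >= patience


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray], lr: float) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1**self.t
        b2t = 1.0 - c.beta2**self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + c.eps)


def evaluate_split(
    model: GazeNet, x: np.ndarray, labels: np.ndarray, chunk: int = 512
) -> Tuple[float, float, np.ndarray]:
    """Frozen-weights loss, accuracy and predictions over a whole subset.

    The loss is the mean cross-entropy over *all* trials (not a mean of
    batch means), so ragged final batches carry their correct weight.
    """
    was_training = model.training
    model.training = False
    logits = np.concatenate(
        [model.forward(x[i : i + chunk]) for i in range(0, len(x), chunk)]
    )
    model.training = was_training
    preds = predict(logits)
    loss = cross_entropy_loss(logits, labels)
    acc = float((preds == labels).mean())
    return loss, acc, preds


def fit(
    data: TraceMatrix,
    labels: np.ndarray,
    split: SplitIndex,
    net_cfg: Optional[NetworkConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
) -> Tuple[GazeNet, TrainingState]:
    """Train a :class:`GazeNet` on the split's training trials.

    Returns the restored minimum-validation-loss model together with the
    full training state (per-cycle history of losses, accuracy and LR).
    Fully deterministic for a fixed ``train_cfg.seed``.
    """
    net_cfg = net_cfg or NetworkConfig(input_length=data.length)
    train_cfg = train_cfg or TrainConfig()
    tr_mask = split.mask(data.trial_order, "train")
    va_mask = split.mask(data.trial_order, "val")
    x_tr, y_tr = data.values[tr_mask], labels[tr_mask]
    x_va, y_va = data.values[va_mask], labels[va_mask]
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("split must reference existing train and validation trials")

    rng = np.random.default_rng(train_cfg.seed)
    model = GazeNet.init(net_cfg, seed=train_cfg.seed)
    model.training = True
    opt = _Adam(model.params, train_cfg)
    state = TrainingState(current_lr=train_cfg.initial_lr)

    for epoch in range(train_cfg.max_epochs):
        state.epoch = epoch
        plan = make_minibatches(
            len(x_tr),
            train_cfg.batch_size,
            shuffle_seed=(train_cfg.seed + epoch if train_cfg.reshuffle_each_epoch else train_cfg.seed),
        )
        losses = []
        for batch in plan.batches:
            cache: dict = {}
            logits = model.forward(x_tr[batch], rng=rng, cache=cache)
            loss = cross_entropy_loss(logits, y_tr[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            losses.append(loss)
            p = softmax(logits)
            p[np.arange(len(batch)), y_tr[batch]] -= 1.0
            grads = model.backward(cache, p / len(batch))
            opt.step(model.params, grads, state.current_lr)
            state.n_updates += 1

        val_loss, val_acc, _ = evaluate_split(model, x_va, y_va)
        state.history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_acc": val_acc,
                "lr": state.current_lr,
            }
        )
        state.current_lr = decay_lr(state.current_lr, train_cfg.gamma)
        state, stop = early_stopping_step(state, val_loss, model, train_cfg.patience)
        if stop:
            break

    best = state.best_checkpoint.copy() if state.best_checkpoint is not None else model.copy()
    best.training = False
    return best, state
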