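"""Train/validation splitting and mini-batching.

The split is deterministic: every third trial of each participant, in
presentation order, is held out for validation (a two-thirds/one-third
split).  Distractor analyses first drop distractor-absent trials, then
split the remainder the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SplitIndex",
    "MiniBatchPlan",
    "split_every_third",
    "subset_distractor_present",
    "make_minibatches",
]


@dataclass
class SplitIndex:
    """Disjoint train/validation trial keys covering the input table."""

    train_ids: List[Tuple[str, int]]
    val_ids: List[Tuple[str, int]]

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_val(self) -> int:
        return len(self.val_ids)

    def mask(self, trial_order: List[Tuple[str, int]], role: str) -> np.ndarray:
        """Boolean mask selecting this split's trials within a tensor order."""
        chosen = set(self.train_ids if role == "train" else self.val_ids)
        return np.array([k in chosen for k in trial_order])


@dataclass
class MiniBatchPlan:
    batch_size: int
    batches: List[np.ndarray]

    @property
    def n_batches(self) -> int:
        return len(self.batches)


def split_every_third(trials: pd.DataFrame) -> SplitIndex:
    """Hold out every third trial per participant (1-based ranks 3, 6, 9, ...).

    Ranks follow presentation order (ascending trial_index within
    participant); the remaining two thirds form the training set.
    """
    train: List[Tuple[str, int]] = []
    val: List[Tuple[str, int]] = []
    order = trials.sort_values(["participant_id", "trial_index"], kind="stable")
    rank = order.groupby("participant_id", sort=False).cumcount() + 1
    for (row, r) in zip(order.itertuples(), rank):
        key = (row.participant_id, int(row.trial_index))
        (val if r % 3 == 0 else train).append(key)
    return SplitIndex(train_ids=train, val_ids=val)


def subset_distractor_present(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep only distractor-present rows, preserving order."""
    out = trials[trials["distractor_location"].notna()]
    return out.reset_index(drop=True)


def make_minibatches(
    n: int,
    batch_size: int = 64,
    shuffle_seed: Optional[int] = None,
) -> MiniBatchPlan:
    """Partition ``range(n)`` into ceil(n/batch_size) consecutive batches.

    Every batch has ``batch_size`` trials except possibly the last, which
    holds the remainder.  With a seed, a reproducible permutation is applied
    before slicing (fresh shuffles between epochs are obtained by advancing
    the seed).
    """
    if n < 1:
        raise ValueError("cannot batch an empty set of trials")
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    idx = np.arange(n)
    if shuffle_seed is not None:
        idx = np.random.default_rng(shuffle_seed).permutation(n)
    batches = [idx[i : i + batch_size] for i in range(0, n, batch_size)]
    return MiniBatchPlan(batch_size=batch_size, batches=batches)
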