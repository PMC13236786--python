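"""Frequentist performance summaries.

Accuracies are aggregated per participant (the unit of inference throughout),
confidence intervals come from a percentile bootstrap over participants, and
comparisons use one-sample / paired t-tests: against the six-way chance level
of 1/6 = 16.67 %, or against the first-saccade heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CHANCE_LEVEL",
    "AccuracyReport",
    "IntervalEstimate",
    "score",
    "bootstrap_ci",
    "t_vs_chance",
    "paired_t",
]

#: Random guessing among six candidate locations.
CHANCE_LEVEL = 1.0 / 6.0


@dataclass
class AccuracyReport:
    """Trial-level outcomes rolled up overall, per participant, per location."""

    overall_accuracy: float
    per_participant: Dict[str, Tuple[int, int, float]]  # pid -> (C_i, N_i, acc)
    trial_outcomes: pd.DataFrame                        # participant_id, trial_index, correct
    confusion: np.ndarray                               # 6x6, true x predicted

    @property
    def participant_accuracies(self) -> np.ndarray:
        return np.array([v[2] for v in self.per_participant.values()])

    @property
    def counts(self) -> Tuple[np.ndarray, np.ndarray]:
        """(C_i, N_i) vectors in participant order — the Bayesian model's data."""
        c = np.array([v[0] for v in self.per_participant.values()])
        n = np.array([v[1] for v in self.per_participant.values()])
        return c, n


@dataclass
class IntervalEstimate:
    mean: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 10_000
    seed: int = 0


def score(preds: np.ndarray, labels: np.ndarray, trials: pd.DataFrame) -> AccuracyReport:
    """Score predictions against labels, trial-aligned with the trial table."""
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if not (len(preds) == len(labels) == len(trials)):
        raise ValueError("preds, labels and trials must be aligned 1:1")
    correct = preds == labels
    outcomes = pd.DataFrame(
        {
            "participant_id": trials["participant_id"].to_numpy(),
            "trial_index": trials["trial_index"].to_numpy(),
            "correct": correct,
        }
    )
    per: Dict[str, Tuple[int, int, float]] = {}
    for pid, grp in outcomes.groupby("participant_id", sort=False):
        c, n = int(grp["correct"].sum()), len(grp)
        per[pid] = (c, n, c / n)
    confusion = np.zeros((6, 6), dtype=int)
    np.add.at(confusion, (labels, preds), 1)
    return AccuracyReport(
        overall_accuracy=float(correct.mean()),
        per_participant=per,
        trial_outcomes=outcomes,
        confusion=confusion,
    )


def bootstrap_ci(
    per_participant_acc: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> IntervalEstimate:
    """Percentile bootstrap of the participant-level mean accuracy.

    Participants are resampled with replacement; the 2.5th/97.5th
    percentiles of the replicate means bound the interval.
    """
    acc = np.asarray(per_participant_acc, dtype=float)
    if acc.size == 0:
        raise ValueError("need at least one participant accuracy")
    rng = np.random.default_rng(seed)
    reps = rng.integers(0, acc.size, size=(n_boot, acc.size))
    means = acc[reps].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return IntervalEstimate(
        mean=float(acc.mean()), lower=float(lo), upper=float(hi),
        level=level, n_boot=n_boot, seed=seed,
    )


def t_vs_chance(
    per_participant_acc: Sequence[float], chance: float = CHANCE_LEVEL
) -> Tuple[float, int, float]:
    """One-sample t-test of participant accuracies against chance (two-sided)."""
    acc = np.asarray(per_participant_acc, dtype=float)
    if acc.size < 2:
        raise ValueError("t-test needs at least 2 participants")
    if np.allclose(acc.std(ddof=1), 0.0) and not np.allclose(acc.mean(), chance):
        raise ValueError("zero variance across participants; t undefined")
    res = stats.ttest_1samp(acc, popmean=chance)
    return float(res.statistic), int(acc.size - 1), float(res.pvalue)


def paired_t(
    acc_a: Dict[str, float] | Sequence[float],
    acc_b: Dict[str, float] | Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> Tuple[float, int, float, float, IntervalEstimate]:
    """Paired t-test of two per-participant accuracy sets.

    Dict inputs are matched by participant id (mismatched ids raise);
    sequence inputs are assumed aligned.  The mean difference is reported
    with a participant-level percentile-bootstrap CI.
    """
    if isinstance(acc_a, dict) or isinstance(acc_b, dict):
        if not (isinstance(acc_a, dict) and isinstance(acc_b, dict)):
            raise ValueError("either both or neither input may be a dict")
        if set(acc_a) != set(acc_b):
            raise ValueError("participant sets differ between the two conditions")
        keys = list(acc_a)
        a = np.array([acc_a[k] for k in keys], dtype=float)
        b = np.array([acc_b[k] for k in keys], dtype=float)
    else:
        a = np.asarray(acc_a, dtype=float)
        b = np.asarray(acc_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired inputs must have equal length")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(a, b)
        t, p = float(res.statistic), float(res.pvalue)
    ci = bootstrap_ci(diff, n_boot=n_boot, seed=seed)
    return t, int(a.size - 1), p, float(diff.mean()), ci
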