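"""Raw gaze traces -> fixed-length network tensors, plus participant exclusion.

A trial's trace becomes a (2, L) block: missing samples are replaced by the
central-fixation coordinate, short traces are fixation-padded at the end
(the search array disappears at response), and over-long traces are truncated.
For the 1,200-ms response window at 500 Hz, L = 600 samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import ArrayGeometry, Dataset

__all__ = [
    "DEFAULT_WINDOW_SAMPLES",
    "TraceMatrix",
    "ExclusionReport",
    "fill_missing",
    "pad_or_truncate",
    "assemble",
    "preprocess_dataset",
    "exclude_participants",
    "exclusion_from_proportions",
]

#: 1,200-ms window sampled at 500 Hz.
DEFAULT_WINDOW_SAMPLES = 600


@dataclass
class TraceMatrix:
    """Preprocessed gaze tensor: trials x 2 features (x then y) x L samples."""

    values: np.ndarray
    trial_order: List[Tuple[str, int]]

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[1] != 2:
            raise ValueError("values must have shape (n_trials, 2, L)")
        if self.values.shape[0] != len(self.trial_order):
            raise ValueError("trial_order must align with the tensor rows")
        if not np.isfinite(self.values).all():
            raise ValueError("preprocessed tensor must be fully observed")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[2]


@dataclass
class ExclusionReport:
    """Participants excluded for excess missing data (> mean + 2 SD)."""

    proportions: Dict[str, float]
    mean: float
    sd: float
    threshold: float
    excluded: List[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": list(self.proportions),
                "missing_proportion": list(self.proportions.values()),
                "excluded": [p in self.excluded for p in self.proportions],
            }
        )


def fill_missing(trace: np.ndarray, g: ArrayGeometry) -> np.ndarray:
    """Replace missing (NaN) samples with the central-fixation coordinate."""
    out = np.array(trace, dtype=float, copy=True)
    if out.size:
        out[np.isnan(out[:, 0]), 0] = g.center_x
        out[np.isnan(out[:, 1]), 1] = g.center_y
    return out


def pad_or_truncate(trace: np.ndarray, L: int, g: ArrayGeometry) -> np.ndarray:
    """Equate trace length to L samples.

    Shorter traces are padded at the end with the fixation coordinate
    (the array has disappeared by then); longer traces — which arise from
    slight misalignment between the tracker clock and the response-window
    signal — lose their excess tail.
    """
    if L <= 0:
        raise ValueError("target length L must be positive")
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    if n >= L:
        return trace[:L].copy()
    out = np.empty((L, 2))
    out[:n] = trace
    out[n:] = (g.center_x, g.center_y)
    return out


def assemble(
    traces: Sequence[np.ndarray],
    trials: pd.DataFrame,
    semantics: str = "target",
) -> Tuple[TraceMatrix, np.ndarray]:
    """Stack fixed-length traces into the (n, 2, L) tensor with labels.

    ``semantics`` selects the label column: the search target's location or
    the distractor's.  Distractor semantics requires every row to carry a
    distractor; callers subset distractor-present trials first.
    """
    if semantics not in ("target", "distractor"):
        raise ValueError("semantics must be 'target' or 'distractor'")
    if len(traces) != len(trials):
        raise ValueError("one trace per trial row is required")
    col = "target_location" if semantics == "target" else "distractor_location"
    lab = trials[col].to_numpy(dtype=float)
    if np.isnan(lab).any():
        raise ValueError(
            "distractor semantics requires distractor-present trials only; "
            "subset before assembling"
        )
    arrs = [np.asarray(t, dtype=float) for t in traces]
    L = arrs[0].shape[0] if arrs else 0
    if any(a.shape != (L, 2) for a in arrs):
        raise ValueError("all traces must share the same fixed length")
    values = np.stack([a.T for a in arrs]) if arrs else np.empty((0, 2, L))
    order = [(r.participant_id, int(r.trial_index)) for r in trials.itertuples()]
    return TraceMatrix(values=values, trial_order=order), lab.astype(int)


def preprocess_dataset(
    d: Dataset,
    semantics: str = "target",
    L: int = DEFAULT_WINDOW_SAMPLES,
) -> Tuple[TraceMatrix, np.ndarray]:
    """fill_missing + pad_or_truncate + assemble over a whole dataset."""
    traces = [
        pad_or_truncate(fill_missing(d.traces[k], d.geometry), L, d.geometry)
        for k in d.trial_keys
    ]
    return assemble(traces, d.trials, semantics=semantics)


def exclude_participants(d: Dataset) -> ExclusionReport:
    """Flag participants whose missing-data proportion exceeds mean + 2 SD.

    The per-participant proportion averages, over that participant's trials,
    the fraction of *recorded* samples (while the array was on screen) that
    are missing; fixation padding never counts.  The group SD uses the n-1
    sample convention and the comparison is strict, so a degenerate group
    with identical proportions excludes nobody.
    """
    pids = d.participants()
    if len(pids) < 2:
        raise ValueError("participant exclusion needs at least 2 participants")
    props: Dict[str, float] = {}
    for pid in pids:
        fracs = []
        for key in d.trial_keys:
            if key[0] != pid:
                continue
            arr = d.traces[key]
            if arr.shape[0] == 0:
                continue
            fracs.append(float(np.isnan(arr).any(axis=1).mean()))
        props[pid] = float(np.mean(fracs)) if fracs else 0.0
    return exclusion_from_proportions(props)


def exclusion_from_proportions(props: Dict[str, float]) -> ExclusionReport:
    """Apply the mean + 2 SD rule to precomputed missing proportions."""
    if len(props) < 2:
        raise ValueError("participant exclusion needs at least 2 participants")
    vals = np.array(list(props.values()))
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    threshold = mean + 2.0 * sd
    excluded = [p for p, v in props.items() if v > threshold]
    return ExclusionReport(props, mean, sd, threshold, excluded)
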