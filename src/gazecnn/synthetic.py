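"""Synthetic visual-search gaze datasets with known ground truth.

Each trial emulates the oculomotor structure the analyses assume: steady
central fixation with pixel noise, a target-directed saccade after a
lognormal latency, and — on a configurable fraction of distractor-present
trials — an initial *capture* saccade to the distractor followed, after a
short dwell, by a corrective saccade to the target.  Saccades follow a
smooth logistic position profile.  The response ends the trial (the array
disappears), so traces stop at RT and are fixation-padded downstream;
samples drop out at a configurable rate to mimic tracker loss.

The generator is the ground-truth oracle for every downstream test: the
capture fraction, label structure, and noise levels are all dialled in
explicitly and recorded in the trial table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import ArrayGeometry, Dataset, default_geometry

__all__ = ["SynthConfig", "generate", "null_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Simulator settings; defaults mirror a 1,200-ms, 500-Hz search task."""

    n_participants: int = 12
    trials_per_participant: int = 120
    distractor_present_fraction: float = 0.5
    capture_prob: float = 0.3          # P(first saccade targets the distractor)
    saccade_latency_median_ms: float = 200.0
    saccade_latency_sigma: float = 0.2  # lognormal shape
    saccade_duration_ms: float = 34.0
    saccade_duration_sd_ms: float = 5.0
    corrective_delay_ms: float = 150.0  # dwell on the distractor before correcting
    decision_lag_ms: float = 250.0      # target arrival -> button press
    decision_lag_sd_ms: float = 60.0
    gaze_noise_sd: float = 0.5          # pixels, per sample and axis
    missing_rate: float = 0.02          # per-sample dropout probability
    window_ms: float = 1200.0
    sample_period_ms: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("distractor_present_fraction", "capture_prob", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


def _logistic_profile(tau: np.ndarray) -> np.ndarray:
    # smooth 0->1 position profile over normalised saccade time
    return 1.0 / (1.0 + np.exp(-12.0 * (np.clip(tau, 0.0, 1.0) - 0.5)))


def _trial_trace(
    rng: np.random.Generator,
    cfg: SynthConfig,
    g: ArrayGeometry,
    target: int,
    distractor: Optional[int],
    captured: bool,
) -> tuple[np.ndarray, float]:
    coords = g.location_coords()
    center = g.center
    latency = float(cfg.saccade_latency_median_ms * np.exp(cfg.saccade_latency_sigma * rng.standard_normal()))
    dur1 = float(np.clip(rng.normal(cfg.saccade_duration_ms, cfg.saccade_duration_sd_ms), 15.0, 80.0))

    # waypoints: (arrival_time_ms, position); gaze holds between saccades
    legs = []  # (onset, duration, from_xy, to_xy)
    if captured and distractor is not None:
        legs.append((latency, dur1, center, coords[distractor]))
        dur2 = float(np.clip(rng.normal(cfg.saccade_duration_ms, cfg.saccade_duration_sd_ms), 15.0, 80.0))
        onset2 = latency + dur1 + cfg.corrective_delay_ms
        legs.append((onset2, dur2, coords[distractor], coords[target]))
        arrival = onset2 + dur2
    else:
        legs.append((latency, dur1, center, coords[target]))
        arrival = latency + dur1

    lag = float(np.clip(rng.normal(cfg.decision_lag_ms, cfg.decision_lag_sd_ms), 60.0, None))
    rt = float(min(arrival + lag, cfg.window_ms))
    n = max(int(round(rt / cfg.sample_period_ms)), 2)
    t = np.arange(n) * cfg.sample_period_ms

    pos = np.tile(center, (n, 1))
    for onset, dur, a, b in legs:
        tau = (t - onset) / dur
        w = _logistic_profile(tau)[:, None]
        seg = a + (b - a) * w
        pos = np.where((t >= onset)[:, None], np.where((t <= onset + dur)[:, None], seg, b), pos)
    pos = pos + rng.normal(0.0, cfg.gaze_noise_sd, size=pos.shape)
    if cfg.missing_rate > 0:
        lost = rng.random(n) < cfg.missing_rate
        pos[lost] = np.nan
    return pos, rt


def generate(cfg: SynthConfig = SynthConfig(), g: Optional[ArrayGeometry] = None) -> Dataset:
    """Draw a full synthetic dataset; bitwise-reproducible for a fixed seed.

    Targets are uniform over the six locations; the distractor, present on
    exactly the configured fraction of each participant's trials (for even
    counts), is uniform over the remaining five.  First saccades go to the
    distractor on ``capture_prob`` of distractor-present trials and to the
    target otherwise.
    """
    g = g or default_geometry()
    rng = np.random.default_rng(cfg.seed)
    rows, traces = [], {}
    n_present = int(round(cfg.distractor_present_fraction * cfg.trials_per_participant))
    width = max(3, len(str(cfg.n_participants)))
    for p in range(cfg.n_participants):
        pid = f"p{p + 1:0{width}d}"
        present_mask = np.zeros(cfg.trials_per_participant, dtype=bool)
        present_mask[rng.permutation(cfg.trials_per_participant)[:n_present]] = True
        for ti in range(cfg.trials_per_participant):
            target = int(rng.integers(6))
            if present_mask[ti]:
                others = [l for l in range(6) if l != target]
                distractor: Optional[int] = int(others[rng.integers(5)])
                captured = bool(rng.random() < cfg.capture_prob)
            else:
                distractor, captured = None, False
            trace, rt = _trial_trace(rng, cfg, g, target, distractor, captured)
            key = (pid, ti + 1)
            traces[key] = trace
            rows.append(
                {
                    "participant_id": pid,
                    "trial_index": ti + 1,
                    "target_location": target,
                    "distractor_location": np.nan if distractor is None else distractor,
                    "rt_ms": rt,
                    "n_recorded_samples": trace.shape[0],
                    "captured": captured,  # ground truth, extra column
                }
            )
    trials = pd.DataFrame(rows)
    return Dataset(geometry=g, trials=trials, traces=traces)


def null_dataset(cfg: SynthConfig = SynthConfig(), g: Optional[ArrayGeometry] = None) -> Dataset:
    """Negative control: traces carry no information about distractor labels.

    Traces are generated with ``capture_prob = 0`` (gaze is driven only by
    the target) and the distractor labels of the distractor-present trials
    are then reassigned uniformly over all six locations, independently of
    everything else.  Any classifier's expected accuracy against these
    labels is exactly 1/6.  Because reassignment ignores the target, a null
    label may coincide with the target location; null tables are an
    in-memory control and are not meant for interchange round-trips.
    """
    d = generate(replace(cfg, capture_prob=0.0), g)
    rng = np.random.default_rng(cfg.seed + 1)
    trials = d.trials.copy()
    present = trials["distractor_location"].notna()
    trials.loc[present, "distractor_location"] = rng.integers(6, size=int(present.sum())).astype(float)
    trials["captured"] = False
    return Dataset(geometry=d.geometry, trials=trials, traces=d.traces)
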