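"""Traditional oculomotor comparators for the network.

The classic way to quantify distractor-driven capture is the landing of the
first saccade: the search array is divided into six 60-degree pie-shaped
"chunks", each centered on a candidate stimulus location, and a trial counts
as captured when the first saccade lands in the distractor's chunk.  A
velocity-threshold detector extracts that first saccade from a raw trace
(vendor-parsed event tables can be supplied instead and are taken verbatim).

Also provided is the simple minimum-mean-distance baseline: average the
gaze-to-location distance over the whole trace for each of the six
locations and answer with the closest one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple
import warnings

import numpy as np

from .io import ArrayGeometry, Dataset

__all__ = [
    "SaccadeEvent",
    "SaccadeParams",
    "ChunkPartition",
    "detect_first_saccade",
    "detect_all_first_saccades",
    "assign_chunk",
    "first_saccade_distractor_rate",
    "min_mean_distance_baseline",
]


@dataclass(frozen=True)
class SaccadeEvent:
    onset_sample: int
    offset_sample: int
    landing_x: float
    landing_y: float
    peak_velocity: float  # pixels / sample

    def __post_init__(self) -> None:
        if self.onset_sample >= self.offset_sample:
            raise ValueError("saccade onset must precede offset")


@dataclass(frozen=True)
class SaccadeParams:
    """Velocity-threshold detector settings (pixels/sample at 500 Hz)."""

    velocity_threshold: float = 1.0
    min_duration_samples: int = 5  # 10 ms


@dataclass(frozen=True)
class ChunkPartition:
    """Six half-open 60-degree wedges, each centered on a location angle."""

    geometry: ArrayGeometry

    def wedge_bounds(self) -> np.ndarray:
        """(6, 2) array of [theta - 30, theta + 30) interval edges in degrees."""
        a = np.mod(np.asarray(self.geometry.location_angles, dtype=float), 360.0)
        return np.column_stack([a - 30.0, a + 30.0])


def _speeds(trace: np.ndarray) -> np.ndarray:
    # central-difference gaze speed in pixels/sample
    d = np.gradient(trace, axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def detect_first_saccade(
    trace: np.ndarray, params: SaccadeParams = SaccadeParams()
) -> Optional[SaccadeEvent]:
    """First sustained suprathreshold run of gaze speed, or None.

    A saccade is the first run of at least ``min_duration_samples``
    consecutive samples whose central-difference speed exceeds
    ``velocity_threshold``; the landing point is the gaze at the run's end.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape[0] < 2:
        return None
    if np.isnan(trace).any():
        raise ValueError("detector requires a gap-filled trace (no missing samples)")
    fast = _speeds(trace) > params.velocity_threshold
    n = fast.size
    i = 0
    while i < n:
        if fast[i]:
            j = i
            while j < n and fast[j]:
                j += 1
            if j - i >= params.min_duration_samples:
                off = j - 1
                v = _speeds(trace)[i:j].max()
                return SaccadeEvent(
                    onset_sample=i,
                    offset_sample=off,
                    landing_x=float(trace[off, 0]),
                    landing_y=float(trace[off, 1]),
                    peak_velocity=float(v),
                )
            i = j
        else:
            i += 1
    return None


def _hold_fill(trace: np.ndarray, g: ArrayGeometry) -> np.ndarray:
    """Fill dropouts by holding the last seen position (center before first).

    Center-filling (the network's preprocessing) would fabricate huge
    center-ward jumps at every dropout and corrupt velocity estimates, so
    event detection holds position across gaps instead.
    """
    out = np.array(trace, dtype=float, copy=True)
    for c in range(out.shape[1]):
        col = out[:, c]
        bad = np.isnan(col)
        if bad.all():
            col[:] = (g.center_x, g.center_y)[c]
            continue
        idx = np.where(~bad, np.arange(col.size), 0)
        np.maximum.accumulate(idx, out=idx)
        col[:] = col[idx]
        lead = np.isnan(col)
        col[lead] = (g.center_x, g.center_y)[c]
    return out


def detect_all_first_saccades(
    d: Dataset, params: SaccadeParams = SaccadeParams()
) -> Dict[Tuple[str, int], Optional[SaccadeEvent]]:
    """Per-trial first saccade over a dataset (dropouts hold-filled first)."""
    return {
        k: detect_first_saccade(_hold_fill(d.traces[k], d.geometry), params)
        for k in d.trial_keys
    }


def assign_chunk(x: float, y: float, part: ChunkPartition) -> int:
    """Index of the wedge containing screen point (x, y); radius is ignored.

    The point is centered on fixation and y-negated before taking atan2; a
    point exactly at fixation has no angle and raises.
    """
    g = part.geometry
    u, v = x - g.center_x, -(y - g.center_y)
    if u == 0.0 and v == 0.0:
        raise ValueError("angle undefined exactly at the fixation center")
    # snap at nanodegree precision so exact wedge boundaries classify
    # deterministically despite the atan2 round trip
    ang = np.round(np.degrees(np.arctan2(v, u)) % 360.0, 9)
    centers = np.mod(np.asarray(g.location_angles, dtype=float), 360.0)
    delta = (ang - centers + 180.0) % 360.0 - 180.0  # signed offset in (-180, 180]
    inside = (delta >= -30.0) & (delta < 30.0)
    return int(np.flatnonzero(inside)[0])


def first_saccade_distractor_rate(
    d: Dataset,
    events: Dict[Tuple[str, int], Optional[SaccadeEvent]],
) -> Dict[str, float]:
    """Per-participant proportion of first saccades landing in the distractor chunk.

    Only distractor-present trials enter; trials without a detected saccade
    (or without eye data) are dropped from the denominator.  A participant
    with no qualifying trial is omitted with a warning.
    """
    part = ChunkPartition(d.geometry)
    hits: Dict[str, list] = {}
    trials = d.trials
    present = trials["distractor_location"].notna()
    if not present.all():
        raise ValueError("subset distractor-present trials before computing the rate")
    for row in trials.itertuples():
        key = (row.participant_id, int(row.trial_index))
        ev = events.get(key)
        if ev is None:
            continue
        chunk = assign_chunk(ev.landing_x, ev.landing_y, part)
        hits.setdefault(row.participant_id, []).append(chunk == int(row.distractor_location))
    out: Dict[str, float] = {}
    for pid in d.participants():
        if pid not in hits:
            warnings.warn(
                f"participant {pid!r} has no trial with a detected saccade; omitted",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out[pid] = float(np.mean(hits[pid]))
    return out


def min_mean_distance_baseline(trace: np.ndarray, g: ArrayGeometry) -> int:
    """Location whose center has the smallest mean distance to the gaze trace.

    Ties (e.g. a trace parked at fixation, equidistant from all six) resolve
    to the lowest index.
    """
    trace = np.asarray(trace, dtype=float)
    if np.isnan(trace).any():
        raise ValueError("baseline requires a gap-filled trace")
    coords = g.location_coords()  # (6, 2)
    dists = np.linalg.norm(trace[:, None, :] - coords[None, :, :], axis=2)
    # round so exact geometric ties (e.g. a center-parked trace) resolve to
    # the lowest index instead of float noise
    return int(np.argmin(np.round(dists.mean(axis=0), 9)))
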