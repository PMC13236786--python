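"""On-disk interchange formats and the in-memory dataset container.

Gaze recordings travel as a pair of long-form CSV files:

* a *meta* file with one row per trial
  (``participant_id,trial_index,target_location,distractor_location,rt_ms,n_recorded_samples``),
* a *trace* file with one row per recorded sample
  (``participant_id,trial_index,sample_index,x,y``).

Missing samples (eye-tracker dropouts) and absent distractors are encoded as
empty cells and held in memory as NaN.  The six candidate stimulus locations
sit on a circle around central fixation and are described by
:class:`ArrayGeometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConsistencyError",
    "ArrayGeometry",
    "Dataset",
    "default_geometry",
    "read_dataset",
    "write_dataset",
    "validate_trials",
    "META_COLUMNS",
    "TRACE_COLUMNS",
]

META_COLUMNS = (
    "participant_id",
    "trial_index",
    "target_location",
    "distractor_location",
    "rt_ms",
    "n_recorded_samples",
)
TRACE_COLUMNS = ("participant_id", "trial_index", "sample_index", "x", "y")

#: Sampling period of the eye tracker, in milliseconds (500 Hz).
SAMPLE_PERIOD_MS = 2.0


class FormatError(ValueError):
    """A file does not follow the documented interchange format."""


class ConsistencyError(ValueError):
    """Trial metadata and traces contradict each other or an invariant."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Circular six-location search-array geometry on a pixel screen.

    Screen coordinates use the raster convention: origin top-left, x grows
    rightward, y grows *downward*.  Polar angles are measured counterclockwise
    from the positive x-axis in the conventional mathematical frame, i.e. the
    screen y-coordinate is negated before any trigonometry.

    Parameters
    ----------
    center_x, center_y
        Central fixation, in pixels.
    eccentricity
        Distance from fixation to each stimulus center, in pixels.
    location_angles
        Six polar angles in degrees, one per candidate location, indexed 0-5.
    stimulus_radius
        Radius of each stimulus disc, in pixels (used only for overlays).
    meridian
        Which screen axis carries two stimuli: ``"horizontal"`` or
        ``"vertical"``.
    """

    center_x: float
    center_y: float
    eccentricity: float
    location_angles: Tuple[float, ...]
    stimulus_radius: float
    meridian: str

    def __post_init__(self) -> None:
        if len(self.location_angles) != 6:
            raise ValueError("exactly 6 location angles are required")
        if self.eccentricity <= 0:
            raise ValueError("eccentricity must be positive")
        ang = np.sort(np.mod(self.location_angles, 360.0))
        if len(np.unique(np.round(ang, 9))) != 6:
            raise ValueError("location angles must be distinct modulo 360")
        gaps = np.diff(np.concatenate([ang, [ang[0] + 360.0]]))
        if not np.allclose(gaps, 60.0):
            raise ValueError("adjacent locations must be 60 degrees apart")
        if self.meridian not in ("horizontal", "vertical"):
            raise ValueError("meridian must be 'horizontal' or 'vertical'")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y], dtype=float)

    def location_coords(self) -> np.ndarray:
        """Pixel coordinates of the six stimulus centers, shape (6, 2).

        y is negated going from the math frame back to screen pixels, so a
        positive angle places the stimulus *above* fixation on screen.
        """
        theta = np.deg2rad(np.asarray(self.location_angles, dtype=float))
        dx = self.eccentricity * np.cos(theta)
        dy = -self.eccentricity * np.sin(theta)
        return np.column_stack([self.center_x + dx, self.center_y + dy])


def default_geometry(
    screen_w: float = 2560.0,
    screen_h: float = 1440.0,
    meridian: str = "horizontal",
    eccentricity: float = 400.0,
    stimulus_radius: float = 75.0,
) -> ArrayGeometry:
    """Standard six-location geometry for a given screen.

    Central fixation is the pixel-grid center ``((w-1)/2, (h-1)/2)`` — e.g.
    (1279.5, 719.5) on a 2560x1440 display.  The ``horizontal`` variant places
    two stimuli on the horizontal meridian (angles 0..300 in 60-degree steps);
    the ``vertical`` variant rotates the array by 30 degrees (angles 30..330).
    Location indices run counterclockwise starting from the smallest
    non-negative angle.
    """
    if screen_w <= 0 or screen_h <= 0:
        raise ValueError("screen dimensions must be positive")
    if meridian == "horizontal":
        angles = tuple(float(a) for a in range(0, 360, 60))
    elif meridian == "vertical":
        angles = tuple(float(a) for a in range(30, 360, 60))
    else:
        raise ValueError("meridian must be 'horizontal' or 'vertical'")
    return ArrayGeometry(
        center_x=(screen_w - 1) / 2.0,
        center_y=(screen_h - 1) / 2.0,
        eccentricity=float(eccentricity),
        location_angles=angles,
        stimulus_radius=float(stimulus_radius),
        meridian=meridian,
    )


@dataclass
class Dataset:
    """A geometry, a trial table, and one raw gaze trace per trial.

    ``trials`` is a pandas DataFrame with the meta-file columns; absent
    distractors and missing RTs are NaN.  ``traces`` maps
    ``(participant_id, trial_index)`` to a float array of shape
    ``(n_samples, 2)`` with columns (x, y) in pixels and NaN for missing
    samples.  The dict iterates in (participant_id, trial_index) order.
    """

    geometry: ArrayGeometry
    trials: pd.DataFrame
    traces: Dict[Tuple[str, int], np.ndarray] = field(default_factory=dict)

    @property
    def trial_keys(self):
        return [(row.participant_id, int(row.trial_index)) for row in self.trials.itertuples()]

    def participants(self):
        return list(dict.fromkeys(self.trials["participant_id"]))

    def with_trials(self, trials: pd.DataFrame) -> "Dataset":
        """Subset view sharing traces, restricted to the given trial rows."""
        keys = {(r.participant_id, int(r.trial_index)) for r in trials.itertuples()}
        traces = {k: v for k, v in self.traces.items() if k in keys}
        return replace(self, trials=trials.reset_index(drop=True), traces=traces)


def validate_trials(trials: pd.DataFrame) -> None:
    for col in META_COLUMNS:
        if col not in trials.columns:
            raise FormatError(f"meta file is missing required column {col!r}")
    if (trials["trial_index"] < 1).any():
        raise ConsistencyError("trial_index must be >= 1")
    dup = trials.duplicated(subset=["participant_id", "trial_index"])
    if dup.any():
        raise ConsistencyError("trial_index must be unique within participant")
    for col in ("target_location", "distractor_location"):
        vals = trials[col].dropna()
        if ((vals < 0) | (vals > 5)).any():
            raise ConsistencyError(f"{col} values must lie in 0..5")
    present = trials["distractor_location"].notna()
    clash = present & (trials.loc[present, "distractor_location"] == trials.loc[present, "target_location"])
    if clash.any():
        bad = trials.loc[clash, ["participant_id", "trial_index"]].iloc[0]
        raise ConsistencyError(
            "distractor_location equals target_location for participant "
            f"{bad.participant_id!r} trial {int(bad.trial_index)}"
        )


def read_dataset(trace_file, meta_file, geometry: ArrayGeometry | None = None) -> Dataset:
    """Read the CSV pair into a :class:`Dataset`.

    Trials and traces are grouped and ordered by (participant_id,
    trial_index); empty cells become NaN and are preserved as missing.
    A trace row referring to a trial absent from the meta file raises
    :class:`ConsistencyError`; a missing column raises :class:`FormatError`
    naming the column.
    """
    if geometry is None:
        geometry = default_geometry()
    meta = pd.read_csv(meta_file, dtype={"participant_id": str})
    validate_trials(meta)
    meta = meta.sort_values(["participant_id", "trial_index"], kind="stable").reset_index(drop=True)

    tr = pd.read_csv(trace_file, dtype={"participant_id": str})
    for col in TRACE_COLUMNS:
        if col not in tr.columns:
            raise FormatError(f"trace file is missing required column {col!r}")

    known = {(r.participant_id, int(r.trial_index)) for r in meta.itertuples()}
    traces: Dict[Tuple[str, int], np.ndarray] = {}
    if len(tr):
        tr = tr.sort_values(["participant_id", "trial_index", "sample_index"], kind="stable")
        for (pid, tidx), grp in tr.groupby(["participant_id", "trial_index"], sort=True):
            key = (str(pid), int(tidx))
            if key not in known:
                raise ConsistencyError(
                    f"trace refers to unknown trial {key[1]} of participant {key[0]!r}"
                )
            n = int(grp["sample_index"].max()) + 1 if len(grp) else 0
            arr = np.full((n, 2), np.nan)
            idx = grp["sample_index"].to_numpy(dtype=int)
            arr[idx, 0] = grp["x"].to_numpy(dtype=float)
            arr[idx, 1] = grp["y"].to_numpy(dtype=float)
            traces[key] = arr
    for key in sorted(known):
        traces.setdefault(key, np.empty((0, 2)))
    traces = {k: traces[k] for k in ((r.participant_id, int(r.trial_index)) for r in meta.itertuples())}
    return Dataset(geometry=geometry, trials=meta, traces=traces)


def write_dataset(d: Dataset, trace_file, meta_file) -> None:
    """Write the CSV pair; NaN cells are written empty, round-trip lossless."""
    trace_file, meta_file = Path(trace_file), Path(meta_file)
    meta = d.trials.loc[:, list(META_COLUMNS)].copy()
    meta.to_csv(meta_file, index=False, na_rep="")

    rows = []
    for (pid, tidx), arr in d.traces.items():
        n = arr.shape[0]
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "trial_index": tidx,
                    "sample_index": np.arange(n),
                    "x": arr[:, 0],
                    "y": arr[:, 1],
                }
            )
        )
    if rows:
        out = pd.concat(rows, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(TRACE_COLUMNS))
    out.to_csv(trace_file, index=False, na_rep="")
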