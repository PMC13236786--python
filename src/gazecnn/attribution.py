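"""Additive feature attribution for the gaze classifier, and the
spatiotemporal analyses built on top of it.

For every query trial, each of the 1,200 input cells (2 features x 600
samples) receives, per output class, a signed contribution relative to a
background reference set, computed by backpropagating rescale-rule
multipliers through the network (the deep variant of Shapley-value
approximation for networks with hidden layers).  Contributions are exactly
additive: summed over cells they equal the query logit minus the mean
background logit, class by class.

Per-sample *global importance* is the mean absolute contribution over the
12 (feature x class) cells at that sample.  Downstream analyses take the
gaze position at each trial's importance peak, rotate trials about fixation
to align object locations, and summarise the point cloud with a
Silverman-bandwidth Gaussian KDE and a polar histogram coloured by peak
time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .io import ArrayGeometry, SAMPLE_PERIOD_MS
from .network import GazeNet

__all__ = [
    "AttributionError",
    "AttributionTensor",
    "GlobalImportance",
    "KDEGrid",
    "explain",
    "global_importance",
    "max_shap_vs_rt",
    "rotate_point",
    "silverman_bandwidth",
    "kde_heatmap",
    "polar_time_histogram",
    "correct_mask",
    "first_saccade_chunk_mask",
]


class AttributionError(RuntimeError):
    """The additivity/completeness contract was violated."""


@dataclass
class AttributionTensor:
    """Signed contributions: queries x 2 features x L samples x 6 classes."""

    values: np.ndarray
    baseline_outputs: np.ndarray  # (6,) mean background logits
    query_outputs: np.ndarray     # (n, 6) query logits
    trial_order: list

    def additivity_residual(self) -> float:
        """Largest relative completeness residual over queries and classes."""
        total = self.values.sum(axis=(1, 2))
        target = self.query_outputs - self.baseline_outputs
        scale = np.abs(target).max() + 1e-12
        return float(np.abs(total - target).max() / scale)


@dataclass
class GlobalImportance:
    """Per-sample mean |contribution| across the 12 feature-class cells."""

    values: np.ndarray        # (n, L), nonnegative
    argmax_sample: np.ndarray  # (n,) 0-based; ties -> earliest
    argmax_gaze: np.ndarray    # (n, 2) gaze (x, y) at the peak sample
    trial_order: list


@dataclass
class KDEGrid:
    density: np.ndarray  # (ny, nx), max-normalised to [0, 1]
    xs: np.ndarray
    ys: np.ndarray
    bandwidth: float
    raw_integral: float  # pre-normalisation mass x cell area


# ----- the explainer --------------------------------------------------------


def _forward_states(model: GazeNet, x: np.ndarray) -> dict:
    cache: dict = {}
    was = model.training
    model.training = False
    logits = model.forward(x, cache=cache)
    model.training = was
    cache["logits"] = logits
    return cache


def _head_multiplier(model: GazeNet) -> np.ndarray:
    """Composite multiplier of the (activation-free) linear head: (flat, 6)."""
    M = model.params[f"W{model.n_linear - 1}"]
    for i in range(model.n_linear - 2, -1, -1):
        M = model.params[f"W{i}"] @ M
    return M


def explain(
    model: GazeNet,
    background: np.ndarray,
    queries: np.ndarray,
    trial_order: Optional[list] = None,
    tol: float = 1e-3,
    ref_chunk: int = 32,
) -> AttributionTensor:
    """Backpropagation-based additive contributions vs a background set.

    ``background`` and ``queries`` are (n, 2, L) arrays (by convention the
    background is the first 100 validation trials, or all of them if fewer).
    Per query-reference pair, rescale multipliers traverse the linear head
    exactly, route each pooling window's output difference through the
    window element with the dominant activation difference, rescale through
    the ReLU, and distribute linearly through the convolution; pairs are
    then averaged over references.  Dropout is inactive.  Deterministic.

    Raises :class:`AttributionError` if the additivity residual exceeds
    ``tol`` (relative).
    """
    background = np.asarray(background, dtype=float)
    queries = np.asarray(queries, dtype=float)
    cfg = model.config
    if cfg.stride != 1:
        raise NotImplementedError("the explainer assumes a stride-1 convolution")
    Lp, pool = cfg.pooled_length, cfg.pool_size
    F, Lc = cfg.conv_features, cfg.conv_length
    nC = cfg.n_classes

    ref = _forward_states(model, background)
    # per-window head multiplier, expanded to conv positions (zero in the
    # pooling-trimmed tail, which cannot influence the output)
    M_pool = _head_multiplier(model).reshape(F, Lp, nC)
    M_pos = np.zeros((F, Lc, nC))
    M_pos[:, : Lp * pool] = np.repeat(M_pool, pool, axis=1)

    n_ref = background.shape[0]
    ref_pre = ref["pre"]
    ref_act = np.maximum(ref_pre, 0.0)
    ref_win = ref_act[:, :, : Lp * pool].reshape(n_ref, F, Lp, pool)
    ref_poolv = ref_win.max(axis=3)
    baseline = ref["logits"].mean(axis=0)

    Wc = model.params["Wc"]
    out = np.zeros((queries.shape[0], cfg.in_channels, cfg.input_length, nC))
    q_logits = np.empty((queries.shape[0], nC))

    for qi in range(queries.shape[0]):
        q = _forward_states(model, queries[qi : qi + 1])
        q_logits[qi] = q["logits"][0]
        q_pre = q["pre"][0]
        q_act = np.maximum(q_pre, 0.0)
        q_win = q_act[:, : Lp * pool].reshape(F, Lp, pool)
        q_poolv = q_win.max(axis=2)
        phi = np.zeros((cfg.in_channels, cfg.input_length, nC))
        for s in range(0, n_ref, ref_chunk):
            r_sl = slice(s, min(s + ref_chunk, n_ref))
            # route each pooling window's delta through its dominant-delta
            # element: multiplier ratio = d_pool / d_selected there, 0 elsewhere
            d_win = q_win[None] - ref_win[r_sl]                  # (R, F, Lp, pool)
            d_pool = q_poolv[None] - ref_poolv[r_sl]             # (R, F, Lp)
            sel = np.abs(d_win).argmax(axis=3)
            d_sel = np.take_along_axis(d_win, sel[..., None], axis=3)[..., 0]
            ratio = np.divide(
                d_pool, d_sel, out=np.zeros_like(d_pool), where=d_sel != 0.0
            )
            # ReLU rescale: delta-out / delta-in, gradient fallback at ties
            d_pre = q_pre[None] - ref_pre[r_sl]
            d_act = q_act[None] - ref_act[r_sl]
            small = np.abs(d_pre) < 1e-9
            m_relu = np.divide(d_act, d_pre, out=np.zeros_like(d_act), where=~small)
            m_relu[small] = np.broadcast_to((q_pre > 0), d_pre.shape)[small]
            # scalar multiplier field at conv positions: nonzero only at the
            # routed element of each window (class dim factored out via M_pos)
            sval = ratio * np.take_along_axis(
                m_relu[:, :, : Lp * pool].reshape(*d_pool.shape, pool), sel[..., None], axis=3
            )[..., 0]
            S = np.zeros((d_pool.shape[0], F, Lc))
            Sw = S[:, :, : Lp * pool].reshape(*d_pool.shape, pool)
            np.put_along_axis(Sw, sel[..., None], sval[..., None], axis=3)
            S[:, :, : Lp * pool] = Sw.reshape(d_pool.shape[0], F, Lp * pool)
            # contract references first, then distribute through the conv
            d_x = queries[qi][None] - background[r_sl]           # (R, 2, L)
            for k in range(cfg.kernel_size):
                U = np.einsum("rfl,rcl->flc", S, d_x[:, :, k : k + Lc], optimize=True)
                phi[:, k : k + Lc] += np.einsum(
                    "fc,flc,flj->clj", Wc[:, :, k], U, M_pos, optimize=True
                )
        out[qi] = phi / n_ref

    tensor = AttributionTensor(
        values=out,
        baseline_outputs=baseline,
        query_outputs=q_logits,
        trial_order=list(trial_order) if trial_order is not None else list(range(len(queries))),
    )
    resid = tensor.additivity_residual()
    if resid > tol:
        raise AttributionError(
            f"additivity violated: relative residual {resid:.2e} exceeds {tol:.0e}"
        )
    return tensor


def global_importance(a: AttributionTensor, queries: Optional[np.ndarray] = None) -> GlobalImportance:
    """Collapse to one nonnegative importance per sample (mean |.| over 12 cells)."""
    vals = np.abs(a.values).mean(axis=(1, 3))  # (n, L)
    arg = vals.argmax(axis=1)                  # first occurrence on ties
    if queries is not None:
        queries = np.asarray(queries, dtype=float)
        gaze = queries[np.arange(len(arg)), :, arg]
    else:
        gaze = np.full((len(arg), 2), np.nan)
    return GlobalImportance(
        values=vals, argmax_sample=arg, argmax_gaze=gaze, trial_order=a.trial_order
    )


def max_shap_vs_rt(gi: GlobalImportance, trials: pd.DataFrame) -> pd.DataFrame:
    """Pair each trial's importance-peak time (sample x 2 ms) with its RT.

    The returned frame flags trials whose peak falls after the response
    (above the unity line), i.e. inside the fixation-padded tail.
    """
    if len(trials) != len(gi.argmax_sample):
        raise ValueError("trial table must align with the importance rows")
    t_ms = gi.argmax_sample * SAMPLE_PERIOD_MS
    rt = trials["rt_ms"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "participant_id": trials["participant_id"].to_numpy(),
            "trial_index": trials["trial_index"].to_numpy(),
            "argmax_time_ms": t_ms,
            "rt_ms": rt,
            "after_response": t_ms > rt,
        }
    )


# ----- rotation, KDE, polar histogram --------------------------------------


def rotate_point(
    x, y, g: ArrayGeometry, from_angle: float, to_angle: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Rigidly rotate screen point(s) about fixation by (to - from) degrees.

    The rotation is counterclockwise in the mathematical frame; because
    screen y grows downward, the point is y-negated into that frame and
    back.  Used to align every trial's distractor (or target) at a common
    polar angle before spatial pooling.
    """
    phi = np.deg2rad(to_angle - from_angle)
    u = np.asarray(x, dtype=float) - g.center_x
    v = -(np.asarray(y, dtype=float) - g.center_y)
    u2 = u * np.cos(phi) - v * np.sin(phi)
    v2 = u * np.sin(phi) + v * np.cos(phi)
    return g.center_x + u2, g.center_y - v2


def silverman_bandwidth(points: np.ndarray) -> float:
    """Rule-of-thumb bandwidth for a 2-D Gaussian KDE: mean(sd_x, sd_y) * n^(-1/6)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two 2-D points")
    sd = pts.std(axis=0, ddof=1)
    sbar = float(sd.mean())
    if sbar <= 0:
        raise ValueError("zero spread: bandwidth undefined")
    return sbar * pts.shape[0] ** (-1.0 / 6.0)


def kde_heatmap(
    points: np.ndarray,
    h: float,
    resolution: float = 10.0,
    extent: Tuple[float, float, float, float] = (0.0, 2560.0, 0.0, 1440.0),
) -> KDEGrid:
    """Isotropic-Gaussian KDE on a pixel grid, max-normalised for display.

    The raw (pre-normalisation) grid is a proper density: summed over cells
    and multiplied by the cell area it integrates to ~1 when the bandwidth
    spans a few cells and the mass sits inside the extent.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one 2-D point")
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    x0, x1, y0, y1 = extent
    xs = np.arange(x0 + resolution / 2, x1, resolution)
    ys = np.arange(y0 + resolution / 2, y1, resolution)
    dx = xs[None, :] - pts[:, 0][:, None]   # (n, nx)
    dy = ys[None, :] - pts[:, 1][:, None]   # (n, ny)
    gx = np.exp(-0.5 * (dx / h) ** 2)
    gy = np.exp(-0.5 * (dy / h) ** 2)
    dens = (gy.T @ gx) / (pts.shape[0] * 2.0 * np.pi * h * h)  # (ny, nx)
    integral = float(dens.sum() * resolution * resolution)
    peak = dens.max()
    return KDEGrid(
        density=dens / peak if peak > 0 else dens,
        xs=xs,
        ys=ys,
        bandwidth=float(h),
        raw_integral=integral,
    )


def polar_time_histogram(
    points: np.ndarray,
    times_ms: np.ndarray,
    g: ArrayGeometry,
    n_bins: int = 24,
) -> pd.DataFrame:
    """Counts and mean peak time by polar angle around fixation.

    Bin 0 is centered on 0 degrees; bins are half-open and tile the circle.
    Points exactly at fixation carry no angle and are dropped with a warning.
    """
    pts = np.asarray(points, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    u = pts[:, 0] - g.center_x
    v = -(pts[:, 1] - g.center_y)
    central = (u == 0) & (v == 0)
    if central.any():
        warnings.warn(
            f"excluding {int(central.sum())} point(s) at the exact fixation center",
            RuntimeWarning,
            stacklevel=2,
        )
    u, v, times = u[~central], v[~central], times[~central]
    ang = np.degrees(np.arctan2(v, u)) % 360.0
    width = 360.0 / n_bins
    idx = (np.floor((ang + width / 2) / width) % n_bins).astype(int)
    centers = np.arange(n_bins) * width
    count = np.bincount(idx, minlength=n_bins)
    tsum = np.bincount(idx, weights=times, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_t = np.where(count > 0, tsum / np.maximum(count, 1), np.nan)
    return pd.DataFrame(
        {"angle_deg": centers, "count": count, "mean_time_ms": mean_t}
    )


# ----- composable trial filters --------------------------------------------


def correct_mask(report) -> np.ndarray:
    """Boolean mask of correctly classified trials from an AccuracyReport."""
    return report.trial_outcomes["correct"].to_numpy(dtype=bool)


def first_saccade_chunk_mask(
    trials: pd.DataFrame,
    events: Dict[Tuple[str, int], object],
    g: ArrayGeometry,
    column: str = "target_location",
) -> np.ndarray:
    """Mask of trials whose first saccade landed in the `column` location's chunk.

    Trials without a detected saccade are False.  Negate to select, e.g.,
    trials with a first saccade *not* directed at the target.
    """
    from .heuristic import ChunkPartition, assign_chunk

    part = ChunkPartition(g)
    out = np.zeros(len(trials), dtype=bool)
    for i, row in enumerate(trials.itertuples()):
        ev = events.get((row.participant_id, int(row.trial_index)))
        if ev is None:
            continue
        loc = getattr(row, column)
        if pd.isna(loc):
            continue
        out[i] = assign_chunk(ev.landing_x, ev.landing_y, part) == int(loc)
    return out
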