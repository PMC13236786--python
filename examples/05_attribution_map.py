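"""What in the gaze trace drives the distractor classifier?

Trains a small distractor-location CNN on a capture cohort, attributes each
validation trial's logits back to the 1,200 input cells, and summarises the
per-trial importance peaks: their timing against RT, and their spatial
distribution after rotating all trials to put the distractor at 0 degrees.
The capture/correction signature is importance near the distractor early in
the trial and opposite it later.  (Runs a couple of minutes on one CPU.)
"""

import numpy as np

from gazecnn import SynthConfig, TrainConfig, generate
from gazecnn.attribution import (
    explain,
    global_importance,
    kde_heatmap,
    max_shap_vs_rt,
    polar_time_histogram,
    rotate_point,
    silverman_bandwidth,
)
from gazecnn.partition import split_every_third, subset_distractor_present
from gazecnn.preprocess import preprocess_dataset
from gazecnn.training import evaluate_split, fit

d = generate(SynthConfig(n_participants=12, trials_per_participant=120, capture_prob=0.3, seed=3))
dp = d.with_trials(subset_distractor_present(d.trials))
data, labels = preprocess_dataset(dp, semantics="distractor")
split = split_every_third(dp.trials)
model, _ = fit(data, labels, split, train_cfg=TrainConfig(seed=0, max_epochs=30))
mask = split.mask(data.trial_order, "val")
_, acc, _ = evaluate_split(model, data.values[mask], labels[mask])
print(f"distractor validation accuracy {acc:.1%} (chance 16.7%)")

xval = data.values[mask]
vt = dp.trials[mask].reset_index(drop=True)
att = explain(model, xval[:100], xval[:150])   # background: first 100 validation trials
print(f"additivity residual {att.additivity_residual():.2e} (contract: < 1e-3)")

gi = global_importance(att, xval[:150])
timing = max_shap_vs_rt(gi, vt.iloc[:150])
print(f"importance peak precedes the response on {1 - timing['after_response'].mean():.1%} of trials")

angles = np.asarray(d.geometry.location_angles)
dloc = vt["distractor_location"].to_numpy(int)[:150]
rx, ry = rotate_point(gi.argmax_gaze[:, 0], gi.argmax_gaze[:, 1], d.geometry,
                      from_angle=angles[dloc], to_angle=0.0)
pts = np.column_stack([rx, ry])
hist = polar_time_histogram(pts, gi.argmax_sample * 2.0, d.geometry, n_bins=6)
print("\npolar histogram of importance peaks (distractor aligned at 0 deg):")
print(hist.round(1).to_string(index=False))

h = silverman_bandwidth(pts)
grid = kde_heatmap(pts, h)
iy, ix = np.unravel_index(grid.density.argmax(), grid.density.shape)
print(f"\nKDE bandwidth {h:.1f} px (Silverman); density peak at "
      f"({grid.xs[ix]:.0f}, {grid.ys[iy]:.0f}) px on a 10-px grid")
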