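"""Generate a synthetic visual-search cohort and round-trip it through the
CSV interchange format.

Each trial is a 500-Hz (x, y) gaze trace: central fixation, a saccade to the
target (or, on 30% of distractor-present trials, first to the distractor),
and truncation at the response.
"""

import tempfile
from pathlib import Path

from gazecnn import SynthConfig, generate, read_dataset, write_dataset

d = generate(SynthConfig(n_participants=3, trials_per_participant=20, seed=0))
print(f"{len(d.trials)} trials from {len(d.participants())} participants")
print(d.trials.head(4).to_string(index=False))

with tempfile.TemporaryDirectory() as tmp:
    tf, mf = Path(tmp) / "traces.csv", Path(tmp) / "meta.csv"
    write_dataset(d, tf, mf)
    back = read_dataset(tf, mf, geometry=d.geometry)
    same = all((back.traces[k].shape == d.traces[k].shape) for k in d.traces)
    print(f"round-trip preserved all {len(back.traces)} traces: {same}")

# distractor-present trials are half of each participant's session; the
# 'captured' column is the generator's ground truth for first-saccade capture
present = d.trials["distractor_location"].notna()
print(f"distractor present on {present.mean():.0%} of trials; "
      f"capture ground truth on {d.trials.loc[present, 'captured'].mean():.0%} of those")
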