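"""The traditional comparator: where does the first saccade land?

The search array is divided into six 60-degree pie-shaped chunks centered on
the candidate locations; a distractor-present trial counts as 'captured'
when the first saccade lands in the distractor's chunk.  With the generator
set to 30% capture, the recovered rate should sit near 0.30, and the
min-mean-distance baseline should recover the target on direct trials.
"""

import numpy as np

from gazecnn import SynthConfig, generate
from gazecnn.heuristic import (
    detect_all_first_saccades,
    first_saccade_distractor_rate,
    min_mean_distance_baseline,
)
from gazecnn.partition import subset_distractor_present
from gazecnn.preprocess import fill_missing, pad_or_truncate

d = generate(SynthConfig(n_participants=8, trials_per_participant=80, capture_prob=0.3, seed=2))
dp = d.with_trials(subset_distractor_present(d.trials))
events = detect_all_first_saccades(dp)
detected = sum(ev is not None for ev in events.values())
print(f"first saccade detected on {detected}/{len(events)} distractor-present trials")

rates = first_saccade_distractor_rate(dp, events)
print(f"mean distractor-chunk landing rate {np.mean(list(rates.values())):.3f} "
      f"(generator capture probability 0.30, chance 0.167)")

hits = 0
for row in d.trials.itertuples():
    trace = pad_or_truncate(
        fill_missing(d.traces[(row.participant_id, int(row.trial_index))], d.geometry),
        600, d.geometry,
    )
    hits += min_mean_distance_baseline(trace, d.geometry) == int(row.target_location)
print(f"min-mean-distance baseline recovers target on {hits / len(d.trials):.1%} of trials")
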