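"""Generate a synthetic virtual-navigation session and inspect behavior.

Builds a 40-trial session on the 200-cm circular corridor with gain
blocks at {0.8, 1.0, 1.2}, segments it into trials, detects lick bouts
and classifies trial outcomes.
"""

import numpy as np

from vrnav import GeneratorConfig, generate_session, physical_lap_distance
from vrnav.session import (
    classify_trials, detect_lick_bouts, licks_from_timeline, segment_trials,
)

session = generate_session(GeneratorConfig(n_trials=40, n_ca1=8, n_v1=6, seed=7))
tl = session.timeline

trials = segment_trials(tl)
licks = licks_from_timeline(tl)
bouts = detect_lick_bouts(
    licks["position"].to_numpy(), licks["trial_id"].to_numpy(),
    licks["rewarded"].to_numpy(), tl.geometry,
)
trials = classify_trials(bouts, trials)

print(f"session: {tl.duration / 60:.1f} min, {len(trials)} trials, "
      f"{len(session.spikes)} neurons, {int(tl.lick.sum())} licks")
print("gain counts:", trials["gain"].value_counts().to_dict())
print("outcomes:", trials["outcome"].value_counts().to_dict())
for g in sorted(trials["gain"].unique()):
    # physical running distance needed per lap: corridor_length / gain
    print(f"  gain {g}: a 200-cm lap costs {physical_lap_distance(200, g):.0f} cm of running")

# the wheel trace obeys the gain geometry trial by trial
r = trials.iloc[3]
wheel_run = tl.wheel[int(r["i_end"]) - 1] - tl.wheel[int(r["i_start"])]
print(f"trial 3 (gain {r['gain']}): ran {wheel_run:.1f} cm "
      f"(expected ~{200 / r['gain']:.1f})")
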