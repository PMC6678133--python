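"""Simulate one labeled playroom session and inspect what it contains.

A session is a randomized sequence of behavior bouts (walking dominates,
as it does in real toddler play) joined by 1-s transitions, rendered as
time-aligned hip and wrist 30 Hz traces plus the ground-truth label track.
"""

from collections import Counter

import toddleracc as ta

schedule = ta.study_schedule("P01", seed=7)
hip, wrist, track = ta.simulate_session(schedule, ta.default_params(), seed=7)

print(f"session duration: {hip.duration:.0f} s "
      f"({hip.n_samples} samples at {hip.sample_rate:.0f} Hz, hip and wrist aligned)")
print(f"labels: {len(track)} intervals")
for behavior, count in sorted(Counter(l.behavior for l in track).items()):
    print(f"  {behavior:12s} x{count}")

kept = ta.filter_labels(track)
print(f"after the >=5 s / nine-behavior filter: {len(kept)} labels "
      "(transitions and short bouts drop out, as in video coding)")

noisy = ta.perturb_labels(kept, shift_sd_s=1.0, confusion_rate=0.05, seed=7)
agreement = ta.percent_agreement(kept, noisy)
print(f"agreement with a simulated second coder: {agreement.percent}% "
      f"({agreement.concordant}/{agreement.total} concordant)")
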