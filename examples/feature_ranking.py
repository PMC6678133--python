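"""Extract the 78 window features and rank them by d' for
carried-vs-ambulation separation.

Each 5-s single-behavior window yields 30 time-domain and 48
frequency-domain features; d' = |mean difference| / pooled SD scores how
well one feature alone separates the two classes.
"""

import toddleracc as ta

params = ta.default_params()
windows = []
for i in range(6):
    schedule = ta.study_schedule(f"P{i + 1:02d}", seed=100 + i)
    hip, _, track = ta.simulate_session(schedule, params, seed=100 + i)
    windows += ta.segment_windows(hip, ta.filter_labels(track))

table = ta.extract_features(windows)
print(f"{len(table)} windows x {len(ta.FEATURE_NAMES)} features "
      f"({len(ta.TIME_DOMAIN_NAMES)} time-domain + {len(ta.FREQ_DOMAIN_NAMES)} frequency-domain)")

binary = table.behavior.map(ta.binarize_labels)
ranking = ta.rank_features(table, binary)
print(f"\ntop 10 features by d' ({ranking.group_a} vs {ranking.group_b}):")
print(ranking.top(10).to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nhigh-d' spectral features reflect the design: a carried child's "
      "signal is the caregiver's low-pass-filtered gait, spectrally smoother "
      "than self-propelled movement.")
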