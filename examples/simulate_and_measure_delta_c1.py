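"""Simulate a small sight-recovery-like group and measure its ΔC1.

The generator injects a retinotopic C1 source that flips polarity between
upper and lower visual field stimuli and is multiplicatively suppressed in
the audiovisual conditions (AV_i: 0.5, AV_c: 0).  The ERP pipeline
(re-reference → 0.1–40 Hz band-pass → ocular/motor rejection → left/right
mirroring → baseline → averaging) then recovers the ΔC1 = LVF − UVF mean
over 50–100 ms at each posterior electrode.
"""

import pandas as pd

from c1race import (
    EEGSimConfig,
    expected_delta_c1,
    participant_delta_c1,
    simulate_eeg_participant,
)

config = EEGSimConfig(
    n_participants=4,
    trials_per_cell=120,
    c1_amplitude=2.0,                                # µV source strength
    suppression={"V": 1.0, "AV_i": 0.5, "AV_c": 0.0},
    noise_sd=5.0,
    seed=7,
)

frames = []
for i in range(config.n_participants):
    epochs = simulate_eeg_participant(config, i)
    rows, audit = participant_delta_c1(epochs, group="CC")
    frames.append(rows)
    print(f"participant {i + 1}: {audit['input']} trials in, "
          f"{audit['ocular_rejected']} ocular-rejected, "
          f"{audit['motor_rejected']} motor-rejected")

table = pd.concat(frames, ignore_index=True)
means = table.groupby(["condition", "electrode"]).delta_c1.mean().unstack()
print("\nmean ΔC1 (µV) per condition × electrode:")
print(means.round(2))

print("\nanalytic expectation at O1 per condition:")
for cond in ("V", "AV_i", "AV_c"):
    print(f"  {cond}: {expected_delta_c1(config, 'O1', cond):.2f} µV")

print("\nThe V condition shows the full retinotopic response; AV_i is "
      "halved and AV_c abolished, mirroring a spatially specific "
      "crossmodal suppression of the earliest visual cortical activity.")
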