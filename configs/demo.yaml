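# Desk-scale demonstration run: a suppressed (CC-like) group against an
# intact control group, followed by the behavioral race-model arm.
# Runs end-to-end in a few minutes on one CPU; byte-identical per seed.
seed: 11
out_dir: demo_out
groups:
  - name: CC
    suppression: {V: 1.0, AV_i: 0.5, AV_c: 0.0}
  - name: MCC
    suppression: {V: 1.0, AV_i: 1.0, AV_c: 1.0}
eeg:
  n_participants: 6
  trials_per_cell: 60
  include_auditory: false
inference:
  draws: 4000
  warmup: 500
rt:
  model: coactivation
  coactivation_shift: 40.0
  n_trials: 60
  n_participants: 8
rmi:
  n_perm: 1001
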