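# Demo study conditions shared by the numbered analysis scripts.
# 8 listeners, 40 trials per RATE x BOUNDARY cell, 16 sensors, 100 Hz;
# delta->P600 coupling 4 uV at preferred phase pi/4 (0.7854 rad).
seed: 7
simulation:
  n_participants: 8
  n_trials_per_condition: 40
  n_channels: 16
  sampling_rate: 100.0
erp:
  n_perm: 2000
phase:
  n_perm: 2000
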