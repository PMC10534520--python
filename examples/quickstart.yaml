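# Three-class synthetic benchmark: alpha-, beta- and gamma-dominant
# emotion profiles, 1 s windows with 50% overlap.
mode: benchmark
seed: 5
n_per_class: 60
n_channels: 2
window_length_s: 1.0
step_s: 0.5
train:
  hidden_dim: 32
  max_epochs: 120
  patience: 30
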