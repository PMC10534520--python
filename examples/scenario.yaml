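# Scenario script for `neuroemotion simulate`: emotion blocks with
# scripted transitions, rendered at the native 1000 Hz rate.
blocks:
  - [sad, 6.0]
  - [happy, 6.0]
n_channels: 2
sampling_rate_hz: 1000.0
seed: 11
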