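# Ratio-model anthropometry: one forearm measurement (m) plus the
# population segment-to-forearm ratio table (override any entry to use
# a different population model).
forearm: 0.25
ratios:
  forearm: 1.0
  upper_arm: 1.27
  back: 1.99
  thigh: 1.68
  calf: 1.69
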