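{
  "forearm": 0.25,
  "upper_arm": 0.30,
  "back": 0.50,
  "thigh": 0.45,
  "calf": 0.43
}
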