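{
  "version": 1,
  "endpoint": "radiation pneumonitis grade >= 2, lung",
  "lyman": {"model": "lyman", "td50": 30.8, "m": 0.37, "a_or_k": 0.99},
  "ps": {"model": "ps", "td50": 34.0, "m": 0.90, "a_or_k": 0.06}
}
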