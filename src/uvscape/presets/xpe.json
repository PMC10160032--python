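{
  "description": "XP-E (DDB2 loss): partially reduced GG-NER lesion sensing, TC-NER intact, pol eta intact.",
  "repair": {"gg_scale": 0.4, "tc_scale": 1.0},
  "tls": {"pol_eta": true, "beta_3prime": 0.55}
}
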