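{
  "description": "POLH-knockout cell line: same bypass deficiency as XP-V; repair-proficient background.",
  "repair": {"gg_scale": 1.0, "tc_scale": 1.0},
  "tls": {"pol_eta": false, "beta_3prime": 0.97}
}
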