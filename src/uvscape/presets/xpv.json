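{
  "description": "XP-V (POLH loss): NER intact, error-prone backup translesion synthesis with a strong 3-prime dimer error bias and mutagenic bypass of rare TA/TG photoproducts.",
  "repair": {"gg_scale": 1.0, "tc_scale": 1.0},
  "tls": {"pol_eta": false, "beta_3prime": 0.97}
}
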