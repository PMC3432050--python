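{
  "comment": "Default Reber-style two-branch/loop finite-state grammar over the five-syllable alphabet. Synthetic stand-in topology: the original diagram is not machine-readable, so this automaton was constructed to generate the same kind of sequence language (loops, branch points, lengths 2-5) and to classify the two canonical example sequences correctly.",
  "states": ["S0", "S1", "S2", "S3", "OUT"],
  "in": "S0",
  "out": ["OUT"],
  "arcs": [
    ["S0", "pok", "S1"],
    ["S0", "guk", "S2"],
    ["S1", "kun", "S2"],
    ["S1", "tik", "OUT"],
    ["S1", "pok", "S3"],
    ["S2", "dem", "S2"],
    ["S2", "tik", "OUT"],
    ["S2", "guk", "S3"],
    ["S2", "kun", "S1"],
    ["S3", "pok", "OUT"],
    ["S3", "kun", "S2"],
    ["S3", "tik", "S1"]
  ]
}
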