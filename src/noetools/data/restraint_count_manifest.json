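{
  "intra_residue": 545,
  "sequential": 655,
  "medium_range": 714,
  "long_range": 764,
  "intermolecular": 60,
  "hydrogen_bond": 116,
  "phi": 135,
  "psi": 135
}
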