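{
  "_comment": "Monoisotopic atomic masses (Da), CODATA/IUPAC 2021 values. 'D' is deuterium (2H). 'proton' is the mass of H+ used for charge adjustment of m/z (NOT the H atom mass).",
  "C": 12.0,
  "H": 1.00782503207,
  "D": 2.01410177812,
  "N": 14.0030740048,
  "O": 15.9949146196,
  "proton": 1.00727646688
}
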